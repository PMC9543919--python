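"""Generate the desk-scale synthetic cohort used by the downstream
analysis scripts.

Writes, per subject, the epochs container (HDF5), the trial table (CSV)
and the generator ground truth (JSON) under results/data/.
"""

import json
import pathlib
import sys

import numpy as np

from phasedecode.pipeline import desk_scale_config
from phasedecode.simulate import simulate_subject
from phasedecode.containers import write_epochs

SEED = 0
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    config = desk_scale_config(seed=SEED)
    print(f"simulating {config.n_subjects} subjects, "
          f"{2 * config.n_trials_per_condition} trials each, "
          f"{config.n_channels} sensor channels at {config.fs:.0f} Hz")
    for s in range(config.n_subjects):
        epochs, truth = simulate_subject(config, (SEED, s))
        write_epochs(epochs, OUT / f"sub-{s:02d}_epochs.h5")
        epochs.trial_table.to_csv(OUT / f"sub-{s:02d}_trials.csv", index=False)
        truth.to_json(OUT / f"sub-{s:02d}_truth.json")
        n_ok = int((epochs.trial_table["correct"]).sum())
        print(f"  sub-{s:02d}: {epochs.n_trials} trials "
              f"({n_ok} correct), modulator {truth.f_mod:.0f} Hz, "
              f"m={truth.mod_depth}, phi*={truth.phi_star:.2f} rad")
    with open(OUT / "config.json", "w") as f:
        json.dump({k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()}, f, indent=2)
    print(f"wrote cohort to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
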