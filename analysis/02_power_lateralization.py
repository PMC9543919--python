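"""Attentional modulation of alpha power: AMI topography and the
lateralization index on the dedicated lateralized-power fixture.

Covert spatial attention raises alpha power ipsilateral to the attended
hemifield and lowers it contralaterally; the attentional modulation index
(AMI) is the percent power difference attend-left vs attend-right, and the
lateralization index (LI) contrasts AMI over left vs right posterior
channels in the pre-stimulus alpha window.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

from phasedecode import spectral
from phasedecode.pipeline import desk_scale_config
from phasedecode.simulate import simulate_lateralized_power

SEED = 0
RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(5):
        config = desk_scale_config(seed=SEED, n_trials_per_condition=120)
        epochs = simulate_lateralized_power(config, subject_seed=(SEED, 90 + s))
        attend = epochs.trial_table["attend"].to_numpy()
        left = epochs.subset_trials(attend == "left")
        right = epochs.subset_trials(attend == "right")
        freqs = np.arange(4.0, 21.0, 1.0)
        amap = spectral.ami(
            spectral.tfr_hanning(left, freqs),
            spectral.tfr_hanning(right, freqs),
        )
        n_half = config.n_channels // 2
        li = spectral.lateralization_index(
            amap,
            left_set=epochs.channel_names[:n_half],
            right_set=epochs.channel_names[n_half:2 * n_half],
        )
        rows.append({"subject": s, "lateralization_index_pct": li})
        print(f"sub-{s:02d}: LI = {li:+.1f}%")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "lateralization.csv", index=False)
    print(f"group mean LI = {df['lateralization_index_pct'].mean():+.1f}% "
          f"(positive: ipsilateral alpha increase, as expected under "
          f"covert spatial attention)")


if __name__ == "__main__":
    sys.exit(main())
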