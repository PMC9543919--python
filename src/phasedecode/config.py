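"""Run configuration: every tunable of the pipeline in one place.

Defaults reproduce the full-scale analysis settings (18 phase bins, groups of
5 observations per pseudo-observation, 100 repetitions for the overall
decoder / 20 per phase bin, 100 circular-shift permutations, 1,024 paired
and 1,000 cluster permutations, analysis window 0.4-1.0 s, 4-30 Hz and
4-20 Hz frequency grids).  A reduced-cost mode for tests and desk-scale
experiments is just another RunConfig with smaller resampling counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    # phase binning & cosine fit
    n_bins: int = 18
    # pseudo-observation grouping
    group_size: int = 5
    # decoding
    n_repetitions_overall: int = 100     # overall (single-bin) decoding
    n_repetitions_per_bin: int = 20      # within each phase bin
    n_folds: int = 5
    n_folds_eye: int = 10                # eye-control loop
    variance_kept: float = 0.99
    svm_c: float = 1.0
    # permutations
    n_perm_first: int = 100              # circular-shift / RT-shuffle null
    n_perm_group: int = 1000             # cluster permutations
    n_perm_paired: int = 1024            # paired group permutation test
    alpha: float = 0.05
    # analysis windows / grids
    decode_window: tuple[float, float] = (0.4, 1.0)
    freqs_sensor: tuple[float, ...] = tuple(float(f) for f in range(4, 31))
    freqs_parcel: tuple[float, ...] = tuple(float(f) for f in range(4, 21))
    # phase estimation
    phase_step: float = 0.005
    window_cycles: int = 2
    pad_to: float = 4.0
    # behavioral binning
    behavior_window_deg: float = 90.0
    # bookkeeping
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = json.load(f)
        raw["decode_window"] = tuple(raw["decode_window"])
        raw["freqs_sensor"] = tuple(raw["freqs_sensor"])
        raw["freqs_parcel"] = tuple(raw["freqs_parcel"])
        return cls(**raw)
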