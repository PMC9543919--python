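"""phasedecode: phase-dependent decodability of a binary visual stimulus
class from multichannel neural recordings.

The package implements, end to end, the analysis that asks whether the
strength of a stimulus representation in the brain waxes and wanes with
the phase of ongoing theta/alpha oscillations: instantaneous phase
estimation from a phase-providing channel, phase-binned multivariate
decoding with pseudo-observation averaging, a cosine-fit modulation-depth
statistic with a circular-shift permutation null, group-level cluster
permutation inference, phasic modulation of reaction times, and a
gaze-leakage control -- plus a synthetic-data generator with matching
ground truth so every stage can be validated without any recording.
"""

from .config import RunConfig
from .containers import (
    EpochSet,
    SchemaError,
    ShapeError,
    read_epochs,
    select_trials,
    write_epochs,
)
from .simulate import SimConfig, SimTruth, simulate_cohort, simulate_subject

__all__ = [
    "RunConfig",
    "EpochSet",
    "SchemaError",
    "ShapeError",
    "read_epochs",
    "write_epochs",
    "select_trials",
    "SimConfig",
    "SimTruth",
    "simulate_subject",
    "simulate_cohort",
]

__version__ = "0.1.0"
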