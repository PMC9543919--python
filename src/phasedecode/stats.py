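"""Group-level inference: paired sign-flip permutation tests, cluster-based
permutation across frequencies with max-statistic correction over parcels,
and post-hoc Bayes factors.

Permutation p values use the inclusive convention p = (b + 1) / (n + 1)
(the identity permutation counts), so p is never 0.  Tests are one-sided:
the modulation amplitude is nonnegative by construction and the
alternative is always "observed larger than reference/null".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "GroupSample",
    "ClusterResult",
    "paired_permutation_test",
    "cluster_test_over_freqs",
    "correct_over_parcels",
    "bayes_factor_posthoc",
]


@dataclass
class GroupSample:
    """Per-subject observed statistics and first-level null draws at one
    frequency."""

    observed: np.ndarray             # (n_subjects,)
    first_level_null: np.ndarray     # (n_subjects, n_perm1)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.first_level_null = np.asarray(self.first_level_null, dtype=float)
        if self.observed.size < 2:
            raise ValueError("need at least 2 subjects")
        if self.first_level_null.shape[0] != self.observed.size:
            raise ValueError("first-level null / observed subject mismatch")
        if self.first_level_null.shape[1] < 2:
            raise ValueError("need at least 2 first-level permutations")


@dataclass
class Cluster:
    freq_indices: np.ndarray
    stat_sum: float
    p_value: float


@dataclass
class ClusterResult:
    """Clusters of contiguous supra-threshold frequencies."""

    clusters: list[Cluster]
    threshold_per_freq: np.ndarray
    group_stat: np.ndarray           # subject-mean statistic per frequency
    null_max_sums: np.ndarray        # (n_perm,) max-cluster sums under the null

    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def paired_permutation_test(
    observed: Sequence[float],
    reference: Sequence[float],
    n_perm: int = 1024,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided sign-flip permutation test on per-subject differences.

    For n <= 10 subjects all 2^n sign patterns are enumerated exactly
    (deterministic, no RNG); otherwise ``n_perm`` random sign flips are
    drawn and the inclusive convention applies."""
    d = np.asarray(observed, dtype=float) - np.asarray(reference, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    stat = d.mean()
    if n <= 10:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
        )
        perm_stats = signs @ d / n
        return float(np.mean(perm_stats >= stat - 1e-12))
    rng = np.random.default_rng() if rng is None else rng
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_stats = signs @ d / n
    b = int(np.sum(perm_stats >= stat - 1e-12))
    return float((b + 1) / (n_perm + 1))


def cluster_test_over_freqs(
    samples: Sequence[GroupSample],
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Second-level permutation test with clustering across frequencies.

    Per null draw and frequency, one sample per subject is taken from that
    subject's first-level (circular-shift) null and averaged over subjects.
    The per-frequency threshold is the (1-alpha) quantile of these draws;
    contiguous supra-threshold frequencies are clustered and their group
    statistics summed.  Cluster p values compare each observed sum against
    the distribution of maximum null-cluster sums."""
    rng = np.random.default_rng() if rng is None else rng
    n_freq = len(samples)
    if n_freq == 0:
        raise ValueError("no frequencies")
    n_subj = samples[0].observed.size
    n_perm1 = samples[0].first_level_null.shape[1]
    for s in samples:
        if s.observed.size != n_subj or s.first_level_null.shape[1] != n_perm1:
            raise ValueError("frequencies disagree in subjects or permutations")

    group_stat = np.array([s.observed.mean() for s in samples])
    # second-level null: (n_perm, n_freq)
    draws = rng.integers(0, n_perm1, size=(n_perm, n_freq, n_subj))
    null = np.empty((n_perm, n_freq))
    for f, s in enumerate(samples):
        null[:, f] = s.first_level_null[np.arange(n_subj)[None, :], draws[:, f, :]].mean(
            axis=1
        )
    thresholds = np.quantile(null, 1.0 - alpha, axis=0)

    def cluster_sums(stat_vec):
        above = stat_vec > thresholds
        sums, spans = [], []
        start = None
        for i in range(n_freq + 1):
            if i < n_freq and above[i]:
                if start is None:
                    start = i
            elif start is not None:
                idx = np.arange(start, i)
                spans.append(idx)
                sums.append(float(stat_vec[idx].sum()))
                start = None
        return spans, sums

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        _, sums = cluster_sums(null[p])
        if sums:
            null_max[p] = max(sums)

    spans, sums = cluster_sums(group_stat)
    clusters = [
        Cluster(
            freq_indices=idx,
            stat_sum=s,
            p_value=float((np.sum(null_max >= s - 1e-12) + 1) / (n_perm + 1)),
        )
        for idx, s in zip(spans, sums)
    ]
    return ClusterResult(
        clusters=clusters, threshold_per_freq=thresholds,
        group_stat=group_stat, null_max_sums=null_max,
    )


def correct_over_parcels(
    results: Sequence[ClusterResult],
) -> list[list[float]]:
    """Max-statistic correction over parcels (clusters formed only over
    frequencies).  Per null draw the maximum cluster sum across parcels is
    pooled; each observed cluster sum is compared against that pooled
    distribution.  Returns corrected p values per parcel, ordered like the
    input clusters."""
    if not results:
        raise ValueError("no parcel results")
    n_draws = {r.null_max_sums.size for r in results}
    if len(n_draws) != 1:
        raise ValueError("parcels disagree in null-draw count")
    pooled = np.max(np.stack([r.null_max_sums for r in results]), axis=0)
    n_perm = pooled.size
    corrected = []
    for r in results:
        corrected.append(
            [
                float((np.sum(pooled >= c.stat_sum - 1e-12) + 1) / (n_perm + 1))
                for c in r.clusters
            ]
        )
    return corrected


def bayes_factor_posthoc(
    observed: Sequence[float],
    reference: Sequence[float],
    scale: float = 0.7071067811865476,
) -> float:
    """JZS one-sample Bayes factor (BF10) on paired differences.

    The effect-size prior is a Cauchy with the given ``scale`` (default
    sqrt(2)/2, the conventional "medium" prior); H0 is a point null.
    Computed by quadrature of the Rouder-style integral over the prior on
    the variance ratio g."""
    d = np.asarray(observed, dtype=float) - np.asarray(reference, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t = d.mean() / (sd / np.sqrt(n))
    nu = n - 1
    r = scale

    def integrand(g):
        return (
            (1.0 + n * g * r**2) ** -0.5
            * (1.0 + t**2 / ((1.0 + n * g * r**2) * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    numerator, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    denominator = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return float(numerator / denominator)
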