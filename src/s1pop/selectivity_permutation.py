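"""Tuning exclusivity between stimulus pairs via a reshuffled-pair null.

In a PI scatter of two stimuli, a cell on the diagonal PI_a = PI_b (the
"equally tuned" line) responds equivalently to both; distance from the
diagonal measures response exclusivity.  The observed mean perpendicular
distance is standardized against a permutation null built by reshuffling the
pairing of PIs across cells — each cell keeps its own PI values, but the
association between the two stimuli is destroyed.  The resulting z-distance
is positive when tuning is more mutually exclusive than chance (cells prefer
one stimulus or the other) and negative when it is more co-varying (cells
respond to both alike).  Significance is an empirical two-sided p with the
+1 finite-sample correction, Bonferroni-adjusted over tested pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .errors import ContractError, DegenerateNullError

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null of the mean diagonal distance."""

    mean: float
    sd: float
    samples: np.ndarray
    mode: str
    n_reshuffles: int
    seed: int | None


@dataclass(frozen=True)
class SelectivityResult:
    feature_pair: tuple[str, str]
    observed_mean_distance: float
    null_mean: float
    null_sd: float
    z_distance: float
    p_empirical: float
    n_reshuffles: int
    seed: int | None
    n_cells: int
    p_adjusted: float | None = None


def diagonal_distance(pi_a, pi_b) -> np.ndarray | float:
    """Perpendicular distance |PI_a - PI_b| / sqrt(2) to the diagonal.

    Inputs must lie in [0, 1] (they are preference indexes).
    """
    a = np.asarray(pi_a, dtype=float)
    b = np.asarray(pi_b, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ContractError("PI values must lie in [0, 1]")
    d = np.abs(a - b) / SQRT2
    return float(d) if d.ndim == 0 else d


def exhaustive_null(pi_a, pi_b):
    """Null over all n! pairings of pi_b to pi_a (small n only).

    The brute-force counterpart of :func:`reshuffle_null`: every permutation
    of ``pi_b`` contributes one mean diagonal distance.  Returns
    ``(null_mean, null_sd, samples)`` with the sample s.d. (ddof=1).
    """
    a = np.asarray(pi_a, dtype=float)
    b = np.asarray(pi_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ContractError("need matched 1-D vectors with n >= 2")
    if a.size > 8:
        raise ContractError("exhaustive enumeration is limited to n <= 8")
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ContractError("PI values must lie in [0, 1]")
    perms = np.array(list(permutations(b)))
    samples = (np.abs(a[None, :] - perms) / SQRT2).mean(axis=1)
    return float(samples.mean()), float(samples.std(ddof=1)), samples


def reshuffle_null(
    pi_a,
    pi_b,
    n_reshuffles: int = 10_000,
    seed: int | None = None,
    mode: str = "means",
) -> NullDistribution:
    """Monte-Carlo reshuffled-pair null of the mean diagonal distance.

    Each reshuffle permutes ``pi_b`` across cells while ``pi_a`` stays
    fixed; both marginal PI distributions are preserved, all association is
    destroyed.  With ``mode="means"`` (default) the null distribution is over
    per-reshuffle mean distances, so the z-distance measures displacement of
    the observed mean; ``mode="pooled"`` takes the null over the individual
    reshuffled pair distances instead.
    """
    a = np.asarray(pi_a, dtype=float)
    b = np.asarray(pi_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("pi_a and pi_b must be matched 1-D vectors")
    if a.size < 3:
        raise ContractError("need at least 3 cells")
    if n_reshuffles < 100:
        raise ContractError("n_reshuffles must be >= 100")
    if mode not in ("means", "pooled"):
        raise ContractError("mode must be 'means' or 'pooled'")
    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.tile(b, (n_reshuffles, 1)), axis=1)
    dists = np.abs(a[None, :] - shuffled) / SQRT2
    samples = dists.mean(axis=1) if mode == "means" else dists.ravel()
    sd = float(samples.std(ddof=1))
    # rounding can leave a ~1e-17 spread on an exactly degenerate null
    if sd <= 1e-12 * max(1.0, abs(float(samples.mean()))):
        raise DegenerateNullError(
            "all reshuffles give identical distances; z undefined"
        )
    return NullDistribution(
        mean=float(samples.mean()),
        sd=sd,
        samples=samples,
        mode=mode,
        n_reshuffles=n_reshuffles,
        seed=seed,
    )


def selectivity_z_test(
    pi_a,
    pi_b,
    n_reshuffles: int = 10_000,
    seed: int | None = 0,
    mode: str = "means",
    feature_pair: tuple[str, str] = ("a", "b"),
) -> SelectivityResult:
    """z-distance of the observed mean diagonal distance against the null.

    z = (observed - null_mean) / null_sd; the empirical two-sided p is
    (r + 1) / (R + 1) with r the number of null samples at least as far from
    the null mean as the observation, so p >= 1 / (n_reshuffles + 1).
    """
    a = np.asarray(pi_a, dtype=float)
    observed = float(np.mean(diagonal_distance(pi_a, pi_b)))
    null = reshuffle_null(pi_a, pi_b, n_reshuffles=n_reshuffles, seed=seed, mode=mode)
    z = (observed - null.mean) / null.sd
    r = int(np.sum(np.abs(null.samples - null.mean) >= abs(observed - null.mean)))
    p = (r + 1) / (len(null.samples) + 1)
    return SelectivityResult(
        feature_pair=tuple(feature_pair),
        observed_mean_distance=observed,
        null_mean=null.mean,
        null_sd=null.sd,
        z_distance=float(z),
        p_empirical=float(p),
        n_reshuffles=n_reshuffles,
        seed=seed,
        n_cells=int(a.size),
    )


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p_adj = min(1, p * m)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < 1:
        raise ContractError("m must be >= 1")
    return np.minimum(1.0, p * m)


def selectivity_tests(
    pi: np.ndarray,
    stimulus_labels,
    pairs,
    n_reshuffles: int = 10_000,
    seed: int | None = 0,
    mode: str = "means",
) -> list[SelectivityResult]:
    """Run the z-test for several stimulus pairs and Bonferroni-adjust.

    ``pairs`` is an iterable of (label_a, label_b); the PI matrix columns are
    looked up by label.  Pass only non-broadly-tuned responders: cells tuned
    to everything sit near the diagonal for any pair by construction.
    """
    labels = list(stimulus_labels)
    results = []
    for pair_seed_offset, (la, lb) in enumerate(pairs):
        ja, jb = labels.index(la), labels.index(lb)
        pair_seed = None if seed is None else seed + pair_seed_offset
        results.append(
            selectivity_z_test(
                pi[:, ja],
                pi[:, jb],
                n_reshuffles=n_reshuffles,
                seed=pair_seed,
                mode=mode,
                feature_pair=(la, lb),
            )
        )
    adjusted = bonferroni_adjust([r.p_empirical for r in results], m=len(results))
    return [
        SelectivityResult(**{**r.__dict__, "p_adjusted": float(p_adj)})
        for r, p_adj in zip(results, adjusted)
    ]
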