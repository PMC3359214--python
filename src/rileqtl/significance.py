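"""Permutation thresholds, genome-wide p-values and q-value FDR.

The genome-wide LOD threshold is estimated by phenotype permutation: trait
values are shuffled across lines while the genotypes stay fixed, the genome
scan is repeated, and the maximum LOD is recorded. A random sample of traits
(default 500) supplies per-trait 95th-percentile thresholds whose upper
envelope is taken as the genome-wide threshold. Trait-level multiple testing
uses empirical genome-wide p-values converted to Storey q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import GenotypeProbabilities, _lod_from_r2
from .types import ExpressionMatrix, RileqtlError

__all__ = [
    "PermutationNull",
    "ThresholdEstimate",
    "permute_max_lods",
    "genomewide_threshold",
    "trait_pvalues",
    "qvalues",
    "fdr_cutoff",
]


@dataclass(frozen=True)
class PermutationNull:
    trait: str
    max_lods: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.max_lods) != self.n_perm:
            raise RileqtlError("null vector length != permutation count")


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float
    per_trait: np.ndarray  # 95% threshold per sampled trait
    sampled_traits: list[str]
    nulls: dict[str, PermutationNull] = field(repr=False, default_factory=dict)
    fdr_cutoffs: dict[float, float] = field(default_factory=dict)


def _max_lod_perms(
    X: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized max-LOD permutation null for one complete-case trait.

    Uses the simple-regression identity RSS1 = RSS0 (1 - r^2): all
    permutations reduce to one (n_perm x n) @ (n x p) product.
    """
    n = len(y)
    Xc = X - X.mean(axis=0)
    sx = np.einsum("ij,ij->j", Xc, Xc)
    ok = sx > 0
    yc = y - y.mean()
    sy = float(yc @ yc)
    if sy <= 0:
        return np.zeros(n_perm)
    Y = np.empty((n_perm, n))
    for b in range(n_perm):
        Y[b] = yc[rng.permutation(n)]
    num = Y @ Xc[:, ok]
    r2 = num**2 / (sx[ok][None, :] * sy)
    return _lod_from_r2(r2, n).max(axis=1)


def permute_max_lods(
    probs: GenotypeProbabilities,
    trait: np.ndarray,
    n_perm: int,
    seed: int,
    trait_id: str = "",
) -> PermutationNull:
    """Phenotype-permutation null of the genome-wide maximum LOD."""
    if n_perm < 100:
        raise RileqtlError("need >= 100 permutations")
    rng = np.random.default_rng(seed)
    y = np.asarray(trait, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    X = probs.p_alt[keep]
    maxes = _max_lod_perms(X, y, n_perm, rng)
    return PermutationNull(trait_id, maxes, n_perm, seed)


def genomewide_threshold(
    expr: ExpressionMatrix,
    probs: GenotypeProbabilities,
    n_traits: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
    percentile: float = 95.0,
    method: str = "percentile",
) -> ThresholdEstimate:
    """Estimate the genome-wide LOD threshold from a random trait sample.

    Per sampled trait the ``percentile`` of its permutation max-LOD null is
    taken; the genome-wide threshold is the same percentile of those
    per-trait thresholds (``method='percentile'``, default) or the normal
    95% upper bound mean + 1.645 sd (``method='normal'``).
    """
    rng = np.random.default_rng(seed)
    trait_ids = expr.trait_ids
    if n_traits > len(trait_ids):
        import logging

        logging.getLogger("rileqtl").warning(
            "only %d traits available (requested %d)", len(trait_ids), n_traits
        )
        n_traits = len(trait_ids)
    sampled = [trait_ids[i] for i in rng.choice(len(trait_ids), n_traits, replace=False)]
    per_trait = np.empty(n_traits)
    nulls: dict[str, PermutationNull] = {}
    for i, t in enumerate(sampled):
        null = permute_max_lods(
            probs, expr.trait(t), n_perm, seed=int(rng.integers(2**31)), trait_id=t
        )
        nulls[t] = null
        per_trait[i] = np.percentile(null.max_lods, percentile)
    if method == "percentile":
        thr = float(np.percentile(per_trait, percentile))
    elif method == "normal":
        thr = float(per_trait.mean() + 1.645 * per_trait.std(ddof=1))
    else:
        raise RileqtlError(f"unknown threshold method {method!r}")
    return ThresholdEstimate(thr, per_trait, sampled, nulls)


def trait_pvalues(observed_max: np.ndarray, null_pool: np.ndarray) -> np.ndarray:
    """Empirical genome-wide p per trait: (1 + #{null >= obs}) / (1 + n_null)."""
    null_pool = np.sort(np.asarray(null_pool, dtype=float))
    obs = np.asarray(observed_max, dtype=float)
    n = len(null_pool)
    ge = n - np.searchsorted(null_pool, obs, side="left")
    return (1.0 + ge) / (1.0 + n)


def qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed lambda (no spline smoothing).

    pi0 = min(1, #{p > lam} / ((1 - lam) m)); q_(i) = min_{j>=i} pi0 m p_(j)/j.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise RileqtlError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise RileqtlError("p-values outside [0, 1]")
    m = len(p)
    pi0 = min(1.0, (p > lam).sum() / ((1.0 - lam) * m)) if m else 1.0
    pi0 = max(pi0, 1.0 / m)  # guard against degenerate zero
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_cutoff(p: np.ndarray, level: float = 0.05, lam: float = 0.5) -> float:
    """Largest p-value whose q-value stays at or below ``level`` (0 if none)."""
    p = np.asarray(p, dtype=float)
    q = qvalues(p, lam=lam)
    ok = q <= level
    return float(p[ok].max()) if ok.any() else 0.0
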