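"""Genome architecture of the eQTL landscape.

Local/distant classification (1 Mb peak-to-gene rule), the 1 Mb bin grid
with short-terminal-bin merging, the trans-hotspot permutation test, eQTL
density regressions against SNP/gene density, and cross-population sharing
of local eQTLs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    DISTANT,
    LOCAL,
    UNCLASSIFIED,
    EqtlRecord,
    GeneAnnotation,
    RileqtlError,
)


def classify_eqtls(
    records: Sequence[EqtlRecord],
    annot: GeneAnnotation,
    cutoff_bp: int = 1_000_000,
) -> list[EqtlRecord]:
    """Classify each record local/distant by peak-to-gene distance.

    Local iff the peak lies on the gene's chromosome within ``cutoff_bp`` of
    its position; distant otherwise; unclassified if the trait has no
    annotation. Records are modified in place and returned.
    """
    if cutoff_bp <= 0:
        raise RileqtlError("cutoff must be > 0")
    for rec in records:
        pos = annot.get(rec.trait)
        if pos is None:
            rec.classification = UNCLASSIFIED
            continue
        chrom, bp = pos
        if chrom == rec.chrom and abs(rec.peak_bp - bp) <= cutoff_bp:
            rec.classification = LOCAL
        else:
            rec.classification = DISTANT
    return list(records)


@dataclass(frozen=True)
class BinGrid:
    """1-based inclusive physical bins tiling each chromosome."""

    bins: pd.DataFrame  # columns chrom, start, end, index 0..B-1

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_of(self, chrom: str, bp: int) -> int:
        sub = self.bins[self.bins["chrom"] == chrom]
        if sub.empty:
            raise RileqtlError(f"no bins for chromosome {chrom!r}")
        hit = sub[(sub["start"] <= bp) & (bp <= sub["end"])]
        if hit.empty:
            # peaks beyond the recorded chromosome length fall in the last bin
            return int(sub.index[-1])
        return int(hit.index[0])


def make_bins(
    chrom_lengths: Mapping[str, int],
    size: int = 1_000_000,
    merge_below: int = 500_000,
) -> BinGrid:
    """Tile each chromosome with ``size``-bp bins.

    A final remainder shorter than ``merge_below`` is merged into the
    previous bin (yielding one long terminal bin); otherwise it stands as
    its own short bin. A chromosome shorter than ``size`` forms one bin.
    """
    if not (size > merge_below > 0):
        raise RileqtlError("need size > merge_below > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_full, rem = divmod(int(length), size)
        if n_full == 0:
            rows.append((str(chrom), 1, int(length)))
            continue
        ends = [i * size for i in range(1, n_full + 1)]
        if rem:
            if rem < merge_below:
                ends[-1] = int(length)
            else:
                ends.append(int(length))
        start = 1
        for e in ends:
            rows.append((str(chrom), start, e))
            start = e + 1
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return BinGrid(bins)


@dataclass(frozen=True)
class HotspotResult:
    table: pd.DataFrame  # per bin: chrom, start, end, count, hotspot
    threshold: int
    n_perm: int
    seed: int

    @property
    def hotspot_bins(self) -> pd.DataFrame:
        return self.table[self.table["hotspot"]]


def _bin_counts(records: Sequence[EqtlRecord], grid: BinGrid) -> np.ndarray:
    counts = np.zeros(grid.n_bins, dtype=int)
    for rec in records:
        counts[grid.bin_of(rec.chrom, rec.peak_bp)] += 1
    return counts


def hotspot_test(
    distant: Sequence[EqtlRecord],
    grid: BinGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    stratify_by_chrom: bool = False,
) -> HotspotResult:
    """Permutation test for trans-eQTL hotspots.

    Observed counts tally distant-eQTL peaks per bin. Under the null every
    peak is reassigned to a bin uniformly at random (optionally stratified
    within its chromosome); the threshold is the (1 - alpha) quantile of the
    per-permutation maximum bin count, and a bin is a hotspot iff its
    observed count exceeds it.
    """
    if n_perm < 200:
        raise RileqtlError("need >= 200 permutations")
    bad = [r.trait for r in distant if r.classification != DISTANT]
    if bad:
        raise RileqtlError(f"non-distant records passed to hotspot_test: {bad[:3]}")
    table = grid.bins.copy()
    if len(distant) == 0:
        table["count"] = 0
        table["hotspot"] = False
        return HotspotResult(table, threshold=0, n_perm=n_perm, seed=seed)

    counts = _bin_counts(distant, grid)
    rng = np.random.default_rng(seed)
    n_peaks = len(distant)
    B = grid.n_bins
    maxes = np.empty(n_perm, dtype=int)
    if not stratify_by_chrom:
        for b in range(n_perm):
            assign = rng.integers(0, B, size=n_peaks)
            maxes[b] = np.bincount(assign, minlength=B).max()
    else:
        chrom_groups = table.groupby("chrom").indices
        per_chrom = [
            (np.array(idx), sum(1 for r in distant if str(r.chrom) == chrom))
            for chrom, idx in chrom_groups.items()
        ]
        for b in range(n_perm):
            tally = np.zeros(B, dtype=int)
            for idx, n_c in per_chrom:
                if n_c:
                    assign = idx[rng.integers(0, len(idx), size=n_c)]
                    tally += np.bincount(assign, minlength=B)
            maxes[b] = tally.max()
    threshold = int(np.quantile(maxes, 1.0 - alpha, method="higher"))
    table["count"] = counts
    table["hotspot"] = counts > threshold
    return HotspotResult(table, threshold=threshold, n_perm=n_perm, seed=seed)


def density_regression(
    counts_per_bin: np.ndarray, covariate_per_bin: np.ndarray
) -> dict[str, float]:
    """OLS of per-bin eQTL counts on a per-bin covariate (SNP or gene density)."""
    y = np.asarray(counts_per_bin, dtype=float)
    x = np.asarray(covariate_per_bin, dtype=float)
    if len(y) != len(x):
        raise RileqtlError("count and covariate vectors differ in length")
    if np.ptp(x) == 0:
        raise RileqtlError("zero-variance covariate")
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "rsq": 0.0, "p": 1.0}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "rsq": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


def compare_populations(
    a: Sequence[EqtlRecord], b: Sequence[EqtlRecord]
) -> dict[str, object]:
    """Shared local eQTLs between two populations.

    A trait is shared-local when both populations hold a local eQTL for it
    whose physical support intervals overlap on the same chromosome.
    Reports the shared trait list, the share of pairs with concordant
    additive-effect sign, and Pearson/Spearman correlations of the effects.
    """
    local_a = {r.trait: r for r in a if r.classification == LOCAL}
    local_b = {r.trait: r for r in b if r.classification == LOCAL}
    shared, add_a, add_b = [], [], []
    for trait in sorted(set(local_a) & set(local_b)):
        ra, rb = local_a[trait], local_b[trait]
        if ra.chrom != rb.chrom:
            continue
        if ra.inf_bp <= rb.sup_bp and rb.inf_bp <= ra.sup_bp:
            shared.append(trait)
            add_a.append(ra.add)
            add_b.append(rb.add)
    if not shared:
        return {
            "shared_traits": [],
            "n_shared": 0,
            "concordance": np.nan,
            "pearson_r": np.nan,
            "spearman_rho": np.nan,
        }
    add_a = np.array(add_a)
    add_b = np.array(add_b)
    concord = float(np.mean(np.sign(add_a) == np.sign(add_b)))
    if len(shared) >= 2 and np.ptp(add_a) > 0 and np.ptp(add_b) > 0:
        pearson = float(stats.pearsonr(add_a, add_b).statistic)
        spearman = float(stats.spearmanr(add_a, add_b).statistic)
    else:
        pearson = spearman = np.nan
    return {
        "shared_traits": shared,
        "n_shared": len(shared),
        "concordance": concord,
        "pearson_r": pearson,
        "spearman_rho": spearman,
    }
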