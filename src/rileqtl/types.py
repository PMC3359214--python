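"""Core domain types for RIL eQTL mapping.

The containers here are deliberately thin wrappers around pandas/numpy
objects: a genetic map (marker grid in cM and bp), a line x marker genotype
matrix, a trait x line expression matrix, gene physical positions, and the
record describing one mapped eQTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Genotype codes: biallelic RILs carry either the Col (reference) or the
# alternate parental allele; residual heterozygosity is not modelled.
COL = 0
ALT = 1
MISSING = -1

#: file alphabet <-> in-memory codes
GENO_SYMBOLS = {"A": COL, "B": ALT, "-": MISSING}
GENO_CODES = {v: k for k, v in GENO_SYMBOLS.items()}


class RileqtlError(ValueError):
    """Base class for dialect/validation errors raised by this package."""


@dataclass(frozen=True)
class GeneticMap:
    """Marker grid: per-marker chromosome, genetic (cM) and physical (bp) position.

    ``markers`` is a DataFrame indexed by marker id with columns
    ``chrom`` (str), ``cm`` (float, centiMorgan) and ``bp`` (int, 1-based).
    ``chrom_lengths`` maps chromosome id to its physical length in bp.
    """

    markers: pd.DataFrame
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        m = self.markers
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()][0]
            raise RileqtlError(f"duplicated marker id: {dup!r}")
        for chrom, sub in m.groupby("chrom", sort=False):
            if (np.diff(sub["cm"].to_numpy()) < 0).any():
                raise RileqtlError(f"non-monotone cM positions on chromosome {chrom}")
            if (np.diff(sub["bp"].to_numpy()) < 0).any():
                raise RileqtlError(f"non-monotone bp positions on chromosome {chrom}")
        if (m["cm"] < 0).any():
            raise RileqtlError("negative cM position")
        if (m["bp"] < 1).any():
            raise RileqtlError("bp positions must be >= 1")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]


@dataclass(frozen=True)
class RilGenotypes:
    """Line x marker genotype calls, codes in {COL, ALT, MISSING}."""

    line_ids: list[str]
    calls: np.ndarray  # (n_lines, n_markers) int8
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.line_ids), self.gmap.n_markers):
            raise RileqtlError(
                f"genotype matrix shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {self.gmap.n_markers} markers"
            )
        bad = ~np.isin(self.calls, (COL, ALT, MISSING))
        if bad.any():
            raise RileqtlError("unknown genotype symbol in call matrix")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.line_ids, columns=self.gmap.markers.index
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Traits x lines matrix of normalized log2 intensities (NaN = missing)."""

    values: pd.DataFrame  # index = trait ids, columns = line ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise RileqtlError(f"duplicate trait id: {dup!r}")

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_traits(self) -> int:
        return len(self.values.index)

    def trait(self, trait_id: str) -> np.ndarray:
        return self.values.loc[trait_id].to_numpy(dtype=float)

    def aligned_to(self, line_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict/reorder columns to ``line_ids`` (must be a superset check)."""
        missing = set(self.values.columns) - set(line_ids)
        if missing:
            raise RileqtlError(
                f"expression lines not present in genotypes: {sorted(missing)[:3]}"
            )
        keep = [l for l in line_ids if l in self.values.columns]
        return ExpressionMatrix(self.values[keep])


@dataclass(frozen=True)
class GeneAnnotation:
    """Physical position of each trait's gene: chrom, representative bp (1-based midpoint)."""

    positions: pd.DataFrame  # index = trait id; columns chrom, bp, strand

    def __post_init__(self) -> None:
        if self.positions.index.duplicated().any():
            dup = self.positions.index[self.positions.index.duplicated()][0]
            raise RileqtlError(f"trait annotated twice: {dup!r}")

    def get(self, trait_id: str) -> tuple[str, int] | None:
        if trait_id not in self.positions.index:
            return None
        row = self.positions.loc[trait_id]
        return str(row["chrom"]), int(row["bp"])


LOCAL = "local"
DISTANT = "distant"
UNCLASSIFIED = "unclassified"


@dataclass
class EqtlRecord:
    """One mapped eQTL.

    ``add`` is the additive effect signed Alt minus Col (log2 units): a
    negative value means the Col allele is up-regulated. ``rsq`` is the
    fraction of phenotypic variance explained. The support interval is the
    LOD-drop interval in both coordinate systems.
    """

    trait: str
    chrom: str
    peak_cm: float
    peak_bp: int
    inf_bp: int
    sup_bp: int
    inf_cm: float
    sup_cm: float
    lod: float
    add: float
    rsq: float
    classification: str = UNCLASSIFIED
    p: float = np.nan
    q: float = np.nan

    def __post_init__(self) -> None:
        if not (self.inf_bp <= self.peak_bp <= self.sup_bp):
            raise RileqtlError(
                f"{self.trait}: peak bp {self.peak_bp} outside interval "
                f"[{self.inf_bp}, {self.sup_bp}]"
            )
        if np.isfinite(self.peak_cm) and not (self.inf_cm <= self.peak_cm <= self.sup_cm):
            raise RileqtlError(f"{self.trait}: peak cM outside support interval")
        if self.lod < 0:
            raise RileqtlError("negative LOD")
        if np.isfinite(self.rsq) and not (0.0 <= self.rsq <= 1.0):
            raise RileqtlError("R^2 outside [0, 1]")
        for val in (self.p, self.q):
            if np.isfinite(val) and not (0.0 <= val <= 1.0):
                raise RileqtlError("p/q outside [0, 1]")
        if self.classification not in (LOCAL, DISTANT, UNCLASSIFIED):
            raise RileqtlError(f"bad classification {self.classification!r}")


def records_to_frame(records: Iterable[EqtlRecord]) -> pd.DataFrame:
    cols = [f.name for f in dc_fields(EqtlRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


@dataclass
class RunConfig:
    """Tunable parameters of the pipeline.

    step            pseudomarker spacing on the scan grid (cM)
    exclusion_cm    mask half-width around accepted peaks, reused as the CIM
                    cofactor drop window (cM)
    lod_drop        LOD fall-off defining support intervals
    local_cutoff_bp peak-to-gene distance separating local from distant eQTLs
    n_perm          permutations per sampled trait for thresholds
    n_threshold_traits  number of traits sampled for the genome-wide threshold
    fdr             target false discovery rate
    loess_span/loess_iters  dye-bias smoother parameters
    trim_quantiles  variance-trimming quantiles of the paired t-test
    candidate_k     hidden-factor counts screened by select_k
    allele_band     P(ALT) band treated as ambiguous for allele-group means
    """

    step: float = 2.0
    exclusion_cm: float = 15.0
    lod_drop: float = 1.5
    local_cutoff_bp: int = 1_000_000
    n_perm: int = 1000
    n_threshold_traits: int = 500
    fdr: float = 0.05
    seed: int = 0
    loess_span: float = 0.3
    loess_iters: int = 4
    trim_quantiles: tuple[float, float] = (0.025, 0.975)
    candidate_k: tuple[int, ...] = (0, 5, 10, 20, 30)
    allele_band: tuple[float, float] = (0.45, 0.55)
    lod_cap: float = 50.0
    bin_size: int = 1_000_000
    merge_below: int = 500_000

    def __post_init__(self) -> None:
        if self.step <= 0 or self.exclusion_cm <= 0 or self.lod_drop <= 0:
            raise RileqtlError("window/step parameters must be > 0")
        if not (0.0 < self.fdr < 1.0):
            raise RileqtlError("FDR level must lie in (0, 1)")
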