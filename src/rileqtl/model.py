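"""High-level modelling interface: build a model from a cross and an
expression matrix, fit it, and work with the results object.

    model = RilEqtlModel(gmap, genos, expr, annotation=annot)
    results = model.fit(seed=1)
    print(results.summary())
    results.records            # list[EqtlRecord]
    results.hotspots()         # trans-hotspot permutation test
    results.to_table("eqtls.tsv")

``fit`` runs the full pipeline: genotype probabilities on a pseudomarker
grid, permutation genome-wide threshold over a trait sample, per-trait
interval mapping, composite interval mapping with the IM peaks as
cofactors, peak selection with LOD-drop support intervals, additive-effect
and R^2 estimation, local/distant classification, and genome-wide p / q
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import architecture, io, significance
from .scan import (
    GenotypeProbabilities,
    Peak,
    genotype_probabilities,
    pick_qtls,
    qtl_effects,
    scan_cim,
    scan_im,
    support_interval,
)
from .types import (
    EqtlRecord,
    ExpressionMatrix,
    GeneAnnotation,
    GeneticMap,
    RileqtlError,
    RilGenotypes,
    RunConfig,
    records_to_frame,
)

log = logging.getLogger("rileqtl")


class RilEqtlModel:
    """eQTL mapping model for a biparental RIL population."""

    def __init__(
        self,
        gmap: GeneticMap,
        genotypes: RilGenotypes,
        expression: ExpressionMatrix,
        annotation: GeneAnnotation | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.gmap = gmap
        self.genotypes = genotypes
        self.expression = expression.aligned_to(genotypes.line_ids)
        if self.expression.values.shape[1] < 10:
            raise RileqtlError("need >= 10 lines shared between genotypes and expression")
        self.annotation = annotation
        self.config = config or RunConfig()
        self._probs: GenotypeProbabilities | None = None

    @classmethod
    def from_files(
        cls,
        cross_path: str,
        expression_path: str,
        annotation_path: str | None = None,
        annotation_format: str = "BED",
        config: RunConfig | None = None,
    ) -> "RilEqtlModel":
        gmap, genos = io.read_cross(cross_path)
        expr = io.read_expression(expression_path)
        annot = (
            io.read_gene_positions(annotation_path, annotation_format)
            if annotation_path
            else None
        )
        return cls(gmap, genos, expr, annot, config)

    @property
    def probabilities(self) -> GenotypeProbabilities:
        if self._probs is None:
            self._probs = genotype_probabilities(
                self.gmap, self.genotypes, step=self.config.step
            )
        return self._probs

    def fit(
        self,
        seed: int | None = None,
        threshold: float | None = None,
        use_cim: bool = True,
        n_perm: int | None = None,
        n_threshold_traits: int | None = None,
    ) -> "RilEqtlResults":
        """Run the mapping pipeline and return a results object.

        ``threshold`` can be supplied directly to skip the permutation stage
        (e.g. when reusing a precomputed estimate).
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        n_perm = cfg.n_perm if n_perm is None else n_perm
        n_thr = cfg.n_threshold_traits if n_threshold_traits is None else n_threshold_traits
        probs = self.probabilities
        expr = self.expression

        thr_est = None
        if threshold is None:
            log.info("estimating genome-wide threshold (seed=%d)", seed)
            thr_est = significance.genomewide_threshold(
                expr, probs, n_traits=n_thr, n_perm=n_perm, seed=seed
            )
            threshold = thr_est.threshold
        log.info("genome-wide LOD threshold: %.3f", threshold)

        null_pool = (
            np.concatenate([n.max_lods for n in thr_est.nulls.values()])
            if thr_est is not None
            else None
        )

        records: list[EqtlRecord] = []
        observed_max = np.empty(expr.n_traits)
        trait_rows: dict[str, list[int]] = {}
        for ti, trait_id in enumerate(expr.trait_ids):
            y = expr.trait(trait_id)
            im_curve = scan_im(probs, y, trait_id)
            peaks = pick_qtls(im_curve, threshold, cfg.exclusion_cm, cfg.lod_drop)
            curve = im_curve
            if use_cim and peaks:
                cim = scan_cim(probs, y, peaks, cfg.exclusion_cm, trait_id)
                peaks = pick_qtls(cim, threshold, cfg.exclusion_cm, cfg.lod_drop)
                # support intervals come from the IM profile: the composite
                # curve's active cofactor set changes along the chromosome,
                # which makes the LOD-drop region ill-defined on it
                refined = []
                for pk in peaks:
                    inf_cm, sup_cm, inf_bp, sup_bp = support_interval(
                        im_curve, pk.grid_index, cfg.lod_drop
                    )
                    refined.append(
                        Peak(pk.grid_index, pk.chrom, pk.cm, pk.bp, pk.lod,
                             inf_cm, sup_cm, inf_bp, sup_bp)
                    )
                peaks = refined
                curve = cim
            observed_max[ti] = curve.lod.max()
            if not peaks:
                continue
            effects, _ = qtl_effects(y, probs, peaks, cfg.allele_band)
            idxs = []
            for pk, eff in zip(peaks, effects):
                if eff.flagged:
                    log.warning("%s: empty allele group at %s:%.1f cM", trait_id,
                                pk.chrom, pk.cm)
                rec = EqtlRecord(
                    trait=trait_id,
                    chrom=pk.chrom,
                    peak_cm=pk.cm,
                    peak_bp=pk.bp,
                    inf_bp=pk.inf_bp,
                    sup_bp=pk.sup_bp,
                    inf_cm=pk.inf_cm,
                    sup_cm=pk.sup_cm,
                    lod=pk.lod,
                    add=eff.add,
                    rsq=eff.rsq,
                )
                idxs.append(len(records))
                records.append(rec)
            trait_rows[trait_id] = idxs

        # genome-wide p (vs pooled permutation null) and trait-level q
        if null_pool is not None and len(null_pool):
            p_trait = significance.trait_pvalues(observed_max, null_pool)
            q_trait = significance.qvalues(p_trait)
            for trait_id, p, q in zip(expr.trait_ids, p_trait, q_trait):
                for i in trait_rows.get(trait_id, ()):
                    records[i].p = float(p)
                    records[i].q = float(q)

        if self.annotation is not None:
            architecture.classify_eqtls(records, self.annotation, cfg.local_cutoff_bp)

        return RilEqtlResults(self, records, threshold, thr_est, seed)


@dataclass
class RilEqtlResults:
    """Fitted eQTL mapping results.

    Carries the mapped records, the genome-wide threshold (with the
    permutation estimate when computed in-fit), and helpers for hotspot
    detection, cross-population comparison and export.
    """

    model: RilEqtlModel
    records: list[EqtlRecord]
    threshold: float
    threshold_estimate: significance.ThresholdEstimate | None = None
    seed: int = 0

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    @property
    def n_eqtls(self) -> int:
        return len(self.records)

    def local_records(self) -> list[EqtlRecord]:
        return [r for r in self.records if r.classification == "local"]

    def distant_records(self) -> list[EqtlRecord]:
        return [r for r in self.records if r.classification == "distant"]

    def bin_grid(self) -> architecture.BinGrid:
        cfg = self.model.config
        return architecture.make_bins(
            self.model.gmap.chrom_lengths, cfg.bin_size, cfg.merge_below
        )

    def hotspots(
        self, n_perm: int = 1000, alpha: float = 0.05, seed: int | None = None
    ) -> architecture.HotspotResult:
        return architecture.hotspot_test(
            self.distant_records(),
            self.bin_grid(),
            n_perm=n_perm,
            alpha=alpha,
            seed=self.seed if seed is None else seed,
        )

    def compare(self, other: "RilEqtlResults") -> dict[str, object]:
        return architecture.compare_populations(self.records, other.records)

    def to_table(self, path: str) -> None:
        io.write_eqtl_table(self.records, path)

    def summary(self) -> str:
        df = self.frame
        n_local = int((df["classification"] == "local").sum()) if len(df) else 0
        n_distant = int((df["classification"] == "distant").sum()) if len(df) else 0
        n_traits_hit = df["trait"].nunique() if len(df) else 0
        lines = [
            "RIL eQTL mapping results",
            "=" * 42,
            f"lines:                {self.model.genotypes.n_lines}",
            f"markers:              {self.model.gmap.n_markers}"
            f" on {len(self.model.gmap.chromosomes)} chromosomes",
            f"traits scanned:       {self.model.expression.n_traits}",
            f"LOD threshold:        {self.threshold:.3f}",
            f"eQTLs mapped:         {self.n_eqtls}",
            f"  local (cis-like):   {n_local}",
            f"  distant (trans):    {n_distant}",
            f"traits with an eQTL:  {n_traits_hit}",
        ]
        if len(df):
            lines += [
                f"median LOD:           {df['lod'].median():.2f}",
                f"median |Add| (log2):  {df['add'].abs().median():.3f}",
                f"median R^2:           {df['rsq'].median():.3f}",
            ]
        return "\n".join(lines)
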