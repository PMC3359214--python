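"""GO over-representation of local-eQTL genes and the directional
allelic-effect test.

Under neutrality, the direction of local-eQTL effects inside a functional
gene set should follow the genome-wide ratio of parent-up-regulated alleles.
A significant excess of one direction within a set (tested one-sided against
that ratio) is a signature of concerted, potentially selected, regulatory
divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import LOCAL, EqtlRecord, RileqtlError


@dataclass(frozen=True)
class GoAnnotation:
    """Pre-propagated term -> gene sets with branch and optional names."""

    term_genes: Mapping[str, frozenset[str]]
    term_branch: Mapping[str, str]
    term_names: Mapping[str, str]

    def __post_init__(self) -> None:
        empty = [t for t, g in self.term_genes.items() if not g]
        if empty:
            raise RileqtlError(f"empty gene set for term(s) {empty[:3]}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, names: Mapping[str, str] | None = None
                   ) -> "GoAnnotation":
        """Build from a (gene, term, branch) long table as read by io.read_go_annotation."""
        genes = {t: frozenset(sub["gene"]) for t, sub in df.groupby("term")}
        branch = {t: sub["branch"].iloc[0] for t, sub in df.groupby("term")}
        return cls(genes, branch, dict(names or {}))

    def terms(self, branch: str | None = None, min_genes: int = 0) -> list[str]:
        out = []
        for t, g in self.term_genes.items():
            if branch is not None and self.term_branch.get(t) != branch:
                continue
            if len(g) > min_genes:
                out.append(t)
        return sorted(out)


def go_overrepresentation(
    local_genes: frozenset[str] | set[str],
    annot: GoAnnotation,
    genome_counts: Mapping[str, int],
    n_genome_genes: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of local-eQTL genes per term.

    Population = genome genes, successes = genes in the term (from
    ``genome_counts``), draws = local-eQTL genes. Bonferroni over the tested
    terms; significant iff p < alpha / #terms.
    """
    missing = [t for t in annot.term_genes if t not in genome_counts]
    if missing:
        raise RileqtlError(f"term(s) missing from genome counts: {missing[:3]}")
    draws = len(local_genes)
    rows = []
    terms = sorted(annot.term_genes)
    for term in terms:
        k = len(annot.term_genes[term] & set(local_genes))
        K = genome_counts[term]
        expected = draws * K / n_genome_genes
        p = float(stats.hypergeom.sf(k - 1, n_genome_genes, K, draws))
        rows.append((term, annot.term_names.get(term, term), K, k, expected, p))
    df = pd.DataFrame(
        rows, columns=["term", "name", "genome_genes", "observed", "expected", "p"]
    )
    cutoff = alpha / max(len(terms), 1)
    df["significant"] = df["p"] < cutoff
    return df.sort_values("p").reset_index(drop=True)


def directional_test(
    n_eqtls: int,
    n_col_up: int,
    genome_ratio: float,
    population: tuple[int, int] | None = None,
) -> float:
    """One-sided skew test of local-eQTL direction against the genome ratio.

    ``genome_ratio`` is Col:Alt (e.g. 1.6 for 1.6:1). By default the test is
    binomial with success probability ratio/(ratio+1) for a Col-up draw, one
    sided in the direction of the observed majority. With finite population
    counts (n_col_total, n_alt_total) supplied, the matching hypergeometric
    tail is used instead.
    """
    if not (0 <= n_col_up <= n_eqtls):
        raise RileqtlError("need 0 <= n_col_up <= n_eqtls")
    if genome_ratio <= 0:
        raise RileqtlError("ratio must be > 0")
    n_alt_up = n_eqtls - n_col_up
    col_majority = n_col_up >= n_alt_up
    if population is None:
        p_col = genome_ratio / (genome_ratio + 1.0)
        if col_majority:
            return float(stats.binom.sf(n_col_up - 1, n_eqtls, p_col))
        return float(stats.binom.sf(n_alt_up - 1, n_eqtls, 1.0 - p_col))
    n_col_total, n_alt_total = population
    total = n_col_total + n_alt_total
    if col_majority:
        return float(stats.hypergeom.sf(n_col_up - 1, total, n_col_total, n_eqtls))
    return float(stats.hypergeom.sf(n_alt_up - 1, total, n_alt_total, n_eqtls))


@dataclass(frozen=True)
class DirectionalTestResult:
    term: str
    name: str
    genes_in_term: int
    eqtls_observed: int
    col_up: int
    alt_up: int
    p: float

    def __post_init__(self) -> None:
        if self.col_up + self.alt_up != self.eqtls_observed:
            raise RileqtlError("direction counts do not sum to observed eQTLs")


def run_selection_scan(
    records: Sequence[EqtlRecord],
    annot: GoAnnotation,
    genome_counts: Mapping[str, int],
    n_genome_genes: int,
    min_genes: int = 20,
    overrep_alpha: float = 0.05,
    categories: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Full directional-selection screen over local eQTLs.

    Restricts to local eQTLs with signed additive effects, computes the
    genome-wide Col:Alt up-regulation ratio (negative Add = Col up), finds
    over-represented categories (``categories`` maps coarse category id to
    its member terms; default: every term is its own category), then tests
    every term with more than ``min_genes`` genes inside significant
    categories for directional skew. Returns the table sorted by p.
    """
    local = [r for r in records if r.classification == LOCAL and np.isfinite(r.add)]
    if not local:
        raise RileqtlError("no local eQTLs to analyse")
    signs = np.array([r.add for r in local])
    n_col = int((signs < 0).sum())
    n_alt = int((signs > 0).sum())
    if n_col + n_alt == 0:
        raise RileqtlError("no signed effects")
    ratio = n_col / max(n_alt, 1)
    local_genes = frozenset(r.trait for r in local)
    # direction per gene: a gene with several local eQTLs votes by its strongest
    direction: dict[str, float] = {}
    strongest: dict[str, float] = {}
    for r in local:
        if r.trait not in strongest or abs(r.add) > strongest[r.trait]:
            strongest[r.trait] = abs(r.add)
            direction[r.trait] = np.sign(r.add)

    overrep = go_overrepresentation(
        local_genes, annot, genome_counts, n_genome_genes, alpha=overrep_alpha
    )
    if categories is None:
        sig_terms = set(overrep.loc[overrep["significant"], "term"])
    else:
        term_sig = dict(zip(overrep["term"], overrep["significant"]))
        sig_terms = set()
        for cat, members in categories.items():
            if term_sig.get(cat, False):
                sig_terms.update(members)

    rows = []
    for term in sorted(sig_terms):
        genes = annot.term_genes.get(term)
        if genes is None or len(genes) <= min_genes:
            continue
        hits = [g for g in genes if g in direction and direction[g] != 0]
        if not hits:
            continue
        col_up = sum(1 for g in hits if direction[g] < 0)
        alt_up = len(hits) - col_up
        p = directional_test(len(hits), col_up, ratio)
        rows.append(
            DirectionalTestResult(
                term, annot.term_names.get(term, term), len(genes),
                len(hits), col_up, alt_up, p,
            )
        )
    df = pd.DataFrame(
        [
            (r.term, r.name, r.genes_in_term, r.eqtls_observed, r.col_up, r.alt_up, r.p)
            for r in rows
        ],
        columns=["term", "name", "genes", "eqtls", "col_up", "alt_up", "p"],
    )
    df.attrs["genome_ratio"] = ratio
    return df.sort_values("p").reset_index(drop=True)
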