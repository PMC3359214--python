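"""Synthetic data with known ground truth.

Emulates the study conditions end to end: biparental RIL crosses on a
~90-marker, 5-chromosome map; expression traits with planted local and
distant effects, master-regulator hotspots and hidden confounders; and raw
two-colour dye-swap spot tables with intensity-dependent dye bias and
print-tip block offsets.

Recombination model: Haldane map function r = (1 - e^(-2d/100))/2 for a
map distance of d cM, with the selfed-RIL transformation R = 2r/(1 + 2r)
(fully inbred lines, no interference, chromosomes independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ALT,
    COL,
    MISSING,
    ExpressionMatrix,
    GeneticMap,
    RileqtlError,
    RilGenotypes,
)


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Meiotic recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_R(r: np.ndarray | float) -> np.ndarray | float:
    """Selfed-RIL apparent recombination fraction R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def default_map(
    n_chrom: int = 5,
    markers_per_chrom: int = 18,
    chrom_cm: Sequence[float] = (100.0, 90.0, 95.0, 85.0, 105.0),
    chrom_bp: Sequence[int] = (
        24_000_000,
        20_000_000,
        23_000_000,
        18_500_000,
        26_000_000,
    ),
) -> GeneticMap:
    """A 5-chromosome, 90-marker map of the size used for the study populations."""
    rows = []
    for c in range(n_chrom):
        chrom = str(c + 1)
        cms = np.linspace(0.0, chrom_cm[c], markers_per_chrom)
        bps = np.linspace(1, chrom_bp[c], markers_per_chrom).round().astype(int)
        for i in range(markers_per_chrom):
            rows.append((f"m{chrom}_{i + 1}", chrom, cms[i], bps[i]))
    markers = pd.DataFrame(
        rows, columns=["marker", "chrom", "cm", "bp"]
    ).set_index("marker")
    lengths = {str(c + 1): int(chrom_bp[c]) for c in range(n_chrom)}
    return GeneticMap(markers, lengths)


def simulate_ril_genotypes(
    gmap: GeneticMap,
    n_lines: int,
    seed: int,
    missing_rate: float = 0.0,
) -> RilGenotypes:
    """Simulate fully inbred RIL genotypes as a Markov chain along each chromosome.

    The first marker of each chromosome is Bernoulli(1/2); the allele switches
    between adjacent markers with probability R = 2r/(1+2r), r from Haldane's
    map function of the inter-marker distance. ``missing_rate`` optionally
    masks calls at random to exercise missing-data handling.
    """
    if n_lines < 2:
        raise RileqtlError("need at least 2 lines")
    rng = np.random.default_rng(seed)
    n_markers = gmap.n_markers
    calls = np.empty((n_lines, n_markers), dtype=np.int8)
    col = 0
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_markers(chrom)
        k = len(sub)
        d = np.diff(sub["cm"].to_numpy())
        R = ril_R(haldane_r(d))
        state = rng.integers(0, 2, size=n_lines).astype(np.int8)
        calls[:, col] = state
        for i in range(k - 1):
            flip = rng.random(n_lines) < R[i]
            state = np.where(flip, 1 - state, state).astype(np.int8)
            calls[:, col + i + 1] = state
        col += k
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return RilGenotypes(line_ids, calls, gmap)


@dataclass
class PlantedEffect:
    """One planted additive effect: trait controlled by a marker with effect a.

    ``a`` follows the Alt-minus-Col sign convention: the trait value gains
    ``a`` in lines carrying the Alt allele at the controlling marker.
    """

    trait: str
    marker: str
    a: float
    kind: str = "local"  # expected classification


@dataclass
class HotspotSpec:
    """A master regulator at ``marker`` controlling ``n_traits`` distant traits."""

    marker: str
    n_traits: int
    a: float = 1.0


@dataclass
class ArchitectureSpec:
    """Expression architecture: planted effects, hotspots, confounders, noise."""

    effects: list[PlantedEffect] = field(default_factory=list)
    hotspots: list[HotspotSpec] = field(default_factory=list)
    n_factors: int = 0
    factor_scale: float = 0.0
    sigma: float = 0.5
    n_null_traits: int = 0
    baseline: float = 8.5
    known_effect: float = 0.0  # effect size of the known covariate, if any

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise RileqtlError("residual sd must be > 0")
        if any(h.n_traits < 0 for h in self.hotspots):
            raise RileqtlError("hotspot trait counts must be >= 0")


def simulate_expression(
    genos: RilGenotypes,
    spec: ArchitectureSpec,
    seed: int,
    known: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate trait values and return them with the planted-truth table.

    Each trait is baseline + sum of planted marker effects (a added to Alt
    carriers) + factor loadings x hidden factors + known-covariate term +
    N(0, sigma^2) noise. The truth table records trait, controlling marker,
    chromosome, position, effect size and expected classification.
    """
    rng = np.random.default_rng(seed)
    gmap = genos.gmap
    n = genos.n_lines

    effects = list(spec.effects)
    for h_i, h in enumerate(spec.hotspots):
        for t in range(h.n_traits):
            effects.append(
                PlantedEffect(
                    trait=f"hot{h_i + 1}_t{t + 1}", marker=h.marker, a=h.a, kind="distant"
                )
            )

    trait_effects: dict[str, list[PlantedEffect]] = {}
    for e in effects:
        if e.marker not in gmap.markers.index:
            raise RileqtlError(f"unknown marker id {e.marker!r}")
        trait_effects.setdefault(e.trait, []).append(e)
    trait_ids = list(trait_effects)
    trait_ids += [f"null_t{t + 1}" for t in range(spec.n_null_traits)]

    factors = None
    if spec.n_factors > 0:
        factors = rng.standard_normal((n, spec.n_factors))

    marker_pos = {m: i for i, m in enumerate(gmap.markers.index)}
    values = np.empty((len(trait_ids), n))
    truth_rows = []
    for ti, trait in enumerate(trait_ids):
        y = np.full(n, spec.baseline, dtype=float)
        for e in trait_effects.get(trait, []):
            x = (genos.calls[:, marker_pos[e.marker]] == ALT).astype(float)
            y += e.a * x
            mrow = gmap.markers.loc[e.marker]
            truth_rows.append(
                {
                    "trait": trait,
                    "marker": e.marker,
                    "chrom": mrow["chrom"],
                    "cm": float(mrow["cm"]),
                    "bp": int(mrow["bp"]),
                    "a": e.a,
                    "kind": e.kind,
                }
            )
        if factors is not None:
            lam = rng.normal(0.0, spec.factor_scale, size=spec.n_factors)
            y += factors @ lam
        if known is not None and spec.known_effect != 0.0:
            y += spec.known_effect * known
        y += rng.normal(0.0, spec.sigma, size=n)
        values[ti] = y

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=trait_ids, columns=genos.line_ids)
    )
    truth = pd.DataFrame(
        truth_rows, columns=["trait", "marker", "chrom", "cm", "bp", "a", "kind"]
    )
    return expr, truth


def simulate_dye_swap_arrays(
    levels_a: pd.Series,
    levels_b: pd.Series,
    green_on_array1: str,
    seed: int,
    n_blocks: int = 4,
    block_offsets: Sequence[float] | None = None,
    dye_bias: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emit a dye-swap pair of spot tables for two co-hybridized RILs.

    ``levels_a``/``levels_b`` are true log2 expression levels indexed by
    probe; ``green_on_array1`` names which of the two series' lines is
    labelled green on the first array (its name attribute is the line id).
    The observed log-ratio gains a smooth intensity-dependent dye bias
    ``dye_bias * (A - mean(A))``, a per-print-tip-block offset, and
    N(0, noise_sd^2) channel noise. Array 2 swaps the dyes.
    """
    if green_on_array1 not in (levels_a.name, levels_b.name):
        raise RileqtlError("pairing metadata does not name either line")
    if not levels_a.index.equals(levels_b.index):
        raise RileqtlError("probe sets differ between the two lines")
    rng = np.random.default_rng(seed)
    probes = list(levels_a.index)
    n = len(probes)
    blocks = (np.arange(n) * n_blocks // n) + 1
    if block_offsets is None:
        block_offsets = np.zeros(n_blocks)
    block_offsets = np.asarray(block_offsets, dtype=float)
    if len(block_offsets) != n_blocks:
        raise RileqtlError("need one offset per block")

    green1 = levels_a if green_on_array1 == levels_a.name else levels_b
    red1 = levels_b if green_on_array1 == levels_a.name else levels_a

    def one_array(green: pd.Series, red: pd.Series) -> pd.DataFrame:
        g = green.to_numpy(dtype=float) + rng.normal(0, noise_sd, n)
        r = red.to_numpy(dtype=float) + rng.normal(0, noise_sd, n)
        a = 0.5 * (g + r)
        # dye bias and print-tip offsets act on the ratio: push them into red
        bias = dye_bias * (a - a.mean()) + block_offsets[blocks - 1]
        r = r + bias
        return pd.DataFrame(
            {
                "spot": [f"s{i + 1}" for i in range(n)],
                "probe": probes,
                "block": blocks,
                "log2_red": r,
                "log2_green": g,
                "flag": "ok",
            }
        )

    array1 = one_array(green1, red1)
    array2 = one_array(red1, green1)  # fluorochrome reversal
    meta = {
        "green_on_array1": green_on_array1,
        "lines": (str(levels_a.name), str(levels_b.name)),
    }
    return array1, array2, meta
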