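import numpy as np
import pandas as pd
import pytest

from rileqtl import simulate as sim
from rileqtl.scan import (
    ScanCurve,
    genotype_probabilities,
    pick_qtls,
    qtl_effects,
    scan_cim,
    scan_im,
    support_interval,
)
from rileqtl.types import GeneticMap, RilGenotypes


def brute_force_lod(y, x):
    """Independent oracle: LOD from explicit least squares at one position."""
    n = len(y)
    rss0 = np.sum((y - y.mean()) ** 2)
    A = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss1 = np.sum((y - A @ beta) ** 2)
    return (n / 2) * np.log10(rss0 / rss1)


class TestGenotypeProbabilities:
    def test_observed_marker_is_certain(self, toy_probs, toy_cross):
        _, genos = toy_cross
        j = toy_probs.marker_column("m2")
        np.testing.assert_array_equal(
            toy_probs.p_col[:, j], (genos.calls[:, 1] == 0).astype(float)
        )

    def test_midpoint_between_opposite_flanks_is_half(self):
        markers = pd.DataFrame(
            {"chrom": ["1", "1"], "cm": [0.0, 20.0], "bp": [1, 1000]},
            index=pd.Index(["a", "b"], name="marker"),
        )
        gmap = GeneticMap(markers, {"1": 1000})
        genos = RilGenotypes(
            ["L1", "L2"], np.array([[0, 1], [1, 0]], dtype=np.int8), gmap
        )
        probs = genotype_probabilities(gmap, genos, step=10.0)
        mid = np.flatnonzero(probs.grid["cm"].to_numpy() == 10.0)[0]
        np.testing.assert_allclose(probs.p_col[:, mid], 0.5)

    def test_agreeing_flanks_two_point_formula(self):
        # flanks both Col at 5 cM each side: r = 0.04758, R = 0.08689,
        # P(Col) = (1-R)^2 / ((1-R)^2 + R^2) = 0.99103
        markers = pd.DataFrame(
            {"chrom": ["1", "1"], "cm": [0.0, 10.0], "bp": [1, 1000]},
            index=pd.Index(["a", "b"], name="marker"),
        )
        gmap = GeneticMap(markers, {"1": 1000})
        genos = RilGenotypes(["L1"], np.array([[0, 0]], dtype=np.int8), gmap)
        probs = genotype_probabilities(gmap, genos, step=5.0)
        mid = np.flatnonzero(probs.grid["cm"].to_numpy() == 5.0)[0]
        assert probs.p_col[0, mid] == pytest.approx(0.99103, abs=5e-5)

    def test_probabilities_bounded_and_missing_handled(self, study_cross):
        gmap, _ = study_cross
        genos = sim.simulate_ril_genotypes(gmap, 40, seed=3, missing_rate=0.2)
        probs = genotype_probabilities(gmap, genos, step=2.0)
        assert np.all((probs.p_col >= 0) & (probs.p_col <= 1))
        # grid strictly increasing in cM within each chromosome
        for _, sub in probs.grid.groupby("chrom"):
            assert np.all(np.diff(sub["cm"].to_numpy()) > 0)


class TestScanIm:
    def test_worked_example_lod(self, toy_probs, toy_trait):
        curve = scan_im(toy_probs, toy_trait, "t")
        j = toy_probs.marker_column("m2")
        # RSS0 = 2, RSS1 = 1.5 -> LOD = 4 log10(4/3) = 0.4998
        assert curve.lod[j] == pytest.approx(0.49975, abs=1e-4)

    def test_constant_trait_zero_lod(self, toy_probs):
        curve = scan_im(toy_probs, np.ones(8), "t")
        np.testing.assert_array_equal(curve.lod, 0.0)

    def test_affine_invariance(self, study_probs, study_cross):
        _, genos = study_cross
        rng = np.random.default_rng(0)
        y = rng.normal(size=genos.n_lines)
        a = scan_im(study_probs, y).lod
        b = scan_im(study_probs, 2.0 * y + 3.0).lod
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_oracle_equivalence_at_observed_markers(self):
        # 100 random toy crosses: HK LOD at a fully observed marker equals
        # the brute-force least-squares LOD
        rng = np.random.default_rng(42)
        markers = pd.DataFrame(
            {"chrom": ["1"] * 4, "cm": [0.0, 10.0, 25.0, 40.0],
             "bp": [1, 10_000, 25_000, 40_000]},
            index=pd.Index([f"m{i}" for i in range(4)], name="marker"),
        )
        gmap = GeneticMap(markers, {"1": 40_000})
        for _ in range(100):
            n = int(rng.integers(12, 30))
            calls = rng.integers(0, 2, size=(n, 4)).astype(np.int8)
            if len(np.unique(calls[:, 2])) < 2:
                continue
            genos = RilGenotypes([f"L{i}" for i in range(n)], calls, gmap)
            probs = genotype_probabilities(gmap, genos, step=5.0)
            y = rng.normal(size=n) + calls[:, 2] * rng.normal()
            curve = scan_im(probs, y)
            j = probs.marker_column("m2")
            expected = brute_force_lod(y, (calls[:, 2] == 1).astype(float))
            assert curve.lod[j] == pytest.approx(expected, rel=1e-9)

    def test_lod_nonnegative(self, study_probs):
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(study_probs.line_ids))
        assert np.all(scan_im(study_probs, y).lod >= 0)


def _triangle_curve(grid):
    cm = grid["cm"].to_numpy()
    lod = np.maximum(0.0, 5.0 - 0.25 * np.abs(cm - 50.0))
    return ScanCurve("t", lod, grid)


class TestPickQtls:
    @staticmethod
    def _grid(length_cm=100.0, step=2.0, chrom="1"):
        cm = np.arange(0.0, length_cm + step, step)
        return pd.DataFrame(
            {"chrom": chrom, "cm": cm, "bp": (cm * 10_000).astype(int) + 1,
             "marker": ""}
        )

    def test_below_threshold_empty(self):
        grid = self._grid()
        curve = ScanCurve("t", np.full(len(grid), 2.0), grid)
        assert pick_qtls(curve, 3.0) == []

    def test_exclusion_window_masks_nearby_peak(self):
        grid = self._grid()
        cm = grid["cm"].to_numpy()
        # peaks 40 cM apart -> both kept
        lod = np.zeros(len(grid))
        lod[cm == 30.0] = 5.0
        lod[cm == 70.0] = 4.0
        peaks = pick_qtls(ScanCurve("t", lod, grid), 3.0)
        assert [p.cm for p in peaks] == [30.0, 70.0]
        # peaks 10 cM apart -> only the stronger survives the 15 cM mask
        lod = np.zeros(len(grid))
        lod[cm == 30.0] = 5.0
        lod[cm == 40.0] = 4.0
        peaks = pick_qtls(ScanCurve("t", lod, grid), 3.0)
        assert [(p.cm, p.lod) for p in peaks] == [(30.0, 5.0)]

    def test_triangular_support_interval(self):
        # slope 0.25 LOD/cM, drop 1.5 -> 6 cM each side of the 50 cM peak
        grid = self._grid()
        peaks = pick_qtls(_triangle_curve(grid), 3.0, lod_drop=1.5)
        assert len(peaks) == 1
        assert (peaks[0].inf_cm, peaks[0].cm, peaks[0].sup_cm) == (44.0, 50.0, 56.0)

    def test_no_two_peaks_closer_than_exclusion(self, study_probs):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.normal(size=len(study_probs.line_ids))
            peaks = pick_qtls(scan_im(study_probs, y), 1.0)
            by_chrom: dict = {}
            for p in peaks:
                by_chrom.setdefault(p.chrom, []).append(p.cm)
            for cms in by_chrom.values():
                cms = sorted(cms)
                assert all(b - a > 15.0 for a, b in zip(cms, cms[1:]))


class TestScanCim:
    def test_reduces_to_im_without_cofactors(self, study_probs):
        rng = np.random.default_rng(2)
        y = rng.normal(size=len(study_probs.line_ids))
        np.testing.assert_allclose(
            scan_cim(study_probs, y, []).lod, scan_im(study_probs, y).lod
        )

    def test_cofactor_raises_power_on_other_chromosome(self, study_cross):
        gmap, genos = study_cross
        spec = sim.ArchitectureSpec(
            effects=[
                sim.PlantedEffect("t", "m1_9", a=1.2),
                sim.PlantedEffect("t", "m3_9", a=0.6),
            ],
            sigma=0.4,
        )
        expr, _ = sim.simulate_expression(genos, spec, seed=21)
        probs = genotype_probabilities(gmap, genos, step=2.0)
        y = expr.trait("t")
        im = scan_im(probs, y)
        peaks = pick_qtls(im, 3.0)
        big = max(peaks, key=lambda p: p.lod)
        cim = scan_cim(probs, y, [big], 15.0)
        j = probs.marker_column("m3_9")
        assert cim.lod[j] > im.lod[j]

    def test_cofactor_dropped_within_window(self, study_probs):
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(study_probs.line_ids))
        peaks = pick_qtls(scan_im(study_probs, y), 0.5)
        assert peaks, "need at least one cofactor for this check"
        pk = peaks[0]
        cim = scan_cim(study_probs, y, [pk], 15.0)
        # at the cofactor's own position the cofactor must be excluded,
        # so the CIM LOD equals the IM LOD there
        im = scan_im(study_probs, y)
        assert cim.lod[pk.grid_index] == pytest.approx(im.lod[pk.grid_index], rel=1e-6)


class TestQtlEffects:
    def test_worked_example(self, toy_probs, toy_trait):
        peaks = pick_qtls(scan_im(toy_probs, toy_trait), 0.4)
        effs, _ = qtl_effects(toy_trait, toy_probs, peaks)
        assert effs[0].add == pytest.approx(-0.50)
        assert effs[0].rsq == pytest.approx(0.25)

    def test_identical_groups_zero_effect(self, toy_probs):
        y = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        from rileqtl.scan import Peak

        j = toy_probs.marker_column("m2")
        pk = Peak(j, "1", 10.0, 100_000, 5.0, 0.0, 20.0, 1, 200_000)
        effs, _ = qtl_effects(y, toy_probs, [pk])
        assert effs[0].add == pytest.approx(0.0)
        assert effs[0].rsq == pytest.approx(0.0)

    def test_pure_interaction(self, study_cross, study_probs):
        # XOR trait of two markers: main effects ~0, interaction ~1
        gmap, genos = study_cross
        j1 = list(gmap.markers.index).index("m1_5")
        j2 = list(gmap.markers.index).index("m4_5")
        g1 = genos.calls[:, j1].astype(float)
        g2 = genos.calls[:, j2].astype(float)
        y = np.logical_xor(g1, g2).astype(float)
        from rileqtl.scan import Peak

        c1 = study_probs.marker_column("m1_5")
        c2 = study_probs.marker_column("m4_5")
        grid = study_probs.grid
        pks = [
            Peak(c, grid["chrom"][c], grid["cm"][c], grid["bp"][c], 1.0,
                 grid["cm"][c], grid["cm"][c], grid["bp"][c], grid["bp"][c])
            for c in (c1, c2)
        ]
        effs, inter = qtl_effects(y, study_probs, pks)
        assert inter[(0, 1)] > 0.5
        assert all(e.rsq < 0.2 for e in effs)


def test_support_interval_matches_pick(toy_probs, toy_trait):
    curve = scan_im(toy_probs, toy_trait)
    peaks = pick_qtls(curve, 0.4)
    pk = peaks[0]
    assert support_interval(curve, pk.grid_index) == (
        pk.inf_cm, pk.sup_cm, pk.inf_bp, pk.sup_bp
    )
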