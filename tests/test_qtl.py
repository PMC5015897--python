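"""Map estimation, HMM probabilities, scans, thresholds, model fits."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lobeqtl.config import ConfigError, CrossDesign
from lobeqtl.genotyping import A, B, H, NA, MarkerMatrix
from lobeqtl.qtl import (
    Thresholds,
    _em_recomb_fraction,
    estimate_genetic_map,
    fit_multi_qtl,
    genotype_probabilities,
    haldane_cm,
    haldane_r,
    lod_drop_interval,
    map_expansion,
    permutation_thresholds,
    regress_chr4,
    scan_one,
    significant_peaks,
)


def _matrix(calls, chroms=None, is_x=None, spacing=250_000):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "name": [f"m{j}" for j in range(m)],
            "chrom": chroms or ["2L"] * m,
            "start": np.arange(m) * spacing,
            "end": (np.arange(m) + 1) * spacing,
            "mid": np.arange(m) * spacing + spacing // 2,
            "is_x": is_x if is_x is not None else [False] * m,
        }
    )
    return MarkerMatrix(
        samples=[f"s{i}" for i in range(n)],
        roles=np.array(["rec"] * n),
        sex=np.array(["M"] * n),
        calls=calls,
        markers=markers,
    )


# ---------------------------------------------------------------------------
# recombination-fraction estimation
# ---------------------------------------------------------------------------
class TestMapEstimation:
    def test_identical_columns_give_zero_distance(self, rng):
        col = rng.choice([A, H, B], size=200).astype(np.int8)
        mm = _matrix(np.column_stack([col, col]))
        gmap = estimate_genetic_map(mm)
        assert gmap.chroms[0].cm[-1] < 1e-6

    def test_independent_columns_give_long_distance(self, rng):
        c1 = rng.choice([A, H, B], size=400, p=[0.25, 0.5, 0.25]).astype(np.int8)
        c2 = rng.permutation(c1)
        mm = _matrix(np.column_stack([c1, c2]))
        gmap = estimate_genetic_map(mm)
        r = gmap.chroms[0].r[0]
        assert r > 0.4
        assert gmap.chroms[0].cm[-1] > 80  # Haldane blows up near r = 0.5

    def test_em_matches_direct_count_oracle(self):
        """With no double heterozygotes the EM has a closed form:
        recombinant gametes / (2n)."""
        pairs = [(A, A)] * 40 + [(A, H)] * 6 + [(B, B)] * 40 + [(B, H)] * 4 + [(A, B)] * 2
        g1 = np.array([p[0] for p in pairs], dtype=np.int8)
        g2 = np.array([p[1] for p in pairs], dtype=np.int8)
        r, n = _em_recomb_fraction(g1, g2, hemizygous=False)
        k = 6 * 1 + 4 * 1 + 2 * 2  # recombinant gametes
        assert np.isclose(r, k / (2 * len(pairs)), atol=1e-9)
        # multipoint EM agrees on complete two-marker data
        gmap = estimate_genetic_map(_matrix(np.column_stack([g1, g2])), error_rate=1e-12)
        assert np.isclose(gmap.chroms[0].r[0], k / (2 * len(pairs)), atol=1e-6)

    def test_hemizygous_r_is_mismatch_fraction(self):
        g1 = np.array([A, A, B, B, A, B, NA], dtype=np.int8)
        g2 = np.array([A, B, B, A, A, B, B], dtype=np.int8)
        r, n = _em_recomb_fraction(g1, g2, hemizygous=True)
        assert n == 6 and np.isclose(r, 2 / 6)

    def test_multipoint_em_integrates_over_missing_markers(self, rng):
        """With the middle marker missing in most individuals, the joint
        EM still recovers both interval lengths by splitting the
        end-to-end recombination across the flanking intervals."""
        n = 2000
        # single-gamete chain over 3 markers, r = 0.1 per interval
        def chain():
            g = [rng.random() < 0.5]
            for _ in range(2):
                g.append(g[-1] ^ (rng.random() < 0.1))
            return g
        gam1 = np.array([chain() for _ in range(n)], dtype=int)
        gam2 = np.array([chain() for _ in range(n)], dtype=int)
        calls = (gam1 + gam2).astype(np.int8)
        calls[rng.random(n) < 0.8, 1] = NA
        gmap = estimate_genetic_map(_matrix(calls))
        total = gmap.chroms[0].cm[-1]
        expected = 2 * haldane_cm(0.1)  # Haldane-additive truth ~ 22.3 cM
        assert abs(total - expected) < 0.15 * expected
        assert abs(gmap.chroms[0].r[0] - 0.1) < 0.03


class TestExpansion:
    def test_design_expectations(self, small_cohort, small_genome):
        from lobeqtl.experiments import dense_window_markers, truth_marker_matrix

        mm = truth_marker_matrix(small_cohort, dense_window_markers(small_genome))
        rep = map_expansion(estimate_genetic_map(mm), small_genome, small_cohort.design)
        assert np.isclose(rep.expected_autosome, 6 / 2 / 2)  # t=6: s/2 = 1.5
        assert np.isclose(rep.expected_x, (2 / 3) * 1.5)
        assert (rep.table["ratio"] > 0).all()

    def test_f13_expected_values(self):
        d = CrossDesign(generations=13, population_size=300)
        assert np.isclose(d.s / 2, 3.25)
        assert np.isclose((2 / 3) * d.s / 2, 2.1667, atol=1e-3)
        d2 = CrossDesign(generations=2, population_size=300)
        assert np.isclose(d2.s / 2, 0.5)


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------
def _three_marker_grid(calls, error_rate=0.0, spacing_cm=None):
    mm = _matrix(calls)
    gmap = estimate_genetic_map(mm)
    if spacing_cm is not None:
        # impose an exact map rather than the estimated one
        c = gmap.chroms[0]
        c.cm = np.concatenate([[0.0], np.cumsum(spacing_cm)])
        c.r = haldane_r(np.asarray(spacing_cm, dtype=float))
    return genotype_probabilities(mm, gmap, step=1.0, error_rate=error_rate)


class TestGenotypeProbabilities:
    def test_probabilities_sum_to_one(self, rng):
        calls = rng.choice([A, H, B, NA], size=(30, 8)).astype(np.int8)
        grid = _three_marker_grid(calls, error_rate=0.01)
        for cg in grid.chroms:
            assert np.allclose(cg.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_observed_marker_has_probability_one(self):
        calls = np.array([[A, H, B]] * 10, dtype=np.int8)
        grid = _three_marker_grid(calls, error_rate=0.0, spacing_cm=[10.0, 10.0])
        cg = grid.chroms[0]
        for j, code in zip(np.flatnonzero(cg.is_marker), [A, H, B]):
            assert np.isclose(cg.probs[0, j, {A: 0, H: 1, B: 2}[code]], 1.0, atol=1e-9)

    def test_midpoint_between_b_markers_matches_enumeration(self):
        """P(BB at the midpoint of a 2 cM B...B bracket) from the chain
        equals the direct two-step enumeration."""
        calls = np.array([[B, B]] * 5, dtype=np.int8)
        grid = _three_marker_grid(calls, error_rate=0.0, spacing_cm=[2.0])
        cg = grid.chroms[0]
        mid = int(np.argmin(np.abs(cg.cm - 1.0)))
        from lobeqtl.qtl import _transition

        r = haldane_r(1.0)
        T = _transition(r, 3)
        # oracle: P(state at mid | B at both ends) by enumeration
        probs = T[2, :] * T[:, 2]
        probs = probs / probs.sum()
        assert np.allclose(cg.probs[0, mid], probs, atol=1e-9)
        assert cg.probs[0, mid, 2] > 0.99

    def test_male_x_chain_has_two_states(self):
        calls = np.array([[A, B], [B, B]], dtype=np.int8)
        mm = _matrix(calls, chroms=["X", "X"], is_x=[True, True])
        grid = genotype_probabilities(mm, estimate_genetic_map(mm), step=1.0)
        assert grid.chroms[0].n_states == 2


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------
def _informative_matrix(rng, n=120, m=6, spacing_cm=10.0):
    """Markers from an intercross chain so the map is estimable."""
    r = haldane_r(spacing_cm)
    gam = np.zeros((2, n, m), dtype=int)
    for g in range(2):
        gam[g, :, 0] = rng.random(n) < 0.5
        for j in range(1, m):
            flip = rng.random(n) < r
            gam[g, :, j] = np.where(flip, 1 - gam[g, :, j - 1], gam[g, :, j - 1])
    calls = (gam[0] + gam[1]).astype(np.int8)
    calls[calls == 1] = H
    calls[calls == 2] = B
    return _matrix(calls), gam


class TestScan:
    def test_hk_equals_closed_form_anova_lod(self, rng):
        """At a fully observed marker, the hk LOD equals the group-mean
        ANOVA LOD to 1e-9."""
        mm, _ = _informative_matrix(rng)
        gmap = estimate_genetic_map(mm)
        grid = genotype_probabilities(mm, gmap, step=1.0, error_rate=0.0)
        y = rng.normal(size=len(mm.samples)) + 0.8 * (mm.calls[:, 2].astype(float) - 1)
        scan = scan_one(grid, y, method="hk")
        cg = grid.chroms[0]
        marker_pos = cg.cm[np.flatnonzero(cg.is_marker)[2]]
        lod_hk = scan.loc[np.isclose(scan["pos_cm"], marker_pos), "lod"].iloc[0]
        # oracle: one-way ANOVA on genotype classes
        g = mm.calls[:, 2]
        tss = ((y - y.mean()) ** 2).sum()
        rss = sum(((y[g == k] - y[g == k].mean()) ** 2).sum() for k in (A, H, B))
        lod_anova = len(y) / 2 * np.log10(tss / rss)
        assert abs(lod_hk - lod_anova) < 1e-9

    def test_peak_at_causal_marker(self, rng):
        mm, _ = _informative_matrix(rng, n=200)
        gmap = estimate_genetic_map(mm)
        grid = genotype_probabilities(mm, gmap, step=1.0, error_rate=0.0)
        y = (mm.calls[:, 3].astype(float) - 1) + rng.normal(scale=0.1, size=200)
        scan = scan_one(grid, y)
        cg = grid.chroms[0]
        peak = scan.loc[scan["lod"].idxmax(), "pos_cm"]
        causal = cg.cm[np.flatnonzero(cg.is_marker)[3]]
        assert abs(peak - causal) <= 2.0

    def test_imp_agrees_with_hk_on_complete_data(self, rng):
        mm, _ = _informative_matrix(rng, n=100, m=4)
        gmap = estimate_genetic_map(mm)
        grid = genotype_probabilities(mm, gmap, step=1.0, error_rate=0.0)
        y = rng.normal(size=100) + 0.5 * (mm.calls[:, 1].astype(float) - 1)
        hk = scan_one(grid, y, method="hk")
        imp = scan_one(grid, y, method="imp", n_draws=32, seed=4)
        at_markers = grid.chroms[0].is_marker
        d = np.abs(hk["lod"].to_numpy()[at_markers] - imp["lod"].to_numpy()[at_markers])
        assert d.max() < 0.1  # identical regressions when genotypes observed

    def test_zero_variance_trait_rejected(self, rng):
        mm, _ = _informative_matrix(rng, n=50, m=3)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm))
        with pytest.raises(ConfigError):
            scan_one(grid, np.ones(50))

    def test_missing_trait_values_dropped(self, rng):
        mm, _ = _informative_matrix(rng, n=60, m=3)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm))
        y = rng.normal(size=60)
        y[:10] = np.nan
        scan = scan_one(grid, y)
        assert scan.attrs["n"] == 50


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------
class TestThresholds:
    def test_single_marker_threshold_matches_chi2(self, rng):
        """One fully informative marker: the 95% permutation threshold
        approaches the chi-square(2 df) LOD, 5.99 / (2 ln 10) ~ 1.30."""
        mm, _ = _informative_matrix(rng, n=200, m=1)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm), step=1.0)
        y = rng.normal(size=200)
        thr = permutation_thresholds(grid, y, n_perm=20_000, alpha=0.05, seed=2)
        oracle = stats.chi2.ppf(0.95, df=2) / (2 * np.log(10))
        assert abs(thr.autosome - oracle) < 0.05

    def test_threshold_monotone_in_alpha(self, rng):
        mm, _ = _informative_matrix(rng, n=80, m=4)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm))
        y = rng.normal(size=80)
        t10 = permutation_thresholds(grid, y, n_perm=500, alpha=0.10, seed=1)
        t01 = permutation_thresholds(grid, y, n_perm=500, alpha=0.01, seed=1)
        assert t01.autosome > t10.autosome

    def test_alpha_split_proportional_to_length(self, rng):
        from lobeqtl.experiments import simulate_chain_genotypes, study_map_markers

        markers = study_map_markers()
        calls = simulate_chain_genotypes(markers, 60, seed=3)
        mm = MarkerMatrix(
            [f"s{i}" for i in range(60)],
            np.array(["rec"] * 60),
            np.array(["M"] * 60),
            calls,
            markers.drop(columns=["cm"]),
        )
        grid = genotype_probabilities(mm, estimate_genetic_map(mm))
        y = rng.normal(size=60)
        thr = permutation_thresholds(grid, y, n_perm=100, alpha=0.05, seed=1)
        la, lx = grid.genetic_lengths()
        assert np.isclose(thr.alpha_autosome, 1 - 0.95 ** (la / (la + lx)))
        assert np.isclose(thr.alpha_x, 1 - 0.95 ** (lx / (la + lx)))
        assert thr.n_perm_x >= thr.n_perm * (la + lx) / lx - 1


# ---------------------------------------------------------------------------
# support intervals
# ---------------------------------------------------------------------------
class TestLodInterval:
    def _scan_frame(self, lods, cm=None):
        m = len(lods)
        cm = np.arange(m, dtype=float) if cm is None else np.asarray(cm)
        return pd.DataFrame(
            {
                "name": [f"p{j}" for j in range(m)],
                "chrom": "2L",
                "pos_cm": cm,
                "bp_lo": cm * 1e5,
                "bp_hi": cm * 1e5 + 5e4,
                "is_x": False,
                "lod": lods,
            }
        )

    def test_two_lod_drop_bounds(self):
        lods = np.array([0.5, 3.0, 7.9, 9.8, 8.4, 7.7, 1.0])
        iv = lod_drop_interval(self._scan_frame(lods), "2L")
        assert iv["peak_lod"] == 9.8
        # contiguous run with LOD >= 7.8: indices 2..4
        assert iv["cm_lo"] == 2.0 and iv["cm_hi"] == 4.0

    def test_monotone_curve_clips_at_chromosome_start(self):
        lods = np.array([5.0, 4.5, 4.0, 2.0, 1.0])
        iv = lod_drop_interval(self._scan_frame(lods), "2L")
        assert iv["cm_lo"] == 0.0

    def test_bp_interpolation_midway(self, rng):
        mm, _ = _informative_matrix(rng, n=50, m=3, spacing_cm=4.0)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm), step=1.0)
        cg = grid.chroms[0]
        mks = np.flatnonzero(cg.is_marker)
        lo, hi = mks[0], mks[1]
        midway_cm = (cg.cm[lo] + cg.cm[hi]) / 2
        j = int(np.argmin(np.abs(cg.cm - midway_cm)))
        expect = (cg.bp[lo] + cg.bp[hi]) / 2
        assert abs(cg.bp[j] - expect) <= abs(cg.bp[hi] - cg.bp[lo]) * (
            abs(cg.cm[j] - midway_cm) / (cg.cm[hi] - cg.cm[lo]) + 1e-9
        )


# ---------------------------------------------------------------------------
# multi-QTL fits
# ---------------------------------------------------------------------------
class TestMultiQTL:
    def test_pure_additive_qtl_explains_everything(self, rng):
        mm, _ = _informative_matrix(rng, n=150)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm), error_rate=0.0)
        cg = grid.chroms[0]
        pos = cg.cm[np.flatnonzero(cg.is_marker)[2]]
        y = mm.calls[:, 2].astype(float) - 1.0
        fit = fit_multi_qtl(grid, [("2L", pos)], y, interactions=False, conditional=False)
        assert fit.total_var_explained > 99.9
        assert abs(fit.table.loc[0, "additive"] - 1.0) < 1e-6
        assert abs(fit.table.loc[0, "dominance"]) < 1e-6

    def test_overdominant_qtl_sign_structure(self, rng):
        mm, _ = _informative_matrix(rng, n=200)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm), error_rate=0.0)
        cg = grid.chroms[0]
        pos = cg.cm[np.flatnonzero(cg.is_marker)[3]]
        g = mm.calls[:, 3].astype(float)
        y = 0.05 * (g - 1) - 0.9 * (g == H) + rng.normal(scale=0.05, size=200)
        fit = fit_multi_qtl(grid, [("2L", pos)], y, interactions=False, conditional=False)
        a, d = fit.table.loc[0, "additive"], fit.table.loc[0, "dominance"]
        assert d < 0 and abs(d) > abs(a)

    def test_two_qtl_recovered_jointly(self, rng):
        mm, _ = _informative_matrix(rng, n=250, m=8, spacing_cm=25.0)
        grid = genotype_probabilities(mm, estimate_genetic_map(mm), error_rate=0.0)
        cg = grid.chroms[0]
        mks = np.flatnonzero(cg.is_marker)
        p1, p2 = cg.cm[mks[1]], cg.cm[mks[6]]
        y = (
            0.6 * (mm.calls[:, 1].astype(float) - 1)
            - 0.4 * (mm.calls[:, 6].astype(float) - 1)
            + rng.normal(scale=0.3, size=250)
        )
        fit = fit_multi_qtl(grid, [("2L", p1), ("2L", p2)], y, conditional=True)
        assert abs(fit.table.loc[0, "additive"] - 0.6) < 0.1
        assert abs(fit.table.loc[1, "additive"] + 0.4) < 0.1
        assert (fit.table["lod"] > 3).all()
        assert len(fit.interactions) == 1
        assert fit.interactions.loc[0, "p"] > 0.001  # no planted interaction
        # conditional scan shows no further peaks anywhere near the fit
        assert fit.conditional_scan["lod"].max() < fit.table["lod"].min()


class TestChr4Regression:
    def _consensus(self, codes):
        return pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(len(codes))],
                "consensus": codes,
                "discordant": False,
            }
        )

    def test_exact_dosage_association(self, rng):
        codes = rng.choice([A, H, B], size=60)
        pheno = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(60)], "area": codes.astype(float)}
        )
        out = regress_chr4(self._consensus(codes), pheno, ["area"])
        assert out.loc[0, "p"] < 1e-20

    def test_monomorphic_consensus_gives_na(self, rng):
        codes = np.full(30, B)
        pheno = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(30)], "area": rng.normal(size=30)}
        )
        out = regress_chr4(self._consensus(codes), pheno, ["area"])
        assert np.isnan(out.loc[0, "p"])

    def test_null_p_values_are_uniform(self, rng):
        """Independent traits give approximately uniform regression p."""
        codes = rng.choice([A, H, B], size=100)
        ps = []
        for _ in range(200):
            pheno = pd.DataFrame(
                {"sample_id": [f"s{i}" for i in range(100)], "area": rng.normal(size=100)}
            )
            ps.append(regress_chr4(self._consensus(codes), pheno, ["area"]).loc[0, "p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001


def test_significant_peaks_respects_chromosome_type():
    scan = pd.DataFrame(
        {
            "name": ["a", "b"],
            "chrom": ["X", "2L"],
            "pos_cm": [0.0, 0.0],
            "bp_lo": [0.0, 0.0],
            "bp_hi": [1.0, 1.0],
            "is_x": [True, False],
            "lod": [3.0, 3.0],
        }
    )
    thr = Thresholds(0.05, 0.04, 0.01, autosome=3.5, x=2.7, n_perm=100, n_perm_x=100)
    peaks = significant_peaks(scan, thr)
    assert list(peaks["chrom"]) == ["X"]  # 3.0 clears 2.7 but not 3.5
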