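"""Evidence ladder, KDE likelihood-ratio fitting and PP3/BP4 assignment."""

import numpy as np
import pandas as pd
import pytest

from spdvkit.calibration import (
    EvidenceCall,
    assign_level,
    classify_variants,
    evidence_ladder,
    fit_lr_curve,
    kde_density,
    summarise_calls,
)


class TestEvidenceLadder:
    def test_even_prior_gives_op_99(self):
        assert evidence_ladder(0.5, 0.99).op_vs == pytest.approx(99.0)

    def test_ten_percent_prior_thresholds(self):
        lad = evidence_ladder(0.1, 0.99)
        assert lad.op_vs == pytest.approx(891.0)
        assert lad.pathogenic["supporting"] == pytest.approx(2.3374, abs=1e-3)
        assert lad.pathogenic["moderate"] == pytest.approx(5.4635, abs=1e-3)
        assert lad.pathogenic["strong"] == pytest.approx(29.8496, abs=1e-3)

    def test_successive_squares_chain(self):
        lad = evidence_ladder(0.1)
        assert lad.pathogenic["supporting"] ** 2 == pytest.approx(lad.pathogenic["moderate"], rel=1e-12)
        assert lad.pathogenic["moderate"] ** 2 == pytest.approx(lad.pathogenic["strong"], rel=1e-12)
        assert lad.pathogenic["strong"] ** 2 == pytest.approx(lad.op_vs, rel=1e-12)
        assert lad.pathogenic["supporting"] ** 8 == pytest.approx(lad.op_vs, rel=1e-9)

    def test_benign_thresholds_are_exact_reciprocals(self):
        lad = evidence_ladder(0.1)
        for level, thr in lad.pathogenic.items():
            assert lad.benign[level] == pytest.approx(1.0 / thr, rel=1e-12)
        assert lad.benign["supporting"] == pytest.approx(1 / 2.337, abs=1e-3)

    @pytest.mark.parametrize("prior,post", [(0.0, 0.99), (1.0, 0.99), (0.5, 0.4), (0.5, 1.0)])
    def test_out_of_range_probabilities_rejected(self, prior, post):
        with pytest.raises(ValueError):
            evidence_ladder(prior, post)


class TestFitLrCurve:
    def test_identical_reference_sets_give_lr_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 300)
        m = fit_lr_curve(x, x.copy(), n_boot=100, seed=3)
        inner = (m.grid > -1.5) & (m.grid < 1.5)
        assert np.allclose(m.lr_point[inner], 1.0, atol=1e-9)
        assert np.all(m.lr_lower[inner] <= 1.0 + 1e-9)
        assert np.all(m.lr_upper[inner] >= 1.0 - 1e-9)

    def test_two_gaussian_recovery_at_midpoint(self):
        rng = np.random.default_rng(5)
        p = rng.normal(2, 1, 2000)
        b = rng.normal(0, 1, 2000)
        m = fit_lr_curve(p, b, n_boot=50, seed=5)
        assert 0.8 <= float(m.lr([1.0])[0]) <= 1.25  # true lr(1) = 1

    def test_reference_floor_enforced(self):
        with pytest.raises(ValueError):
            fit_lr_curve(np.arange(5.0), np.arange(20.0), n_boot=10)

    def test_extrapolation_clamps_to_boundary(self):
        rng = np.random.default_rng(9)
        m = fit_lr_curve(rng.normal(1, 1, 100), rng.normal(0, 1, 100), n_boot=20, seed=0)
        assert float(m.lr([1e3])[0]) == pytest.approx(m.lr_point[-1])
        assert float(m.lr([-1e3])[0]) == pytest.approx(m.lr_point[0])

    def test_band_brackets_point_estimate_mostly(self):
        rng = np.random.default_rng(12)
        m = fit_lr_curve(rng.normal(1.5, 1, 400), rng.normal(0, 1, 400), n_boot=200, seed=2)
        assert np.all(m.lr_lower <= m.lr_upper)
        inner = slice(20, -20)
        frac = np.mean((m.lr_lower[inner] <= m.lr_point[inner]) & (m.lr_point[inner] <= m.lr_upper[inner]))
        assert frac > 0.9

    def test_kde_density_integrates_to_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 500)
        grid = np.linspace(-6, 6, 2000)
        dens = kde_density(x, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


class TestClassify:
    @staticmethod
    def _ladder():
        return evidence_ladder(0.1, 0.99)

    def test_lr_one_is_indeterminate(self):
        assert assign_level(1.0, 1.0, self._ladder()) == "indeterminate"

    def test_lr_ten_is_pp3_moderate(self):
        assert assign_level(10.0, 10.0, self._ladder()) == "PP3_moderate"

    def test_lr_point_three_is_bp4_supporting(self):
        assert assign_level(0.3, 0.3, self._ladder()) == "BP4_supporting"

    def test_conservative_edges_used(self):
        # point lr high but lower band below supporting -> no PP3
        lad = self._ladder()
        assert assign_level(2.0, 50.0, lad) == "indeterminate"
        # benign uses the upper edge
        assert assign_level(0.01, 0.3, lad) == "BP4_supporting"

    def test_monotone_model_classifies_monotonically(self):
        from spdvkit.calibration import LrModel

        grid = np.linspace(0, 10, 101)
        lr = np.exp(grid - 5)
        model = LrModel("m", "higher_pathogenic", np.array([]), np.array([]),
                        "silverman", 0, 0, grid, lr, lr, lr)
        scores = pd.DataFrame({"variant": [f"v{i}" for i in range(50)],
                               "score": np.linspace(0, 10, 50)})
        calls = classify_variants(model, self._ladder(), scores)
        order = [
            "BP4_very_strong", "BP4_strong", "BP4_moderate", "BP4_supporting",
            "indeterminate",
            "PP3_supporting", "PP3_moderate", "PP3_strong", "PP3_very_strong",
        ]
        ranks = [order.index(c.level) for c in calls]
        assert ranks == sorted(ranks)

    def test_swapped_references_swap_pp3_bp4_counts_exactly(self):
        rng = np.random.default_rng(7)
        p = rng.normal(1.2, 1, 300)
        b = rng.normal(0, 1, 300)
        lad = self._ladder()
        scores = pd.DataFrame({"variant": [f"v{i}" for i in range(200)],
                               "score": rng.normal(0.6, 1.5, 200)})
        m_fwd = fit_lr_curve(p, b, n_boot=100, seed=11)
        m_swp = fit_lr_curve(b, p, n_boot=100, seed=11)
        calls_fwd = classify_variants(m_fwd, lad, scores)
        calls_swp = classify_variants(m_swp, lad, scores)
        def counts(calls):
            pp3 = sum(c.level.startswith("PP3") for c in calls)
            bp4 = sum(c.level.startswith("BP4") for c in calls)
            return pp3, bp4
        f, s = counts(calls_fwd), counts(calls_swp)
        assert f == (s[1], s[0])

    def test_predictor_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        m = fit_lr_curve(rng.normal(1, 1, 50), rng.normal(0, 1, 50),
                         predictor="SPDV_4", n_boot=10)
        scores = pd.DataFrame({"variant": ["v1"], "predictor": ["other"], "score": [0.5]})
        with pytest.raises(ValueError):
            classify_variants(m, self._ladder(), scores)


class TestSummarise:
    def test_all_indeterminate_single_row_of_one(self):
        calls = [EvidenceCall(f"v{i}", 0, 1, 1, 1, "indeterminate") for i in range(4)]
        out = summarise_calls(calls, {f"v{i}": "gnomAD" for i in range(4)})
        assert out.loc["indeterminate", "gnomAD"] == 1.0

    def test_toy_fractions(self):
        levels = ["PP3_moderate", "PP3_moderate", "BP4_supporting", "indeterminate"]
        calls = [EvidenceCall(f"v{i}", 0, 1, 1, 1, lv) for i, lv in enumerate(levels)]
        out = summarise_calls(calls, {f"v{i}": "ClinVar" for i in range(4)})
        assert out.loc["PP3_moderate", "ClinVar"] == pytest.approx(0.5)
        assert out.loc["BP4_supporting", "ClinVar"] == pytest.approx(0.25)
        assert out.loc["indeterminate", "ClinVar"] == pytest.approx(0.25)
        assert out["ClinVar"].sum() == pytest.approx(1.0)

    def test_missing_category_raises(self):
        calls = [EvidenceCall("v0", 0, 1, 1, 1, "indeterminate")]
        with pytest.raises(ValueError):
            summarise_calls(calls, {})

    def test_pathogenic_fraction_increases_with_separation(self):
        lad = evidence_ladder(0.1)
        fracs = []
        for dmu in (0.0, 1.0, 2.0, 3.0):
            rng = np.random.default_rng(31)
            p = rng.normal(dmu, 1, 400)
            b = rng.normal(0, 1, 400)
            m = fit_lr_curve(p, b, n_boot=60, seed=13)
            scores = pd.DataFrame({"variant": [f"v{i}" for i in range(400)], "score": p})
            calls = classify_variants(m, lad, scores)
            fracs.append(np.mean([c.level.startswith("PP3") for c in calls]))
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]
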