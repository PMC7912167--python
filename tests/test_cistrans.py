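"""Regulatory tests, truth-table classification, magnitudes, scatter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from heterodiff.cistrans import (
    _categorize,
    category_counts,
    classify_regulatory,
    effect_magnitudes,
    regulatory_tests,
    trans_factor_scatter,
)


def _sums(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "fp_par", "mp_par", "fp_hy", "mp_hy"]
    )


class TestRegulatoryTests:
    def test_balanced_counts_give_no_signal(self):
        out = regulatory_tests(_sums([("g", 50, 50, 50, 50)]))
        assert (out[["p_parental", "p_cis", "p_trans"]].to_numpy() > 0.9).all()
        assert out["cis_mag"].iloc[0] == pytest.approx(0.0)
        assert out["trans_mag"].iloc[0] == pytest.approx(0.0)

    def test_pure_cis_pattern(self):
        # parental and hybrid ratios both 4:1 -> P and C fire, T does not
        out = regulatory_tests(_sums([("g", 400, 100, 400, 100)]))
        assert out["p_parental"].iloc[0] < 1e-6
        assert out["p_cis"].iloc[0] < 1e-6
        assert out["p_trans"].iloc[0] > 0.5
        # cross-check the large-count chi-square against the binomial
        from scipy import stats

        exact = stats.binomtest(400, 500, 0.5).pvalue
        assert np.log10(out["p_parental"].iloc[0]) == pytest.approx(
            np.log10(exact), rel=0.2
        )

    def test_pure_trans_pattern(self):
        # parents diverge 4:1 but hybrid alleles are balanced
        out = regulatory_tests(_sums([("g", 400, 100, 250, 250)]))
        assert out["p_parental"].iloc[0] < 1e-6
        assert out["p_trans"].iloc[0] < 1e-6
        assert out["p_cis"].iloc[0] > 0.5

    def test_magnitude_identity(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"g{i}", *rng.integers(1, 1000, size=4)) for i in range(100)
        ]
        out = regulatory_tests(_sums(rows))
        lhs = (out["cis_mag"] + out["trans_mag"]).to_numpy()
        assert np.allclose(lhs, out["parental_mag"].to_numpy(), atol=1e-12)

    def test_zero_side_excluded(self):
        out = regulatory_tests(_sums([("g", 0, 0, 50, 50)]))
        assert out.empty


class TestTruthTable:
    def oracle(self, sig_p, sig_c, sig_t, cis_sign, trans_sign):
        if sig_c and sig_t:
            return (
                "cis_trans_enhancing" if cis_sign == trans_sign
                else "cis_trans_compensating"
            )
        if not (sig_p or sig_c or sig_t):
            return "conserved"
        if sig_p and sig_c:
            return "cis_only"
        if sig_p and sig_t:
            return "trans_only"
        return "ambiguous"

    def test_all_significance_and_sign_combinations(self):
        for sig_p, sig_c, sig_t in itertools.product([False, True], repeat=3):
            for cis_sign, trans_sign in itertools.product([-1.0, 1.0], repeat=2):
                got = _categorize(sig_p, sig_c, sig_t, cis_sign, trans_sign)
                assert got == self.oracle(sig_p, sig_c, sig_t, cis_sign, trans_sign)

    def test_sign_rule_examples(self):
        assert _categorize(True, True, True, 2.0, -2.0) == "cis_trans_compensating"
        assert _categorize(True, True, True, 1.0, 1.0) == "cis_trans_enhancing"
        assert _categorize(False, False, False, 0.0, 0.0) == "conserved"


class TestClassifyRegulatory:
    def test_end_to_end_patterns(self):
        sums = _sums(
            [
                ("conserved_g", 250, 250, 250, 250),
                ("cis_g", 400, 100, 400, 100),
                ("trans_g", 400, 100, 250, 250),
                ("comp_g", 250, 250, 400, 100),   # parents equal, alleles diverge
            ]
        )
        calls = classify_regulatory(regulatory_tests(sums))
        got = calls.set_index("gene_id")["category"]
        assert got["conserved_g"] == "conserved"
        assert got["cis_g"] == "cis_only"
        assert got["trans_g"] == "trans_only"
        assert got["comp_g"] == "cis_trans_compensating"

    def test_fold_ambiguous_reassigns(self):
        # C significant alone -> ambiguous unless folded
        sums = _sums([("g", 250, 250, 400, 100)] + [(f"f{i}", 100, 100, 100, 100) for i in range(5)])
        tests = regulatory_tests(sums)
        strict = classify_regulatory(tests)
        g = strict.set_index("gene_id").loc["g", "category"]
        assert g in ("cis_trans_compensating", "ambiguous")


def test_effect_magnitudes_hand_check():
    calls = pd.DataFrame(
        {
            "gene_id": ["a", "b"],
            "category": ["cis_only", "cis_only"],
            "cis_mag": [1.0, 2.0],
            "trans_mag": [0.5, -0.5],
            "parental_mag": [1.5, 1.5],
        }
    )
    out = effect_magnitudes(calls)
    assert out["category"].tolist() == ["cis_only"]
    assert out["median"].iloc[0] == pytest.approx(1.5)
    assert out.attrs["median_abs_cis"] == pytest.approx(1.5)
    assert out.attrs["median_abs_trans"] == pytest.approx(0.5)


def test_effect_magnitudes_skips_empty_categories():
    calls = pd.DataFrame(
        {"gene_id": ["a"], "category": ["conserved"],
         "cis_mag": [0.0], "trans_mag": [0.0], "parental_mag": [0.0]}
    )
    out = effect_magnitudes(calls)
    assert "trans_only" not in out["category"].tolist()


def test_trans_larger_than_cis_by_construction():
    rng = np.random.default_rng(1)
    n = 200
    calls = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "category": ["ambiguous"] * n,
            "cis_mag": rng.normal(0, 0.5, n),
            "trans_mag": rng.normal(0, 2.0, n),
        }
    )
    calls["parental_mag"] = calls["cis_mag"] + calls["trans_mag"]
    out = effect_magnitudes(calls)
    assert out.attrs["median_abs_trans"] > out.attrs["median_abs_cis"]


class TestTransFactorScatter:
    def test_conserved_gene_sits_at_origin(self):
        sums = _sums([("g", 100, 100, 50, 50)])
        out = trans_factor_scatter(sums)
        assert out["x_mp"].iloc[0] == pytest.approx(0.0)
        assert out["y_fp"].iloc[0] == pytest.approx(0.0)

    def test_upregulated_paternal_allele_moves_x(self):
        # FP trans factors upregulate the MP allele in the hybrid:
        # maternal high-parent dominance, x > 0, y ~ 0
        sums = _sums([("g", 400, 100, 200, 200)])
        out = trans_factor_scatter(sums)
        assert out["x_mp"].iloc[0] == pytest.approx(2.0)  # log2(400/100)
        assert out["y_fp"].iloc[0] == pytest.approx(0.0)

    def test_global_rescaling_invariance(self):
        sums = _sums([("g", 120, 80, 70, 30)])
        doubled = sums.copy()
        doubled[["fp_hy", "mp_hy"]] *= 2
        # doubling hybrid library counts then renormalizing (dividing the
        # hybrid side back by its doubled size factor) restores (x, y)
        renorm = doubled.copy()
        renorm[["fp_hy", "mp_hy"]] = renorm[["fp_hy", "mp_hy"]] / 2
        pd.testing.assert_frame_equal(
            trans_factor_scatter(sums), trans_factor_scatter(renorm)
        )
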