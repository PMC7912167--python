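"""Normalization, DEG calling, BH adjustment, and Venn overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterodiff.core_io import GeneCountMatrix, ValidationError
from heterodiff.de import (
    benjamini_hochberg,
    call_degs,
    deg_overlap,
    deg_summary,
    normalize_counts,
    size_factors,
)
from heterodiff.simdata import SimConfig, simulate_trio_experiment


def _matrix(data):
    return GeneCountMatrix(pd.DataFrame(data))


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = _matrix({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_hand_computed_two_sample_case(self):
        # counts (1,2,3) vs (2,4,6): every ratio to the geometric mean is
        # 1/sqrt(2) and sqrt(2) respectively
        m = _matrix({"s1": [1, 2, 3], "s2": [2, 4, 6]})
        f = size_factors(m)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 500, size=(20, 3))
        m1 = _matrix({f"s{i}": base[:, i] for i in range(3)})
        scaled = base.copy()
        scaled[:, 0] *= 3
        m2 = _matrix({f"s{i}": scaled[:, i] for i in range(3)})
        f1, f2 = size_factors(m1), size_factors(m2)
        # tripling one sample's counts triples its factor relative to a
        # common rescaling of all factors
        ratio = (f2 / f1).to_numpy()
        assert ratio[0] / ratio[1] == pytest.approx(3.0)
        assert ratio[1] == pytest.approx(ratio[2])

    def test_all_zero_gene_matrix_rejected(self):
        with pytest.raises(ValidationError):
            size_factors(_matrix({"s1": [0, 5], "s2": [3, 0]}))


def test_normalize_round_trip():
    m = _matrix({"s1": [4, 0, 8], "s2": [2, 6, 10]})
    f = size_factors(m)
    norm = normalize_counts(m, f)
    assert np.allclose(norm * f, m.df)
    assert (norm.loc[m.df["s1"] == 0, "s1"] == 0).all().all()


class TestBenjaminiHochberg:
    def brute_force(self, p):
        # textbook step-up: adj_i = min over j >= i of p_(j) * n / j
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        for rank_idx, i in enumerate(order):
            candidates = [
                p[order[j]] * n / (j + 1) for j in range(rank_idx, n)
            ]
            adj[i] = min(1.0, min(candidates))
        return adj

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_matches_brute_force(self, seed):
        p = np.random.default_rng(seed).uniform(size=50)
        assert np.allclose(benjamini_hochberg(p), self.brute_force(p), atol=1e-12)

    def test_monotone_and_bounded(self):
        p = np.random.default_rng(0).uniform(size=200)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDegs:
    def test_identical_groups_give_no_degs(self, sheet):
        data = {s: [100, 50, 10] for s in sheet.sample_ids}
        m = GeneCountMatrix(pd.DataFrame(data, index=["g1", "g2", "g3"]))
        res = call_degs(m, sheet, ("FP1", "HY1"))
        assert not res["is_deg"].any()

    def test_requires_two_replicates(self, sheet, small_counts):
        single = sheet.df[sheet.df["replicate"] == 1]
        from heterodiff.core_io import SampleSheet

        with pytest.raises(ValidationError, match="replicates"):
            call_degs(small_counts, SampleSheet(single), ("FP1", "HY1"))

    def test_simulation_recovery_at_paper_cutoffs(self):
        # 10% of genes truly differential at 8-fold, deep counts: the
        # Welch stand-in should find most of them with few false calls
        rng = np.random.default_rng(11)
        n, frac_de, fold = 400, 0.1, 8.0
        true_de = np.zeros(n, dtype=bool)
        true_de[: int(n * frac_de)] = True
        base = rng.integers(200, 2000, size=n).astype(float)
        mean_b = np.where(true_de, base * fold, base)
        data = {}
        for rep in range(3):
            data[f"A_r{rep}"] = rng.poisson(base)
            data[f"B_r{rep}"] = rng.poisson(mean_b)
        m = GeneCountMatrix(pd.DataFrame(data, index=[f"g{i:04d}" for i in range(n)]))
        from heterodiff.core_io import SampleSheet

        sheet = SampleSheet(
            pd.DataFrame(
                [
                    {"sample_id": f"{l}_r{r}", "line_id": l,
                     "role": "hybrid" if l == "B" else "female_parent",
                     "replicate": r + 1}
                    for l in ("A", "B")
                    for r in range(3)
                ]
            )
        )
        res = call_degs(m, sheet, ("A", "B"))
        called = res["is_deg"].to_numpy()
        sensitivity = called[true_de].mean()
        fdr = called[~true_de].sum() / max(called.sum(), 1)
        assert sensitivity >= 0.8
        assert fdr <= 0.05
        assert (res.loc[res["is_deg"] & true_de, "direction"] == "up").all()

    def test_summary_total_is_up_plus_down(self, sheet):
        rng = np.random.default_rng(2)
        data = {
            s: rng.poisson(100 * (4 if "HY" in s else 1), size=50)
            for s in sheet.sample_ids
        }
        m = GeneCountMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(50)]))
        res = call_degs(m, sheet, ("FP1", "HY1"))
        summary = deg_summary(res)
        assert (summary["n_deg"] == summary["up"] + summary["down"]).all()


class TestDegOverlap:
    def test_identical_sets_fill_full_intersection(self):
        genes = {"g1", "g2"}
        out = deg_overlap({"a": genes, "b": genes})
        full = out.set_index("region").loc["a&b", "exclusive_count"]
        assert full == 2
        assert out["exclusive_count"].sum() == 2

    def test_disjoint_sets(self):
        out = deg_overlap({"a": {"g1"}, "b": {"g2"}})
        assert out.set_index("region").loc["a", "exclusive_count"] == 1
        assert out.set_index("region").loc["b", "exclusive_count"] == 1

    def test_four_random_sets_match_brute_force(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(100)]
        sets = {
            name: {g for g in genes if rng.random() < 0.4}
            for name in ("a", "b", "c", "d")
        }
        out = deg_overlap(sets).set_index("region")["exclusive_count"]
        for g in set().union(*sets.values()):
            region = "&".join(n for n in sorted(sets) if g in sets[n])
            assert out[region] >= 1  # every gene's region exists
        assert out.sum() == len(set().union(*sets.values()))

    def test_rejects_more_than_four_sets(self):
        with pytest.raises(ValidationError):
            deg_overlap({str(i): {"g"} for i in range(5)})
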