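"""Low-expression filtering, error-model z-transform, consistent-top
selection and the triple-random-draw FDR estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirmkit import expression as ex
from sirmkit import synthetic as sy


def make_eset(frames):
    exps = []
    for i, df in enumerate(frames):
        roles = {c: ("sample" if c.startswith("s") else "control") for c in df.columns}
        exps.append(ex.Experiment(f"exp{i + 1}", df, roles))
    return ex.ExperimentSet(exps)


def brute_force_select(z: pd.DataFrame, q: float) -> set:
    """Independent per-gene oracle for the consistent-top selection."""
    thresholds = {}
    for col in z.columns:
        absz = sorted(abs(v) for v in z[col])
        thresholds[col] = float(np.quantile(absz, 1.0 - q))
    chosen = set()
    for gene in z.index:
        vals = [z.loc[gene, col] for col in z.columns]
        in_top = all(abs(v) >= thresholds[col] for v, col in zip(vals, z.columns))
        signs = {np.sign(v) for v in vals}
        if in_top and len(signs) == 1:
            chosen.add(gene)
    return chosen


class TestFilterLowExpression:
    def _fixture(self):
        # 10 genes; G0 below the median everywhere, G9 above in exactly one sample
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            rng.uniform(5, 10, (10, 4)),
            index=[f"G{i}" for i in range(10)],
            columns=["s1", "s2", "c1", "c2"],
        )
        data.loc["G0"] = 0.0
        data.loc["G9"] = 0.0
        data.loc["G9", "s2"] = 100.0
        return make_eset([data])

    def test_consistently_low_removed_single_high_retained(self):
        filtered = ex.filter_low_expression(self._fixture())
        assert "G0" not in filtered.genes
        assert "G9" in filtered.genes

    def test_planted_low_count(self):
        # constructed so only the 10 planted genes sit below every median:
        # the other 90 equal the per-sample median exactly (not strictly below)
        data = pd.DataFrame(
            10.0, index=[f"G{i:03d}" for i in range(100)], columns=["s1", "c1", "c2"]
        )
        data.iloc[:10] = 0.5
        filtered = ex.filter_low_expression(make_eset([data]))
        assert len(filtered.genes) == 90

    def test_filter_is_idempotent(self):
        once = ex.filter_low_expression(self._fixture())
        twice = ex.filter_low_expression(once)
        assert list(once.genes) == list(twice.genes)


class TestAverageTechnicalReplicates:
    def test_mean_on_log2_scale(self):
        data = pd.DataFrame({"s_a": [4.0], "s_b": [6.0], "c_a": [3.0]}, index=["G0"])
        exp = ex.Experiment(
            "e", data,
            roles={"s_a": "sample", "s_b": "sample", "c_a": "control"},
            tech_groups={"s_a": "s", "s_b": "s", "c_a": "c"},
        )
        out = ex.average_technical_replicates(ex.ExperimentSet([exp]))
        assert out.experiments[0].data.loc["G0", "s"] == 5.0

    def test_replicate_order_irrelevant(self):
        data = pd.DataFrame({"r1": [4.0], "r2": [6.0], "c": [1.0]}, index=["G0"])
        roles = {"r1": "sample", "r2": "sample", "c": "control"}
        groups = {"r1": "s", "r2": "s", "c": "c"}
        a = ex.average_technical_replicates(
            ex.ExperimentSet([ex.Experiment("e", data, roles, groups)])
        )
        b = ex.average_technical_replicates(
            ex.ExperimentSet([ex.Experiment("e", data[["r2", "c", "r1"]], roles, groups)])
        )
        pd.testing.assert_frame_equal(
            a.experiments[0].data.sort_index(axis=1), b.experiments[0].data.sort_index(axis=1)
        )


class TestZTransform:
    def test_zero_fold_changes_give_zero_z(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(5, 10, 300)
        data = pd.DataFrame(
            {"s1": base, "c1": base}, index=[f"G{i}" for i in range(300)]
        )
        z = ex.z_transform(make_eset([data]), window=50)
        assert (z.z.to_numpy() == 0).all()

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(5, 10, 300)
        fc = rng.normal(0, 0.3, 300)
        idx = [f"G{i}" for i in range(300)]
        d1 = pd.DataFrame({"s1": base + fc, "c1": base}, index=idx)
        d2 = pd.DataFrame({"s1": base + fc + 1.0, "c1": base + 1.0}, index=idx)
        z1 = ex.z_transform(make_eset([d1]), window=50)
        z2 = ex.z_transform(make_eset([d2]), window=50)
        np.testing.assert_allclose(z1.fold_change.to_numpy(), z2.fold_change.to_numpy(), atol=1e-9)

    def test_homoscedastic_sigma_recovery(self):
        """Rolling MAD recovers a flat sigma; tight bound needs a wide window."""
        rng = np.random.default_rng(42)
        n, sigma = 5000, 0.5
        base = rng.uniform(6, 14, n)
        fc = rng.normal(0, sigma, n)
        data = pd.DataFrame(
            {"s1": base + fc, "c1": base}, index=[f"G{i}" for i in range(n)]
        )
        z = ex.z_transform(make_eset([data]), window=2000)
        rel = np.abs(z.sigma["exp1"].to_numpy() - sigma) / sigma
        assert rel.max() < 0.10
        z_narrow = ex.z_transform(make_eset([data]), window=200)
        rel_narrow = np.abs(z_narrow.sigma["exp1"].to_numpy() - sigma) / sigma
        assert np.median(rel_narrow) < 0.10

    def test_window_too_large_errors(self):
        data = pd.DataFrame({"s1": [1.0, 2.0], "c1": [1.0, 2.0]}, index=["G0", "G1"])
        with pytest.raises(ValueError, match="window"):
            ex.z_transform(make_eset([data]), window=10)

    def test_user_sigma_table_overrides(self):
        idx = ["G0", "G1"]
        data = pd.DataFrame({"s1": [2.0, 3.0], "c1": [1.0, 1.0]}, index=idx)
        sigma = pd.Series([0.5, 2.0], index=idx)
        z = ex.z_transform(make_eset([data]), window=2, sigma_table={"exp1": sigma})
        assert z.z.loc["G0", "exp1"] == pytest.approx(2.0)
        assert z.z.loc["G1", "exp1"] == pytest.approx(1.0)


grid_values = st.sampled_from([-3.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 3.0])


class TestSelectConsistentTop:
    def test_single_dominant_gene(self):
        rng = np.random.default_rng(4)
        z = pd.DataFrame(
            rng.normal(0, 1, (10, 3)), index=[f"G{i}" for i in range(10)], columns=list("abc")
        )
        z.loc["G5"] = [10.0, 11.0, 12.0]
        sel = ex.select_consistent_top(z, q=0.10)
        assert brute_force_select(z, 0.10) == set(sel.genes)
        assert "G5" in sel.genes

    def test_top_in_only_two_of_three_not_selected(self):
        z = pd.DataFrame(
            {"a": [10.0, 1.0, 0.1], "b": [10.0, 1.0, 0.1], "c": [1.0, 10.0, 0.1]},
            index=["G0", "G1", "G2"],
        )
        sel = ex.select_consistent_top(z, q=0.34)
        assert "G0" not in sel.genes
        assert set(sel.genes) == brute_force_select(z, 0.34)

    def test_sign_inconsistency_excluded(self):
        z = pd.DataFrame({"a": [5.0, 0.1], "b": [5.0, 0.1], "c": [-5.0, 0.1]},
                         index=["G0", "G1"])
        sel = ex.select_consistent_top(z, q=0.5)
        assert "G0" not in sel.genes

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        st.integers(2, 12).flatmap(
            lambda n: st.lists(
                st.tuples(grid_values, grid_values, grid_values), min_size=n, max_size=n
            )
        ),
        st.sampled_from([0.05, 0.10, 0.25]),
    )
    def test_matches_exhaustive_oracle(self, rows, q):
        """Agreement with a per-gene brute-force oracle on small z tables."""
        z = pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))], columns=list("abc"))
        sel = ex.select_consistent_top(z, q=q)
        assert set(sel.genes) == brute_force_select(z, q)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.tuples(grid_values, grid_values, grid_values), min_size=5, max_size=12),
        st.floats(0.5, 5.0),
    )
    def test_invariant_to_rescaling_one_experiment(self, rows, scale):
        z = pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))], columns=list("abc"))
        scaled = z.copy()
        scaled["b"] = scaled["b"] * scale
        s1 = ex.select_consistent_top(z, q=0.25)
        s2 = ex.select_consistent_top(scaled, q=0.25)
        assert set(s1.genes) == set(s2.genes)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(6)
        z = pd.DataFrame(rng.normal(0, 1, (200, 3)), columns=list("abc"),
                         index=[f"G{i}" for i in range(200)])
        s_strict = ex.select_consistent_top(z, q=0.05)
        s_loose = ex.select_consistent_top(z, q=0.10)
        assert set(s_strict.genes) <= set(s_loose.genes)


class TestEstimateFdr:
    def test_reproducible_single_draw(self):
        rng = np.random.default_rng(7)
        z = pd.DataFrame(rng.normal(0, 1, (500, 3)), columns=list("abc"))
        r1 = ex.estimate_fdr(z, n_draws=1, seed=9)
        r2 = ex.estimate_fdr(z, n_draws=1, seed=9)
        assert r1.null_counts.tolist() == r2.null_counts.tolist()

    def test_pure_null_reports_high_fdr(self):
        rng = np.random.default_rng(8)
        z = pd.DataFrame(rng.normal(size=(50_000, 3)), columns=list("abc"))
        rep = ex.estimate_fdr(z, n_draws=50, seed=10)
        assert rep.observed > 0
        assert rep.fdr >= 0.6

    def test_zero_observed_is_undefined(self):
        # two genes, opposite signs everywhere -> nothing consistently selected
        z = pd.DataFrame({"a": [1.0, -1.0], "b": [-1.0, 1.0], "c": [1.0, -1.0]})
        rep = ex.estimate_fdr(z, q=0.4, n_draws=5, seed=1)
        assert rep.observed == 0 and rep.fdr is None

    def test_planted_signal_low_fdr(self):
        eset, truth = sy.generate_expression_experiments(
            1000, 50, log2_effect=3.0, replicate_cv=0.15, seed=12
        )
        z = ex.z_transform(ex.filter_low_expression(eset), window=200)
        sel = ex.select_consistent_top(z)
        rep = ex.estimate_fdr(z, n_draws=100, seed=13)
        fdp = 1.0 - truth.loc[sel.genes, "regulated"].mean()
        assert rep.fdr < 0.1
        assert abs(rep.fdr - fdp) < 0.05


class TestRankKnockdownTarget:
    def test_minimum_gets_rank_one(self):
        z = pd.DataFrame({"a": [-5.0, 0.0, 1.0], "b": [-4.0, 0.5, 1.0]},
                         index=["HIF1A", "G1", "G2"])
        out = ex.rank_knockdown_target(z, "HIF1A")
        assert out["per_experiment"] == {"a": 1, "b": 1}
        assert out["pooled"] == 1
        assert not out["tied"]

    def test_tie_flagged_with_min_rank(self):
        z = pd.DataFrame({"a": [-5.0, -5.0, 1.0]}, index=["G0", "G1", "G2"])
        out = ex.rank_knockdown_target(z, "G0")
        assert out["per_experiment"]["a"] == 1
        assert out["tied"]

    def test_planted_knockdown_ranks_top(self):
        eset, _ = sy.generate_expression_experiments(
            1000, 0, log2_effect=0.0, replicate_cv=0.2, seed=14
        )
        # plant an 8-fold (log2 = 3) knock-down of one gene in every experiment
        for exp in eset.experiments:
            exp.data.loc["G00000", "sample"] = exp.data.loc["G00000", "control"] - 3.0
        z = ex.z_transform(eset, window=200)
        out = ex.rank_knockdown_target(z, "G00000")
        assert out["pooled"] <= 5

    def test_absent_gene_errors(self):
        z = pd.DataFrame({"a": [0.0]}, index=["G0"])
        with pytest.raises(KeyError):
            ex.rank_knockdown_target(z, "missing")
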