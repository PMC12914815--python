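"""Scoring, residualization and group-comparison behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bridgenet import (
    CohortTable,
    CovariateSpec,
    LayerSpec,
    compute_gsi,
    group_compare,
    isi_category,
    residualize,
)


class TestCompositeScores:
    @pytest.mark.parametrize(
        "anx,som,dep,expected",
        [
            (2.74, 2.54, 2.83, 8.11),  # subscale means sum to the GSI mean
            (0, 0, 0, 0.0),
            (23, 19, 21, 63.0),  # per-scale maxima
        ],
    )
    def test_gsi_is_subscale_sum(self, anx, som, dep, expected):
        assert compute_gsi(anx, som, dep) == pytest.approx(expected)

    def test_gsi_vectorized(self):
        out = compute_gsi([1, 2], [3, 4], [5, 6])
        np.testing.assert_allclose(out, [9.0, 12.0])

    def test_gsi_rejects_negative(self):
        with pytest.raises(ValueError):
            compute_gsi(-1, 0, 0)

    @pytest.mark.parametrize(
        "score,band",
        [
            (0, "none"), (7, "none"),
            (8, "subthreshold"), (14, "subthreshold"),
            (15, "moderate"), (21, "moderate"),
            (22, "severe"), (28, "severe"),
        ],
    )
    def test_isi_bands(self, score, band):
        assert isi_category(score) == band

    @pytest.mark.parametrize("bad", [-1, 29, 7.5])
    def test_isi_rejects_out_of_range_or_noninteger(self, bad):
        with pytest.raises(ValueError):
            isi_category(bad)


def _table(values: pd.DataFrame, covariates: pd.DataFrame) -> CohortTable:
    spec = LayerSpec({c: ("a" if i % 2 == 0 else "b") for i, c in enumerate(values.columns)})
    return CohortTable(values=values, covariates=covariates, layer_spec=spec)


class TestResidualize:
    def test_perfect_collinearity_gives_zero_residuals(self):
        t = _table(
            pd.DataFrame({"x": [1.0, 2, 3], "y": [0.0, 1, 0]}),
            pd.DataFrame({"age": [1.0, 2, 3]}),
        )
        out = residualize(t, CovariateSpec({"x": ("age",), "y": ()}))
        np.testing.assert_allclose(out.values["x"], 0.0, atol=1e-12)

    def test_intercept_only_is_centering(self):
        t = _table(
            pd.DataFrame({"x": [1.0, 2, 6], "y": [1.0, 1, 4]}),
            pd.DataFrame({"age": [0.0, 0, 0]}).assign(age=[30.0, 40, 50]),
        )
        out = residualize(t, CovariateSpec({"x": (), "y": ()}))
        np.testing.assert_allclose(out.values["x"], [1, 2, 6] - np.mean([1, 2, 6]))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=20)
        c1, c2 = rng.normal(size=20), rng.normal(size=20)
        t = _table(
            pd.DataFrame({"x": y, "z": rng.normal(size=20)}),
            pd.DataFrame({"age": c1, "tiv": c2}),
        )
        out = residualize(t, CovariateSpec({"x": ("age", "tiv"), "z": ()}))
        X = np.column_stack([np.ones(20), c1, c2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # explicit normal equations
        np.testing.assert_allclose(out.values["x"], y - X @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, default_table):
        from bridgenet import default_covariate_spec

        spec = default_covariate_spec(default_table.layer_spec)
        out = residualize(default_table, spec)
        age = default_table.covariates["age"].to_numpy()
        for node in out.node_names:
            r = out.values[node].to_numpy()
            assert abs(r @ age) < 1e-6 * max(1.0, abs(age).sum())
            assert abs(r.sum()) < 1e-7

    def test_idempotent(self, default_table):
        from bridgenet import default_covariate_spec

        spec = default_covariate_spec(default_table.layer_spec)
        once = residualize(default_table, spec)
        twice = residualize(once, spec)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10
        )

    def test_variance_never_increases(self, default_table):
        from bridgenet import default_covariate_spec

        out = residualize(default_table, default_covariate_spec(default_table.layer_spec))
        for node in out.node_names:
            assert out.values[node].var() <= default_table.values[node].var() + 1e-12

    def test_single_site_with_site_in_spec_errors(self):
        t = _table(
            pd.DataFrame({"x": [1.0, 2, 3, 1], "y": [0.0, 1, 0, 2]}),
            pd.DataFrame({"age": [1.0, 2, 3, 4], "site": ["s1"] * 4}),
        )
        # dummy expansion of a single-level factor yields no column, which is
        # fine; but a constant *continuous* covariate collides with the
        # intercept and must be named in the error
        t2 = _table(
            pd.DataFrame({"x": [1.0, 2, 3, 1], "y": [0.0, 1, 0, 2]}),
            pd.DataFrame({"age": [5.0, 5, 5, 5]}),
        )
        with pytest.raises(ValueError, match="x"):
            residualize(t2, CovariateSpec({"x": ("age",), "y": ()}))
        # single site: no dummies generated, residualization proceeds
        out = residualize(t, CovariateSpec({"x": ("age", "site"), "y": ()}))
        assert out.n == 4

    def test_unknown_covariate_rejected(self, default_table):
        with pytest.raises(ValueError, match="not"):
            residualize(default_table, CovariateSpec({"mh1": ("weight",)}))


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: monotonized p*m/rank from the largest."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestGroupCompare:
    def _tables(self, a: dict, b: dict):
        da, db = pd.DataFrame(a), pd.DataFrame(b)
        return da, db

    def test_identical_groups_null(self):
        g = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 2, 3, 3]})
        res = group_compare(g, g.copy())
        assert (res["t"] == 0).all()
        assert (res["p"] == 1).all() or np.allclose(res["p"], 1.0)
        assert not res["significant"].any()

    def test_bh_adjustment_matches_oracle_on_stated_vector(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(_bh_oracle(p), [0.05] * 5)

    def test_strong_effect_flagged(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"x": 10 + 0.01 * rng.normal(size=50)})
        b = pd.DataFrame({"x": 0 + 0.01 * rng.normal(size=50)})
        res = group_compare(a, b)
        assert res.loc["x", "significant"]
        assert res.loc["x", "p"] < 1e-10

    def test_zero_variance_reported_degenerate(self):
        a = pd.DataFrame({"x": [3.0] * 5, "y": [1.0, 2, 3, 4, 5]})
        b = pd.DataFrame({"x": [3.0] * 5, "y": [1.0, 2, 2, 4, 5]})
        res = group_compare(a, b)
        assert res.loc["x", "degenerate"]
        assert res.loc["x", "p"] == 1.0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_bh_never_decreases_p_and_matches_oracle(self, ps):
        from statsmodels.stats.multitest import multipletests

        p = np.array(ps)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, np.minimum(_bh_oracle(p), 1.0), atol=1e-12)
        assert (adj >= p - 1e-15).all()

    def test_mismatched_variables_rejected(self):
        with pytest.raises(ValueError):
            group_compare(pd.DataFrame({"x": [1.0, 2]}), pd.DataFrame({"y": [1.0, 2]}))
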