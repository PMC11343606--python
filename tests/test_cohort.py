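import numpy as np
import pandas as pd
import pytest

from stepsig.cohort import (
    km_logrank,
    multivariate_ols,
    stratify_by_metagene,
)
from stepsig.errors import InputError, ZeroEventsError

from ._oracles import (
    km_product_limit,
    logrank_observed_expected,
    ols_normal_equations,
)


class TestMultivariateOls:
    def test_exact_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        table = pd.DataFrame(
            {"response": x, "x": x, "noise": rng.normal(0, 1, 30)}
        )
        out = multivariate_ols(table, "response")
        assert out.loc["x", "coef"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["noise", "coef"] == pytest.approx(0.0, abs=1e-10)
        assert out.loc["const", "coef"] == pytest.approx(0.0, abs=1e-10)

    def test_normal_equations_oracle(self, rng):
        n = 40
        table = pd.DataFrame(
            {
                "response": rng.normal(0, 1, n),
                "age": rng.normal(60, 8, n),
                "stage": rng.integers(1, 5, n).astype(float),
                "score": rng.normal(0, 2, n),
            }
        )
        out = multivariate_ols(table, "response")
        design = np.column_stack(
            [np.ones(n), table["age"], table["stage"], table["score"]]
        )
        expected = ols_normal_equations(design, table["response"].to_numpy())
        np.testing.assert_allclose(
            out.loc[["const", "age", "stage", "score"], "coef"], expected,
            atol=1e-8,
        )

    def test_categorical_dummy_coding(self, rng):
        n = 24
        table = pd.DataFrame(
            {
                "response": rng.normal(0, 1, n),
                "location": rng.choice(["right", "left"], n),
            }
        )
        out = multivariate_ols(table, "response")
        # alphabetically first level ('left') is the reference
        assert "location_right" in out.index
        assert "location_left" not in out.index

    def test_confidence_interval_brackets_coef(self, rng):
        table = pd.DataFrame(
            {"response": rng.normal(0, 1, 30), "x": rng.normal(0, 1, 30)}
        )
        out = multivariate_ols(table, "response")
        assert (out["ci_low"] <= out["coef"]).all()
        assert (out["coef"] <= out["ci_high"]).all()

    def test_rank_deficient_names_columns(self, rng):
        x = rng.normal(0, 1, 20)
        table = pd.DataFrame(
            {"response": rng.normal(0, 1, 20), "a": x, "b": 2 * x}
        )
        with pytest.raises(InputError, match="b"):
            multivariate_ols(table, "response")

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"response": [1.0, 2.0], "x": [1.0, np.nan]})
        with pytest.raises(InputError, match="x"):
            multivariate_ols(table, "response")

    def test_too_few_samples(self, rng):
        table = pd.DataFrame(
            {"response": [1.0, 2.0], "a": [0.3, 1.0], "b": [1.0, 0.1]}
        )
        with pytest.raises(InputError):
            multivariate_ols(table, "response")

    def test_null_calibration(self):
        # independent-noise response: ~5% of covariate p-values below 0.05
        rejections, total = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {
                    "response": rng.normal(0, 1, 50),
                    "a": rng.normal(0, 1, 50),
                    "b": rng.normal(0, 1, 50),
                    "c": rng.normal(0, 1, 50),
                }
            )
            out = multivariate_ols(table, "response").drop(index="const")
            rejections += int((out["p"] < 0.05).sum())
            total += len(out)
        assert 0.02 <= rejections / total <= 0.08


class TestKmLogrank:
    def _table(self, times_a, events_a, times_b, events_b):
        return pd.DataFrame(
            {
                "time": list(times_a) + list(times_b),
                "event": list(events_a) + list(events_b),
                "stratum": ["A"] * len(times_a) + ["B"] * len(times_b),
            }
        )

    def test_identical_strata(self):
        t = [1.0, 2.0, 3.0]
        e = [True, True, False]
        out = km_logrank(self._table(t, e, t, e))
        assert out.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.p == pytest.approx(1.0)

    def test_worked_six_sample_example(self):
        ta, ea = [1.0, 3.0, 5.0], [True, True, False]
        tb, eb = [2.0, 4.0, 6.0], [True, True, True]
        out = km_logrank(self._table(ta, ea, tb, eb))
        expected = logrank_observed_expected(ta, ea, tb, eb)
        assert out.statistic == pytest.approx(expected, rel=1e-9)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            ta = rng.exponential(5, n).round(2) + 0.01
            tb = rng.exponential(3, n).round(2) + 0.01
            ea = rng.random(n) < 0.8
            eb = rng.random(n) < 0.8
            if ea.sum() + eb.sum() == 0:
                continue
            out = km_logrank(self._table(ta, ea, tb, eb))
            expected = logrank_observed_expected(ta, ea, tb, eb)
            assert out.statistic == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_km_curve_matches_product_limit(self, rng):
        times = rng.exponential(5, 15).round(1) + 0.1
        events = rng.random(15) < 0.7
        out = km_logrank(
            self._table(times, events, [99.0, 99.0], [True, True])
        )
        curve = out.curves["A"]
        expected = dict(km_product_limit(times.tolist(), events.tolist()))
        observed = dict(
            zip(
                curve.loc[curve["events"] > 0, "time"],
                curve.loc[curve["events"] > 0, "survival"],
            )
        )
        for t, s in expected.items():
            assert observed[t] == pytest.approx(s, rel=1e-12)

    def test_curve_shape_invariants(self, rng):
        times = rng.exponential(5, 20) + 0.1
        events = rng.random(20) < 0.6
        try:
            out = km_logrank(self._table(times, events, times + 1, events))
        except ZeroEventsError:
            return
        for curve in out.curves.values():
            surv = curve["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()  # non-increasing
            assert surv[0] <= 1.0 + 1e-12
            # steps only where events occur
            drops = np.where(np.diff(surv) < -1e-12)[0] + 1
            assert (curve["events"].to_numpy()[drops] > 0).all()

    def test_symmetric_under_relabeling(self):
        ta, ea = [1.0, 3.0, 5.0], [True, True, False]
        tb, eb = [2.0, 4.0, 6.0], [True, True, True]
        fwd = km_logrank(self._table(ta, ea, tb, eb))
        rev = km_logrank(self._table(tb, eb, ta, ea))
        assert fwd.statistic == pytest.approx(rev.statistic)
        assert fwd.p == pytest.approx(rev.p)

    def test_all_censored_stratum(self):
        out = km_logrank(
            self._table([1.0, 2.0, 3.0], [True, True, True],
                        [4.0, 5.0], [False, False])
        )
        assert np.isfinite(out.statistic)
        assert (out.curves["B"]["survival"] == 1.0).all()

    def test_zero_events_raises_with_curves(self):
        with pytest.raises(ZeroEventsError) as err:
            km_logrank(
                self._table([1.0, 2.0], [False, False], [3.0], [False])
            )
        assert set(err.value.curves) == {"A", "B"}

    def test_nonpositive_time_rejected(self):
        with pytest.raises(InputError):
            km_logrank(self._table([0.0, 1.0], [True, True], [2.0], [True]))

    def test_single_stratum_rejected(self):
        table = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [True, True], "stratum": ["A", "A"]}
        )
        with pytest.raises(InputError):
            km_logrank(table)


class TestStratifyByMetagene:
    def test_two_samples(self):
        matrix = pd.DataFrame(
            [[1.0, 3.0], [1.0, 3.0]], index=["g1", "g2"], columns=["lo", "hi"]
        )
        out = stratify_by_metagene(matrix, ["g1", "g2"])
        assert out.stratum["lo"] == "low"
        assert out.stratum["hi"] == "high"
        assert out.metagene["hi"] == pytest.approx(3.0)

    def test_all_equal_ties_go_low(self):
        matrix = pd.DataFrame(
            [[2.0, 2.0, 2.0]], index=["g"], columns=["a", "b", "c"]
        )
        out = stratify_by_metagene(matrix, ["g"])
        assert (out.stratum == "low").all()

    def test_gene_order_invariance(self, tiny_matrix, rng):
        base = stratify_by_metagene(tiny_matrix, ["gA", "gB", "gC"]).stratum
        for _ in range(10):
            perm = list(rng.permutation(["gA", "gB", "gC"]))
            assert stratify_by_metagene(tiny_matrix, perm).stratum.equals(base)

    def test_missing_reported(self, tiny_matrix):
        out = stratify_by_metagene(tiny_matrix, ["gA", "ghost"])
        assert out.missing_genes == ("ghost",)

    def test_empty_signature_rejected(self, tiny_matrix):
        with pytest.raises(InputError):
            stratify_by_metagene(tiny_matrix, ["ghost"])

    def test_median_split_sizes(self, rng):
        matrix = pd.DataFrame(
            rng.normal(0, 1, (5, 11)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(11)],
        )
        out = stratify_by_metagene(matrix, [f"g{i}" for i in range(5)])
        # with an odd cohort and continuous metagenes: 5 high, 6 low
        assert (out.stratum == "high").sum() == 5
        assert (out.stratum == "low").sum() == 6
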