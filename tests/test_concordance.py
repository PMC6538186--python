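import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivive.concordance import (
    ComparisonSet,
    DegenerateComparisonError,
    OrmseRecord,
    allocate_wins,
    aggregate_counts,
    build_comparisons,
    comparison_seed,
    evaluate_comparison,
    make_randomization_plan,
    ormse,
    pod10_aed10,
    residual_param_correlations,
    standardize,
)
from ivive.io_formats import AssayHit, EndpointDoseRecord


def make_comparison(n=8, seed=0, assay="A", endpoint="E"):
    rng = np.random.default_rng(seed)
    return ComparisonSet(
        assay_endpoint=assay,
        in_vivo_endpoint=endpoint,
        chemical_ids=[f"C{i}" for i in range(n)],
        doses=10 ** rng.uniform(-1, 2, n),
        ac50s=10 ** rng.uniform(-1, 2, n),
        study_lengths=np.full(n, 90.0),
    )


class TestStandardize:
    def test_hand_example(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateComparisonError):
            standardize([2.0, 2.0, 2.0])

    @given(st.lists(st.integers(min_value=-1000, max_value=1000), min_size=3,
                    max_size=40, unique=True))
    def test_mean_zero_sd_one(self, values):
        z = standardize([float(v) for v in values])
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestOrmse:
    def test_identity_zero(self):
        z = standardize([1.0, 2.0, 4.0])
        assert ormse(z, z) == 0.0

    def test_symmetry_in_arguments(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert ormse(standardize(x), standardize(y)) == pytest.approx(
            ormse(standardize(y), standardize(x)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ormse(np.zeros(3), np.zeros(4))

    def test_closed_form_vs_pearson(self, rng):
        # ormse^2 == ((n-1)/n) * (1 - r) for sample-sd standardization
        for _ in range(50):
            n = int(rng.integers(3, 100))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r = np.corrcoef(x, y)[0, 1]
            o = ormse(standardize(y), standardize(x))
            assert o**2 == pytest.approx((n - 1) / n * (1 - r), abs=1e-12)


class TestRandomizationPlan:
    def test_reproducible(self):
        comp = make_comparison()
        a = make_randomization_plan(comp, seed=99)
        b = make_randomization_plan(comp, seed=99)
        np.testing.assert_array_equal(a.permuted_indices, b.permuted_indices)

    def test_shapes(self):
        comp = make_comparison(n=7)
        plan = make_randomization_plan(comp, seed=1)
        assert plan.permuted_indices.shape == (10, 7)

    def test_uniform_resampling(self):
        from scipy.stats import chisquare
        comp = make_comparison(n=5)
        plan = make_randomization_plan(comp, seed=3, n_sets=2000)
        counts = np.bincount(plan.permuted_indices.ravel(), minlength=5)
        assert chisquare(counts).pvalue > 1e-4

    def test_per_comparison_seed_stable(self):
        assert comparison_seed(7, "A::E") == comparison_seed(7, "A::E")
        assert comparison_seed(7, "A::E") != comparison_seed(8, "A::E")
        assert comparison_seed(7, "A::E") != comparison_seed(7, "A::F")


class TestBuildComparisons:
    def _hits(self, chem_ids, assay="A"):
        return [AssayHit(c, assay, 1.0 + i, True, ())
                for i, c in enumerate(chem_ids)]

    def _records(self, chem_ids):
        return [
            EndpointDoseRecord(c, f"S{i}", "chronic", "sys", "nn", "liver",
                               2.0 + i, 730.0)
            for i, c in enumerate(chem_ids)
        ]

    def test_threshold_exclusion(self):
        ids = [f"C{i}" for i in range(4)]
        comps = build_comparisons(self._hits(ids), self._records(ids), min_n=5)
        assert comps == []

    def test_threshold_boundary(self):
        ids = [f"C{i}" for i in range(5)]
        comps = build_comparisons(self._hits(ids), self._records(ids), min_n=5)
        assert len(comps) == 1
        assert comps[0].n == 5

    def test_duplicate_ac50_takes_minimum(self):
        ids = [f"C{i}" for i in range(5)]
        hits = self._hits(ids) + [AssayHit("C0", "A", 0.1, True, ())]
        (comp,) = build_comparisons(hits, self._records(ids), min_n=5)
        assert comp.ac50s[comp.chemical_ids.index("C0")] == 0.1

    def test_pod_level(self):
        ids = [f"C{i}" for i in range(6)]
        pods = {c: 1.0 + i for i, c in enumerate(ids)}
        comps = build_comparisons(self._hits(ids), pods, min_n=5, level="pod")
        assert len(comps) == 1
        assert comps[0].in_vivo_endpoint == "POD"


class TestEvaluateAndWins:
    def _kappa_lookup(self, mapping):
        return lambda cid, length, label: mapping[cid]

    def test_perfect_model_zero_ormse(self, rng):
        n = 10
        kappas = {f"C{i}": float(10 ** rng.uniform(-2, 1)) for i in range(n)}
        ac50s = 10 ** rng.uniform(-1, 2, n)
        doses = np.array([ac50s[i] / kappas[f"C{i}"] for i in range(n)])
        comp = ComparisonSet("A", "E", [f"C{i}" for i in range(n)],
                             doses, ac50s, np.full(n, 90.0))
        plan = make_randomization_plan(comp, seed=5)
        for direction in ("forward", "reverse"):
            records = evaluate_comparison(
                comp, self._kappa_lookup(kappas), plan, direction, "L")
            pbtk_rec = [r for r in records if r.predictor == "pbtk"][0]
            assert pbtk_rec.ormse == pytest.approx(0.0, abs=1e-9)

    def test_untransformed_direction_symmetric(self, rng):
        comp = make_comparison(n=12, seed=4)
        kappas = {c: float(10 ** rng.uniform(-2, 1))
                  for c in comp.chemical_ids}
        plan = make_randomization_plan(comp, seed=5)
        fwd = evaluate_comparison(comp, self._kappa_lookup(kappas), plan,
                                  "forward", "L")
        rev = evaluate_comparison(comp, self._kappa_lookup(kappas), plan,
                                  "reverse", "L")
        u_f = [r.ormse for r in fwd if r.predictor == "untransformed"][0]
        u_r = [r.ormse for r in rev if r.predictor == "untransformed"][0]
        assert u_f == pytest.approx(u_r, abs=1e-12)

    def test_pbtk_directions_generally_differ(self, rng):
        # outlier-style fixture: one wild kappa decouples the directions
        n = 10
        kappas = {f"C{i}": 1.0 for i in range(n)}
        kappas["C0"] = 1e4
        ac50s = 10 ** rng.uniform(-1, 2, n)
        doses = 10 ** rng.uniform(0, 2, n)
        comp = ComparisonSet("A", "E", [f"C{i}" for i in range(n)],
                             doses, ac50s, np.full(n, 90.0))
        plan = make_randomization_plan(comp, seed=5)
        fwd = evaluate_comparison(comp, self._kappa_lookup(kappas), plan,
                                  "forward", "L")
        rev = evaluate_comparison(comp, self._kappa_lookup(kappas), plan,
                                  "reverse", "L")
        p_f = [r.ormse for r in fwd if r.predictor == "pbtk"][0]
        p_r = [r.ormse for r in rev if r.predictor == "pbtk"][0]
        assert p_f != pytest.approx(p_r, abs=1e-6)

    def test_random_uses_original_study_length(self):
        comp = ComparisonSet("A", "E", ["C0", "C1", "C2"],
                             [1.0, 2.0, 4.0], [1.0, 2.0, 4.0],
                             [10.0, 20.0, 30.0])
        seen = []

        def lookup(cid, length, label):
            seen.append((cid, length))
            return 1.0 if cid != "C9" else 2.0

        plan = make_randomization_plan(comp, seed=5, n_sets=1)
        plan.permuted_indices[:] = [[2, 0, 1]]
        evaluate_comparison(comp, lookup, plan, "forward", "L")
        # the random pass pairs substituted chemicals with original lengths
        assert ("C2", 10.0) in seen
        assert ("C0", 20.0) in seen
        assert ("C1", 30.0) in seen

    def test_allocate_wins_lowest(self):
        records = [
            OrmseRecord("pbtk", "forward", 0.5),
            OrmseRecord("untransformed", "forward", 0.8),
            OrmseRecord("random", "forward", 0.9, random_index=0),
        ]
        assert allocate_wins(records) == {0: "pbtk"}

    def test_allocate_wins_tie_priority(self):
        records = [
            OrmseRecord("pbtk", "forward", 0.8),
            OrmseRecord("untransformed", "forward", 0.9),
            OrmseRecord("random", "forward", 0.8, random_index=0),
        ]
        assert allocate_wins(records) == {0: "random"}
        records = [
            OrmseRecord("pbtk", "forward", 0.8),
            OrmseRecord("untransformed", "forward", 0.8),
            OrmseRecord("random", "forward", 0.8, random_index=0),
        ]
        assert allocate_wins(records) == {0: "untransformed"}

    def test_wins_conserved_per_set(self, rng):
        comps = [make_comparison(n=8, seed=s, assay=f"A{s}") for s in range(6)]
        kappas = {c: float(10 ** rng.uniform(-2, 1))
                  for comp in comps for c in comp.chemical_ids}
        lookup = self._kappa_lookup(kappas)
        counts = {i: 0 for i in range(10)}
        for comp in comps:
            plan = make_randomization_plan(comp, seed=11)
            records = evaluate_comparison(comp, lookup, plan, "forward", "L")
            for i in allocate_wins(records):
                counts[i] += 1
        assert all(v == len(comps) for v in counts.values())


class TestAggregateCounts:
    def _table(self, counts_by_set):
        rows = []
        for set_index, counts in enumerate(counts_by_set):
            for predictor, wins in counts.items():
                rows.append({"label": "L", "direction": "forward",
                             "set_index": set_index, "predictor": predictor,
                             "wins": wins})
        return pd.DataFrame(rows)

    def test_identical_counts_sd_zero(self):
        table = self._table([{"pbtk": 3, "random": 1, "untransformed": 2}] * 10)
        out = aggregate_counts(table)
        assert (out["sd_wins"] == 0).all()
        row = out[out.predictor == "pbtk"].iloc[0]
        assert row["median_wins"] == 3

    def test_median_of_1_to_10(self):
        table = self._table([
            {"pbtk": k, "random": 0, "untransformed": 0}
            for k in range(1, 11)
        ])
        out = aggregate_counts(table)
        assert out[out.predictor == "pbtk"]["median_wins"].iloc[0] == 5.5

    def test_fractions_sum_to_one(self):
        table = self._table([{"pbtk": 3, "random": 1, "untransformed": 2}] * 10)
        out = aggregate_counts(table)
        assert out["median_fraction"].sum() == pytest.approx(1.0)


class TestPod10:
    def test_single_value_degenerate_quantile(self):
        records, rmse, o = pod10_aed10({"C1": [7.0]}, {"C1": [7.0]})
        assert records[0].pod10 == 7.0
        assert rmse == 0.0

    def test_hand_interpolated_quantile(self):
        records, _, _ = pod10_aed10({"C1": [1.0, 10.0, 100.0]},
                                    {"C1": [5.0]}, q=0.1)
        assert records[0].pod10 == pytest.approx(2.8)

    def test_equal_sides_zero_errors(self):
        pods = {f"C{i}": [float(i + 1)] for i in range(5)}
        records, rmse, o = pod10_aed10(pods, pods)
        assert rmse == 0.0
        assert o == pytest.approx(0.0, abs=1e-12)


class TestResidualCorrelations:
    def _chem(self, cid, **kw):
        from ivive.chem_params import ChemicalRecord
        defaults = dict(id=cid, mw=300.0, logp=2.0, fup=0.3, clint_1=5.0)
        defaults.update(kw)
        return ChemicalRecord(**defaults)

    def _records(self, residuals):
        from ivive.concordance import PodComparisonRecord
        return [
            PodComparisonRecord(f"C{i}", pod10=10.0 ** r, aed10=1.0)
            for i, r in enumerate(residuals)
        ]

    def test_linear_in_logp_detected(self, rng):
        n = 60
        logps = rng.normal(2, 1, n)
        chems = {f"C{i}": self._chem(f"C{i}", logp=float(logps[i]))
                 for i in range(n)}
        records = self._records(2 * logps + rng.normal(0, 1e-8, n))
        cors = {c.parameter: c.abs_cor
                for c in residual_param_correlations(records, chems)}
        assert cors["logP"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_parameter_near_zero(self, rng):
        n = 200
        mws = rng.uniform(100, 500, n)
        chems = {f"C{i}": self._chem(f"C{i}", mw=float(mws[i]))
                 for i in range(n)}
        records = self._records(rng.normal(0, 1, n))
        cors = {c.parameter: c.abs_cor
                for c in residual_param_correlations(records, chems)}
        assert cors["MW"] < 0.2

    def test_bounds(self, rng):
        n = 30
        chems = {f"C{i}": self._chem(f"C{i}", logp=float(rng.normal(2, 1)),
                                     fup=float(rng.uniform(0.01, 1)))
                 for i in range(n)}
        records = self._records(rng.normal(0, 1, n))
        for c in residual_param_correlations(records, chems):
            assert 0.0 <= c.abs_cor <= 1.0
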