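"""z-score screening, Mann-Whitney comparison, univariate Cox against a
brute-force partial-likelihood oracle, and promoter pairing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from glioclass.io import ClinicalTable, OmicsMatrix, ProbeAnnotation
from glioclass.screen import (
    compare_selected_groups,
    compute_zscores,
    fit_univariate_cox,
    map_promoter_pairs,
    sample_random_pairs,
    screen_survival,
    select_differential,
)


def _matrix(arr, features=None, samples=None, layer="expression"):
    arr = np.asarray(arr, dtype=float)
    features = features or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return OmicsMatrix(layer=layer,
                       values=pd.DataFrame(arr, index=features, columns=samples))


def _subtypes(mapping):
    return pd.Series(mapping)


class TestComputeZscores:
    def test_worked_example(self):
        # values [1,2,3,4]; subtype = last two samples
        m = _matrix([[1, 2, 3, 4]])
        subs = _subtypes({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        z = compute_zscores(m, subs).set_index("subtype")
        row = z.loc["B"]
        assert row["pop_mean"] == pytest.approx(2.5)
        assert row["pop_sd"] == pytest.approx(1.1180, abs=1e-4)
        assert row["subtype_mean"] == pytest.approx(3.5)
        assert row["z"] == pytest.approx(0.8944, abs=1e-4)

    def test_subtype_mean_equal_population_mean_gives_zero(self):
        m = _matrix([[2.0, 4.0, 2.0, 4.0]])
        subs = _subtypes({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        z = compute_zscores(m, subs)
        assert np.allclose(z["z"], 0.0)

    def test_constant_feature_flagged_undefined(self):
        m = _matrix([[5, 5, 5, 5]])
        subs = _subtypes({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        z = compute_zscores(m, subs)
        assert z["undefined"].all()
        assert z["z"].isna().all()

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            arr = rng.uniform(0.0, 10.0, size=(20, 12))
            labels = rng.choice(["A", "B", "C"], size=12)
            samples = [f"s{i}" for i in range(12)]
            m = _matrix(arr, samples=samples)
            subs = _subtypes(dict(zip(samples, labels)))
            z = compute_zscores(m, subs)
            for _, row in z.iterrows():
                i = m.feature_ids.index(row["feature_id"])
                vals = arr[i]
                cols = labels == row["subtype"]
                expected = (vals[cols].mean() - vals.mean()) / vals.std()
                assert row["z"] == pytest.approx(expected, abs=1e-12)

    def test_unknown_sample_raises(self):
        m = _matrix([[1, 2]])
        with pytest.raises(ValueError, match="without subtype"):
            compute_zscores(m, _subtypes({"s0": "A"}))


class TestSelectDifferential:
    @staticmethod
    def _ztable(zs):
        return pd.DataFrame(
            {
                "feature_id": [f"G{i}" for i in range(len(zs))],
                "subtype": "A",
                "z": zs,
                "undefined": [not np.isfinite(v) for v in zs],
            }
        )

    def test_boundary_is_strict(self):
        per, union = select_differential(self._ztable([1.0, -1.0, 1.0001]))
        assert union == {"G2"}

    def test_negative_selection_in_one_subtype(self):
        t = pd.concat([
            self._ztable([0.5]),
            self._ztable([-1.5]).assign(subtype="B"),
        ])
        per, union = select_differential(t)
        assert per["B"]["down"] == {"G0"}
        assert union == {"G0"}
        assert per["A"]["up"] == set()

    def test_nonpositive_threshold_raises(self):
        with pytest.raises(ValueError):
            select_differential(self._ztable([0.0]), threshold=0)

    def test_null_selection_rate_matches_permutation_oracle(self):
        """Under a null simulation the per-subtype selection rate agrees with
        an empirical permutation recomputation on the same matrix."""
        from glioclass.synthetic import SimConfig, generate_dataset

        cfg = SimConfig(n_per_subtype=(40, 40, 40), n_genes=400, n_cpgs=10,
                        n_informative_pairs=5, expr_effect=0.0, cox_coef=0.0,
                        seed=5)
        expr, _, clin, _, _ = generate_dataset(cfg)
        z = compute_zscores(expr, clin.subtype_of)
        _, union = select_differential(z)
        observed_rate = len(union) / 400
        # permutation oracle: shuffle labels, recompute selection rate
        rng = np.random.default_rng(0)
        rates = []
        labels = clin.subtype_of.copy()
        for _ in range(5):
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            zp = compute_zscores(expr, perm)
            _, up = select_differential(zp)
            rates.append(len(up) / 400)
        assert observed_rate == pytest.approx(np.mean(rates), abs=0.05)


class TestMannWhitney:
    def test_identical_groups_symmetric(self):
        m = _matrix(np.tile([[1.0, 2.0]], (6, 1)))
        res = compare_selected_groups(m, {"G0", "G1", "G2"}, {"G3", "G4", "G5"})
        assert res.u == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_exact_enumeration_example(self):
        # means [1,2,3] vs [4,5,6]: U = 0, exact two-sided p = 2/20
        arr = np.array([[1], [2], [3], [4], [5], [6]], dtype=float)
        m = _matrix(arr)
        res = compare_selected_groups(m, {"G0", "G1", "G2"}, {"G3", "G4", "G5"})
        assert res.u == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1)

    def test_planted_effect_significant(self, default_cohort):
        _, (expr, _, clin, _, truth) = default_cohort
        z = compute_zscores(expr, clin.subtype_of)
        per, _ = select_differential(z)
        some = next(iter(per.values()))
        res = compare_selected_groups(expr, some["up"], some["down"])
        assert res.p_value < 0.001

    def test_empty_set_raises(self, tiny_expr):
        with pytest.raises(ValueError):
            compare_selected_groups(tiny_expr, set(), {"G1"})


def oracle_cox_coef(x, time, event, lo=-30.0, hi=30.0):
    """Brute-force maximizer of the no-ties Cox partial likelihood, written
    from the textbook definition (independent of the package solver)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def negloglik(b):
        ll = 0.0
        for i in range(len(x)):
            if event[i]:
                risk = time >= time[i]
                ll += b * x[i] - math.log(np.exp(b * x[risk]).sum())
        return -ll

    res = optimize.minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x), negloglik


class TestUnivariateCox:
    def test_matches_oracle_on_exhaustive_small_instances(self):
        """All no-tie instances with n <= 6: every 2+-event pattern, with a
        seeded continuous covariate per instance."""
        rng = np.random.default_rng(0)
        checked = 0
        for n in (4, 5, 6):
            times = np.arange(1.0, n + 1)
            for pattern in itertools.product([0, 1], repeat=n):
                if sum(pattern) < 2:
                    continue
                x = rng.normal(size=n)
                event = np.array(pattern)
                res = fit_univariate_cox(x, times, event)
                bound = 30.0 / x.std()
                b_star, negll = oracle_cox_coef(x, times, event, -bound, bound)
                if not res.converged:
                    # monotone likelihood: the oracle drifts to a huge effect
                    assert abs(b_star) * x.std() > 8
                    continue
                assert res.coef == pytest.approx(b_star, abs=1e-4)
                checked += 1
        assert checked > 50

    def test_binary_covariate_against_oracle(self):
        # x = [1,0,1,0] interleaves groups, so the likelihood has an interior
        # maximum; the [1,1,0,0] ordering by contrast is separable (the
        # likelihood is monotone in b) and must come back flagged
        times = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = fit_univariate_cox(x, times, event)
        b_star, _ = oracle_cox_coef(x, times, event)
        assert res.converged
        assert res.coef == pytest.approx(b_star, abs=1e-4)
        assert res.hr == pytest.approx(math.exp(res.coef))
        separable = fit_univariate_cox(np.array([1.0, 1.0, 0.0, 0.0]), times, event)
        assert not separable.converged
        assert math.isnan(separable.p_value)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        times = rng.exponential(scale=np.exp(-0.5 * x))
        event = rng.random(30) < 0.8
        a = fit_univariate_cox(x, times, event.astype(int))
        b = fit_univariate_cox(-x, times, event.astype(int))
        assert a.coef == pytest.approx(-b.coef, abs=1e-7)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_agrees_with_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        # integer-rounded times create ties; Efron handling on both sides
        times = np.maximum(np.round(rng.exponential(scale=20 * np.exp(-0.3 * x))), 1.0)
        event = (rng.random(60) < 0.8).astype(int)
        res = fit_univariate_cox(x, times, event)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"T": times, "E": event, "x": x}),
                duration_col="T", event_col="E")
        # lifelines' own stopping rule is looser than ours, hence 1e-4
        assert res.coef == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_null_false_positive_rate_within_binomial_bounds(self):
        """200 covariates independent of survival at n = 150: the p < 0.05
        rate stays inside the binomial 95% band around 0.05."""
        rng = np.random.default_rng(6)
        n = 150
        times = rng.exponential(scale=100, size=n)
        event = (rng.random(n) < 0.8).astype(int)
        hits = 0
        for _ in range(200):
            x = rng.normal(size=n)
            res = fit_univariate_cox(x, times, event)
            if res.converged and res.p_value < 0.05:
                hits += 1
        lo = 0.05 - 1.96 * math.sqrt(0.05 * 0.95 / 200)
        hi = 0.05 + 1.96 * math.sqrt(0.05 * 0.95 / 200)
        assert lo <= hits / 200 <= hi

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_univariate_cox(np.ones(5), np.arange(1.0, 6), np.ones(5, int))
        with pytest.raises(ValueError, match="no events"):
            fit_univariate_cox(np.arange(5.0), np.arange(1.0, 6), np.zeros(5, int))


class TestScreenSurvival:
    def test_alpha_one_keeps_all_converging(self, small_cohort):
        _, (expr, _, clin, _, truth) = small_cohort
        cand = set(list(truth.informative_gene_ids)[:10])
        selected, table = screen_survival(expr, clin, cand, alpha=1.0)
        assert selected == set(table.loc[table["converged"], "feature_id"])

    def test_constant_feature_excluded_not_fatal(self, tiny_clinical):
        arr = np.array([[3.0, 3.0, 3.0, 3.0], [1.0, 2.0, 3.0, 4.0]])
        m = _matrix(arr, features=["const", "ok"], samples=list("abcd"))
        m.values.columns = ["s1", "s2", "s3", "s4"]
        selected, table = screen_survival(m, tiny_clinical, {"const", "ok"}, alpha=1.0)
        assert "const" not in set(table.get("feature_id", []))
        assert "ok" in set(table["feature_id"])

    def test_recovers_planted_survival_features(self, default_cohort):
        _, (expr, _, clin, _, truth) = default_cohort
        selected, _ = screen_survival(expr, clin, truth.survival_feature_ids)
        sens = len(selected & truth.survival_feature_ids) / len(truth.survival_feature_ids)
        assert sens > 0.8


class TestPromoterPairs:
    @staticmethod
    def _annotation(rows):
        return ProbeAnnotation(
            records=pd.DataFrame(rows, columns=["cpg_id", "gene_id", "region"])
        )

    def test_promoter_kept_body_dropped_unselected_dropped(self):
        ann = self._annotation([
            ("cg1", "G1", "TSS200"),
            ("cg2", "G1", "Body"),
            ("cg3", "G2", "TSS1500"),
        ])
        pairs = map_promoter_pairs({"G1"}, {"cg1", "cg2", "cg3"}, ann)
        assert list(pairs.records.itertuples(index=False, name=None)) == [
            ("cg1", "G1", "TSS200")
        ]

    def test_order_invariance_and_dedup(self):
        rows = [("cg1", "G1", "TSS200"), ("cg2", "G2", "UTR5"),
                ("cg1", "G1", "TSS200")]
        a = map_promoter_pairs({"G1", "G2"}, {"cg1", "cg2"}, self._annotation(rows))
        b = map_promoter_pairs({"G2", "G1"}, {"cg2", "cg1"},
                               self._annotation(rows[::-1]))
        pd.testing.assert_frame_equal(a.records, b.records)
        assert len(a.records) == 2

    def test_empty_result_raises(self):
        ann = self._annotation([("cg1", "G1", "Body")])
        with pytest.raises(ValueError, match="empty integration set"):
            map_promoter_pairs({"G1"}, {"cg1"}, ann)


class TestSampleRandomPairs:
    def test_seed_reproducible(self, small_cohort):
        _, (expr, meth, _, _, _) = small_cohort
        a = sample_random_pairs(expr, meth, 10, 20, seed=3)
        b = sample_random_pairs(expr, meth, 10, 20, seed=3)
        assert a.gene_ids == b.gene_ids and a.cpg_ids == b.cpg_ids
        assert len(a.gene_ids) == 10 and len(a.cpg_ids) == 20

    def test_all_genes_selected_when_requested(self, small_cohort):
        _, (expr, meth, _, _, _) = small_cohort
        sel = sample_random_pairs(expr, meth, len(expr.feature_ids), 5, seed=0)
        assert sel.gene_ids == sorted(expr.feature_ids)

    def test_overlap_matches_hypergeometric_expectation(self, small_cohort):
        _, (expr, meth, _, _, truth) = small_cohort
        m = 40
        n_total = len(expr.feature_ids)
        k_info = len(truth.informative_gene_ids)
        overlaps = [
            len(set(sample_random_pairs(expr, meth, m, 5, seed=s).gene_ids)
                & truth.informative_gene_ids)
            for s in range(100)
        ]
        expected = m * k_info / n_total
        se = math.sqrt(m * (k_info / n_total) * (1 - k_info / n_total)) / 10
        assert np.mean(overlaps) == pytest.approx(expected, abs=4 * se)

    def test_oversized_request_raises(self, small_cohort):
        _, (expr, meth, _, _, _) = small_cohort
        with pytest.raises(ValueError):
            sample_random_pairs(expr, meth, len(expr.feature_ids) + 1, 5, seed=0)
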