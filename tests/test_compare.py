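"""Paired statistics, margin tests, letters, rankings, power."""

import numpy as np
import pandas as pd
import pytest

import gpcv
from gpcv.compare import (
    MarginConfig,
    RankingInconsistencyError,
    all_pairs_tests,
    bootstrap_ci,
    build_ranking,
    equivalence_letters,
    paired_differences,
    power_paired_vs_unpaired,
    run_tests,
    summarize_tasks,
    t_interval,
    table1_report,
)
from gpcv.crossval import CVResult, selection_intensity


def cv_from_scores(**model_scores) -> CVResult:
    """Wrap per-fold score vectors into a CVResult (k folds, 1 replicate)."""
    rows = []
    for name, scores in model_scores.items():
        for i, s in enumerate(np.asarray(scores)):
            rows.append(
                {"replicate": 0, "fold": i + 1, "model": name,
                 "accuracy": float(s), "mse": 0.0, "n_test": 10}
            )
    return CVResult(pd.DataFrame(rows), plan_seed=0, model_names=list(model_scores))


def stat_from_d(d, scale="accuracy"):
    """PairedStat built directly from a difference vector (t interval)."""
    cv = cv_from_scores(a=np.asarray(d, dtype=float), b=np.zeros(len(d)))
    return paired_differences(cv, "a", "b", scale=scale, ci="t")


class TestPairedDifferences:
    def test_self_comparison_is_degenerate_zero(self):
        scores = np.array([0.5, 0.52, 0.48, 0.51])
        cv = cv_from_scores(a=scores, b=scores)
        with pytest.warns(UserWarning):
            stat = paired_differences(cv, "a", "b")
        assert np.all(stat.d == 0)
        assert stat.mean_d == 0 and (stat.ci_low, stat.ci_high) == (0.0, 0.0)

    def test_variance_reduction_at_rho_08(self):
        # Var(a-b) = 2 sigma^2 (1-rho): at rho=0.8 the paired variance is a
        # fifth of the unpaired difference variance 2 sigma^2
        a, b = gpcv.sim_fold_scores(100, 100, 0.8, 0.5, 0.5, 1.0, seed=5)
        cv = cv_from_scores(a=a, b=b)
        stat = paired_differences(cv, "a", "b", ci="t")
        assert np.var(stat.d) == pytest.approx(0.4, rel=0.05)
        unpaired = np.var(a) + np.var(b)
        assert unpaired / np.var(stat.d) == pytest.approx(5.0, rel=0.1)

    def test_variance_identity_exact(self):
        a, b = gpcv.sim_fold_scores(2, 10, 0.6, 0.4, 0.38, 0.05, seed=6)
        cv = cv_from_scores(a=a, b=b)
        d = paired_differences(cv, "a", "b", ci="t").d
        lhs = np.var(d)
        rhs = np.var(a) + np.var(b) - 2 * np.cov(a, b, ddof=0)[0, 1]
        assert lhs == pytest.approx(rhs, abs=1e-14)

    def test_gain_scale_multiplies_by_intensity(self):
        a, b = gpcv.sim_fold_scores(1, 10, 0.5, 0.5, 0.45, 0.05, seed=7)
        cv = cv_from_scores(a=a, b=b)
        acc = paired_differences(cv, "a", "b", ci="t")
        gain = paired_differences(cv, "a", "b", scale="genetic_gain", q=0.1, ci="t")
        assert gain.mean_d == pytest.approx(selection_intensity(0.1) * acc.mean_d)

    def test_replicate_averaged_variant(self):
        a, b = gpcv.sim_fold_scores(4, 10, 0.5, 0.5, 0.45, 0.05, seed=8)
        rows = []
        for i in range(40):
            rows.append({"replicate": i // 10, "fold": i % 10 + 1, "model": "a",
                         "accuracy": a[i], "mse": 0.0, "n_test": 10})
            rows.append({"replicate": i // 10, "fold": i % 10 + 1, "model": "b",
                         "accuracy": b[i], "mse": 0.0, "n_test": 10})
        cv = CVResult(pd.DataFrame(rows), 0, ["a", "b"])
        pooled = paired_differences(cv, "a", "b", ci="t")
        averaged = paired_differences(cv, "a", "b", ci="t", replicate_averaged=True)
        assert averaged.n_folds == 4  # one mean difference per replicate
        assert averaged.mean_d == pytest.approx(pooled.mean_d)
        # conservative: wider interval from r-1 degrees of freedom
        assert (averaged.ci_high - averaged.ci_low) > (pooled.ci_high - pooled.ci_low)

    def test_unmatched_folds_rejected(self):
        cv = cv_from_scores(a=np.arange(5.0), b=np.arange(4.0))
        with pytest.raises(ValueError):
            paired_differences(cv, "a", "b")


class TestBootstrapCI:
    def test_degenerate_sample(self):
        stat = stat_from_d(np.full(8, 0.03))
        with pytest.warns(UserWarning):
            lo, hi = bootstrap_ci(stat)
        assert lo == hi == pytest.approx(0.03)

    def test_agrees_with_t_interval_for_normal_data(self, rng):
        d = rng.normal(0.05, 0.02, size=200)
        stat = stat_from_d(d)
        blo, bhi = bootstrap_ci(stat, B=4000, seed=1)
        tlo, thi = t_interval(d, 0.95)
        assert (bhi - blo) == pytest.approx(thi - tlo, rel=0.10)
        assert blo == pytest.approx(tlo, abs=0.15 * (thi - tlo))

    def test_seeded_reproducibility(self, rng):
        stat = stat_from_d(rng.normal(0, 1, 30))
        assert bootstrap_ci(stat, seed=3) == bootstrap_ci(stat, seed=3)


class TestRunTests:
    def test_confidently_small_difference(self, rng):
        # mean 0.03, tight CI inside (-0.05, 0.05): equivalent AND
        # non-inferior, but not superior
        d = 0.03 + rng.normal(0, 0.01, 50)
        out = run_tests(stat_from_d(d), MarginConfig(delta=0.05))
        assert out["eq"].null_rejected
        assert out["noi"].null_rejected
        assert not out["sup"].null_rejected

    def test_confidently_large_difference(self, rng):
        # mean 0.09, tight CI above 0.05: superior (hence non-inferior),
        # not equivalent
        d = 0.09 + rng.normal(0, 0.01, 50)
        out = run_tests(stat_from_d(d), MarginConfig(delta=0.05))
        assert out["sup"].null_rejected
        assert out["noi"].null_rejected
        assert not out["eq"].null_rejected
        assert out["sd"].null_rejected

    def test_zero_margin_eq_undecidable(self, rng):
        d = rng.normal(0, 0.01, 20)
        with pytest.warns(UserWarning):
            out = run_tests(stat_from_d(d), MarginConfig(delta=0.0))
        assert not out["eq"].null_rejected

    def test_coherence_over_grid(self):
        # exhaustive (mean, spread, delta) grid: sup => noi and, for
        # delta > 0, eq => not sup; guaranteed by the shared CI machinery
        base = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5])  # mean 0
        for mean in np.linspace(-0.12, 0.12, 13):
            for spread in (1e-4, 1e-3, 1e-2, 0.1):
                d = mean + spread * base
                for delta in (0.01, 0.05, 0.1):
                    out = run_tests(stat_from_d(d), MarginConfig(delta=delta))
                    if out["sup"].null_rejected:
                        assert out["noi"].null_rejected
                    if out["eq"].null_rejected:
                        assert not out["sup"].null_rejected

    def test_eq_power_when_truly_equal(self):
        # true d = 0 with sd_d << delta: the equivalence test should almost
        # always reject its null
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(200):
            d = rng.normal(0.0, 0.005, size=30)
            out = run_tests(stat_from_d(d), MarginConfig(delta=0.03))
            rejections += out["eq"].null_rejected
        assert rejections >= 195


class TestLetters:
    def test_isolated_models_get_distinct_letters(self):
        letters = equivalence_letters(["m1", "m2", "m3"], {})
        assert sorted(letters.values()) == ["A", "B", "C"]

    def test_complete_graph_single_letter(self):
        models = ["m1", "m2", "m3"]
        eq = {frozenset((a, b)): True for a in models for b in models if a < b}
        letters = equivalence_letters(models, eq)
        assert set(letters.values()) == {"A"}

    def test_overlapping_cliques_share_letters(self):
        # path m1-m2-m3: two maximal cliques {m1,m2}, {m2,m3}
        eq = {frozenset(("m1", "m2")): True, frozenset(("m2", "m3")): True}
        letters = equivalence_letters(["m1", "m2", "m3"], eq)
        assert letters["m1"] != letters["m3"]
        assert set(letters["m2"]) == set(letters["m1"]) | set(letters["m3"])


class TestRanking:
    def test_no_rejections_all_tied(self):
        assert build_ranking(["a", "b"], {}) == {"a": 1, "b": 1}

    def test_chain(self):
        # c beats b beats a -> ordinals 1, 2, 3 (higher = superior)
        out = build_ranking(
            ["a", "b", "c"], {("c", "b"): True, ("b", "a"): True}, mode="sup"
        )
        assert out == {"a": 1, "b": 2, "c": 3}

    def test_cycle_raises(self):
        with pytest.raises(RankingInconsistencyError):
            build_ranking(["a", "b"], {("a", "b"): True, ("b", "a"): True})

    def test_relabeling_invariance(self):
        edges = {("c", "a"): True, ("c", "b"): True}
        r1 = build_ranking(["a", "b", "c"], edges)
        r2 = build_ranking(["c", "b", "a"], edges)
        assert r1 == r2


class TestPower:
    def test_perfect_correlation_boundary(self):
        paired, _ = power_paired_vs_unpaired(0.01, 0.05, 1.0, 10)
        assert paired == 1.0

    def test_unpaired_constant_in_rho(self):
        powers = {
            power_paired_vs_unpaired(0.03, 0.05, rho, 10)[1]
            for rho in (0.0, 0.4, 0.8)
        }
        assert len({round(p, 12) for p in powers}) == 1

    def test_paired_increasing_and_eventually_superior(self):
        rhos = np.linspace(0.05, 0.95, 10)
        paired = [power_paired_vs_unpaired(0.03, 0.05, r, 10)[0] for r in rhos]
        assert all(a < b for a, b in zip(paired, paired[1:]))
        unpaired = power_paired_vs_unpaired(0.03, 0.05, 0.9, 10)[1]
        assert paired[-1] > unpaired

    def test_monte_carlo_matches_analytic(self):
        # simulate fold-score pairs, t-test each replicate, compare the
        # rejection rate with the noncentral-t power (2 binomial SEs)
        rng = np.random.default_rng(11)
        true_d, sd, rho, k, alpha, n_rep = 0.03, 0.05, 0.8, 10, 0.05, 10_000
        cov = sd**2 * np.array([[1, rho], [rho, 1]])
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((n_rep, k, 2)) @ L.T
        d = z[:, :, 0] - z[:, :, 1] + true_d
        tstat = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(k))
        from scipy import stats as sps

        tcrit = sps.t.ppf(1 - alpha / 2, df=k - 1)
        emp = np.mean(np.abs(tstat) > tcrit)
        analytic = power_paired_vs_unpaired(true_d, sd, rho, k, alpha)[0]
        se = np.sqrt(analytic * (1 - analytic) / n_rep)
        assert abs(emp - analytic) < 2 * se + 1e-9


class TestSummaries:
    def test_single_pattern(self):
        tasks = [
            {"grp": "x", "sd": False, "eq": False, "noi": True, "sup": False}
            for _ in range(6)
        ]
        out = summarize_tasks(tasks, ["grp"])
        row = out.iloc[0]
        assert (row["prop_sd"], row["prop_eq"], row["prop_noi"], row["prop_sup"]) == (
            0.0, 0.0, 1.0, 0.0,
        )

    def test_fractions(self):
        tasks = [
            {"grp": "low", "sd": True, "eq": i == 0, "noi": True, "sup": False}
            for i in range(12)
        ] + [
            {"grp": "high", "sd": False, "eq": i < 4, "noi": True, "sup": False}
            for i in range(8)
        ]
        out = summarize_tasks(tasks, ["grp"]).set_index("grp")
        assert out.loc["low", "prop_eq"] == pytest.approx(1 / 12)
        assert out.loc["high", "prop_eq"] == pytest.approx(0.5)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            summarize_tasks([{"grp": "x", "sd": True}], ["grp"])


class TestReport:
    def test_table_structure_and_reference_row(self, rng):
        base = rng.normal(0.5, 0.02, 20)
        cv = cv_from_scores(
            ref=base, worse=base - 0.05 + rng.normal(0, 0.005, 20),
            better=base + 0.08 + rng.normal(0, 0.005, 20),
        )
        table = table1_report(
            cv, ["ref", "worse", "better"], "ref", MarginConfig(delta=0.02)
        )
        assert list(table.columns) == ["model", "mean", "lower", "upper", "sd", "eq", "sup"]
        ref_row = table[table["model"] == "ref"].iloc[0]
        assert ref_row["mean"] == 0.0
        ranks = table.set_index("model")["sup"]
        assert ranks["worse"] < ranks["ref"] < ranks["better"]

    def test_all_pairs_tests_cover_permutations(self, rng):
        cv = cv_from_scores(a=rng.normal(0.5, 0.02, 10), b=rng.normal(0.5, 0.02, 10))
        out = all_pairs_tests(cv, ["a", "b"], MarginConfig(delta=0.05))
        assert set(out) == {("a", "b"), ("b", "a")}

    def test_bonferroni_is_more_conservative(self, rng):
        base = rng.normal(0.5, 0.02, 20)
        cv = cv_from_scores(
            a=base, b=base + rng.normal(0.004, 0.008, 20),
            c=base + rng.normal(-0.004, 0.008, 20),
        )
        margin = MarginConfig(delta=0.05)
        plain = all_pairs_tests(cv, ["a", "b", "c"], margin)
        adj = all_pairs_tests(cv, ["a", "b", "c"], margin, bonferroni=True)
        for pair in plain:
            for t in ("sd", "eq", "noi", "sup"):
                # corrected rejections are a subset of uncorrected ones
                assert not adj[pair][t].null_rejected or plain[pair][t].null_rejected
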