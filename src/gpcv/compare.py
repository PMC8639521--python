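"""Paired model comparison with equivalence margins.

Given fold-level accuracy scores produced under a shared fold plan, this
module computes per-fold differences between two models, their mean with a
confidence interval (Student-t or bootstrap percentile), and four hypothesis
tests against a user-chosen equivalence margin ``[-delta, +delta]``:

* ``sd``  — statistical difference,   H0: d = 0;
* ``eq``  — equivalence,              H0: |d| > delta (TOST);
* ``noi`` — non-inferiority,          H0: d < -delta;
* ``sup`` — superiority,              H0: d < delta.

All four use the same t machinery, so the logical implications hold by
construction: a superiority rejection implies a non-inferiority rejection,
and (for delta > 0) equivalence and superiority cannot both be rejected.

From all-pairs test outcomes the module derives compact labels:
*equivalence letters* (one letter per maximal clique of the pairwise
equivalence graph — models sharing a letter are confidently equivalent) and
*non-inferiority / superiority ordinals* (a layering of the rejection
digraph; a higher ordinal means confidently superior).  It also provides the
analytic power comparison between paired and unpaired designs and
multi-task summary tables.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .crossval import CVResult, selection_intensity

__all__ = [
    "PairedStat",
    "MarginConfig",
    "TestOutcome",
    "ComparisonLabels",
    "paired_differences",
    "bootstrap_ci",
    "t_interval",
    "run_tests",
    "equivalence_letters",
    "build_ranking",
    "power_paired_vs_unpaired",
    "summarize_tasks",
    "all_pairs_tests",
    "table1_report",
]

TEST_NAMES = ("sd", "eq", "noi", "sup")


class RankingInconsistencyError(ValueError):
    """The rejection digraph contains a cycle; no consistent ranking exists."""


@dataclass
class MarginConfig:
    """Equivalence margin delta (on the scale of d) and test size alpha."""

    delta: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclass
class TestOutcome:
    test: str
    null_rejected: bool
    p_value: float
    ci_used: tuple[float, float]
    ci_level: float


@dataclass
class PairedStat:
    """Per-fold accuracy (or gain) differences a - b with summary statistics."""

    model_a: str
    model_b: str
    d: np.ndarray
    mean_d: float
    se_d: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    scale: str = "accuracy"

    @property
    def n_folds(self) -> int:
        return len(self.d)


@dataclass
class ComparisonLabels:
    letters: dict[str, str]
    noi_rank: dict[str, int] | None = None
    sup_rank: dict[str, int] | None = None


def paired_differences(
    cv: CVResult,
    a: str,
    b: str,
    scale: str = "accuracy",
    q: float | None = None,
    level: float = 0.95,
    ci: str = "bootstrap",
    B: int = 2000,
    seed: int = 0,
    replicate_averaged: bool = False,
) -> PairedStat:
    """Fold-by-fold accuracy differences between models a and b.

    Folds are matched on (replicate, fold) — the pairing produced by the
    shared :class:`~gpcv.crossval.FoldPlan`.  With ``scale="genetic_gain"``
    the differences are multiplied by the selection intensity ``i_q``, so
    the margin for the downstream tests can be stated in units of expected
    genetic gain per phenotypic standard deviation.

    By default all r*k fold differences are pooled as exchangeable.  Fold
    overlap across replicates makes them mildly dependent, so
    ``replicate_averaged=True`` offers a conservative alternative: one mean
    difference per replicate (r values, r-1 degrees of freedom downstream).
    """
    ra = cv.accuracies(a)
    rb = cv.accuracies(b)
    merged = ra.merge(rb, on=["replicate", "fold"], suffixes=("_a", "_b"))
    if len(merged) != len(ra) or len(merged) != len(rb):
        raise ValueError(f"models {a!r} and {b!r} were not evaluated on matched folds")
    if replicate_averaged:
        diffs = merged["accuracy_a"] - merged["accuracy_b"]
        d = diffs.groupby(merged["replicate"]).mean().to_numpy()
    else:
        d = (merged["accuracy_a"] - merged["accuracy_b"]).to_numpy()
    if scale == "genetic_gain":
        if q is None:
            raise ValueError("genetic_gain scale requires a selection quantile q")
        d = d * selection_intensity(q)
    elif scale != "accuracy":
        raise ValueError(f"unknown scale {scale!r}")
    mean_d = float(d.mean())
    se_d = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0
    stat = PairedStat(a, b, d, mean_d, se_d, mean_d, mean_d, level=level, scale=scale)
    if ci == "bootstrap":
        stat.ci_low, stat.ci_high = bootstrap_ci(stat, B=B, level=level, seed=seed)
    elif ci == "t":
        stat.ci_low, stat.ci_high = t_interval(d, level)
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return stat


def t_interval(d: np.ndarray, level: float) -> tuple[float, float]:
    """Two-sided Student-t interval for the mean of d."""
    d = np.asarray(d, dtype=float)
    m = float(d.mean())
    if len(d) < 2 or d.std(ddof=1) == 0:
        return (m, m)
    se = d.std(ddof=1) / np.sqrt(len(d))
    tq = stats.t.ppf(0.5 + level / 2.0, df=len(d) - 1)
    return (m - tq * se, m + tq * se)


def bootstrap_ci(
    stat: PairedStat, B: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap interval for the mean difference.

    Fold-level differences are resampled with replacement; a degenerate
    (all-equal) sample returns the point interval with a warning.
    """
    d = stat.d
    if np.ptp(d) == 0:
        warnings.warn("all fold differences are equal; degenerate interval")
        return (float(d[0]), float(d[0]))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(B, len(d)))
    means = d[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2.0, (1 + level) / 2.0])
    return (float(lo), float(hi))


def _one_sided_p(t_stat: float, df: int) -> float:
    """p-value for H1: parameter > bound, from its t statistic."""
    return float(stats.t.sf(t_stat, df=df))


def run_tests(stat: PairedStat, margin: MarginConfig) -> dict[str, TestOutcome]:
    """The four tests (sd, eq, noi, sup) on a paired difference.

    All are Student-t tests on the mean fold difference with n-1 degrees of
    freedom.  Equivalence uses two one-sided tests (TOST), which is the same
    decision as requiring the two-sided ``1 - 2 alpha`` interval to lie
    inside ``(-delta, +delta)``; non-inferiority and superiority compare the
    lower bound of that same interval against ``-delta`` and ``+delta``.
    The implications sup => noi and eq => not-sup (delta > 0) then hold for
    every input.
    """
    d = stat.d
    n = len(d)
    m = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    df = max(n - 1, 1)
    alpha = margin.alpha
    delta = margin.delta
    ci_2a = t_interval(d, 1.0 - 2.0 * alpha) if se > 0 else (m, m)
    ci_1a = t_interval(d, 1.0 - alpha) if se > 0 else (m, m)

    if se == 0.0:
        # degenerate: all fold differences identical; decide by position
        p_sd = 0.0 if m != 0 else 1.0
        p_noi = 0.0 if m > -delta else 1.0
        p_sup = 0.0 if m > delta else 1.0
        p_eq = 0.0 if (-delta < m < delta) else 1.0
    else:
        p_sd = float(2.0 * stats.t.sf(abs(m / se), df=df))
        p_noi = _one_sided_p((m + delta) / se, df)  # H0: d <= -delta
        p_sup = _one_sided_p((m - delta) / se, df)  # H0: d <= +delta
        p_hi = float(stats.t.cdf((m - delta) / se, df=df))  # H0: d >= +delta
        p_eq = max(p_noi, p_hi)  # TOST

    outcomes = {
        "sd": TestOutcome("sd", p_sd < alpha, p_sd, ci_1a, 1.0 - alpha),
        "noi": TestOutcome("noi", p_noi < alpha, p_noi, ci_2a, 1.0 - 2 * alpha),
        "sup": TestOutcome("sup", p_sup < alpha, p_sup, ci_2a, 1.0 - 2 * alpha),
    }
    if delta == 0.0:
        warnings.warn("delta = 0 makes the equivalence test undecidable")
        outcomes["eq"] = TestOutcome("eq", False, 1.0, ci_2a, 1.0 - 2 * alpha)
    else:
        outcomes["eq"] = TestOutcome("eq", p_eq < alpha, p_eq, ci_2a, 1.0 - 2 * alpha)
    return outcomes


def _letter_sequence(n: int) -> list[str]:
    letters = list(string.ascii_uppercase)
    while len(letters) < n:
        letters += [a + b for a, b in itertools.product(string.ascii_uppercase, repeat=2)]
    return letters[:n]


def equivalence_letters(
    models: list[str], eq_outcomes: dict[frozenset, bool] | dict[tuple, bool]
) -> dict[str, str]:
    """Compact letter display from pairwise equivalence rejections.

    An undirected graph joins two models when their equivalence null was
    rejected (they are confidently equivalent).  Each *maximal clique* gets
    one letter; a model's label concatenates the letters of the maximal
    cliques containing it.  Isolated models form singleton cliques and get a
    letter of their own.
    """
    graph = nx.Graph()
    graph.add_nodes_from(models)
    for pair, rejected in eq_outcomes.items():
        a, b = tuple(pair)
        if rejected and a != b:
            graph.add_edge(a, b)
    order = {m: i for i, m in enumerate(models)}
    cliques = sorted(
        (sorted(c, key=order.__getitem__) for c in nx.find_cliques(graph)),
        key=lambda c: [order[m] for m in c],
    )
    letters = _letter_sequence(len(cliques))
    labels: dict[str, list[str]] = {m: [] for m in models}
    for letter, clique in zip(letters, cliques):
        for m in clique:
            labels[m].append(letter)
    return {m: "".join(ls) for m, ls in labels.items()}


def build_ranking(
    models: list[str], directed_outcomes: dict[tuple[str, str], bool], mode: str = "sup"
) -> dict[str, int]:
    """Ordinal ranking from directed (non-)inferiority or superiority rejections.

    ``directed_outcomes[(a, b)] = True`` records that the test rejected its
    null for the ordered comparison (a, b) — i.e. a is confidently superior
    (mode ``"sup"``) or non-inferior (mode ``"noi"``) to b.  The rejection
    digraph must be acyclic; ordinals are assigned by layering (one plus the
    longest chain of beaten models below), so models that are incomparable
    in every topological order share an ordinal and a *higher* ordinal means
    confidently better.
    """
    if mode not in ("noi", "sup"):
        raise ValueError("mode must be 'noi' or 'sup'")
    graph = nx.DiGraph()
    graph.add_nodes_from(models)
    for (a, b), rejected in directed_outcomes.items():
        if rejected:
            graph.add_edge(b, a)  # points from beaten to beating model
    if not nx.is_directed_acyclic_graph(graph):
        cycle = [e[0] for e in nx.find_cycle(graph)]
        raise RankingInconsistencyError(
            f"cyclic {mode} rejections among {cycle}; no consistent ranking"
        )
    ordinal = {m: 1 for m in models}
    for node in nx.topological_sort(graph):
        for succ in graph.successors(node):
            ordinal[succ] = max(ordinal[succ], ordinal[node] + 1)
    return ordinal


def power_paired_vs_unpaired(
    true_d: float, sd_fold: float, rho: float, k: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Analytic power of detecting a fold-score difference, paired vs unpaired.

    Fold scores of the two models share variance ``sd_fold**2`` and
    correlate at ``rho`` across folds.  The paired design tests the k fold
    differences (variance ``2 sd_fold**2 (1 - rho)``) with a one-sample
    two-sided t test; the unpaired design tests two independent samples of k
    scores (difference variance ``2 sd_fold**2``, constant in rho).  Powers
    come from the noncentral-t distribution.
    """
    if sd_fold <= 0:
        raise ValueError("sd_fold must be positive")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")

    def _power(sigma_d: float, df: int) -> float:
        if sigma_d == 0.0:
            return 1.0 if true_d != 0 else alpha
        ncp = true_d / (sigma_d / np.sqrt(k))
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))

    paired = _power(np.sqrt(2.0 * (1.0 - rho)) * sd_fold, k - 1)
    unpaired = _power(np.sqrt(2.0) * sd_fold, 2 * k - 2)
    return paired, unpaired


def summarize_tasks(
    tasks: pd.DataFrame | list[dict], grouping: list[str]
) -> pd.DataFrame:
    """Per-group rejection proportions for the four tests across tasks.

    Each task row carries its grouping keys plus boolean columns ``sd``,
    ``eq``, ``noi``, ``sup`` (was the null rejected for that task).  Returns
    one row per group with the fraction of tasks rejecting each null — the
    bottom summary rows of a multi-dataset comparison table.
    """
    df = pd.DataFrame(tasks)
    missing = [c for c in (*grouping, *TEST_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in task table: {missing}")
    empty_groups = df.groupby(grouping, sort=False).size() == 0
    if empty_groups.any():
        warnings.warn(f"empty groups omitted: {list(empty_groups[empty_groups].index)}")
    out = (
        df.groupby(grouping, sort=False)[list(TEST_NAMES)]
        .mean()
        .reset_index()
        .rename(columns={t: f"prop_{t}" for t in TEST_NAMES})
    )
    return out


def all_pairs_tests(
    cv: CVResult,
    models: list[str],
    margin: MarginConfig,
    scale: str = "accuracy",
    q: float | None = None,
    bonferroni: bool = False,
) -> dict[tuple[str, str], dict[str, TestOutcome]]:
    """Run the four tests for every ordered model pair under one margin.

    No multiplicity correction is applied by default; ``bonferroni=True``
    divides alpha by the number of unordered pairs.
    """
    n_pairs = len(models) * (len(models) - 1) // 2
    alpha = margin.alpha / n_pairs if (bonferroni and n_pairs) else margin.alpha
    adjusted = MarginConfig(delta=margin.delta, alpha=alpha)
    out: dict[tuple[str, str], dict[str, TestOutcome]] = {}
    for a, b in itertools.permutations(models, 2):
        stat = paired_differences(cv, a, b, scale=scale, q=q, ci="t")
        out[(a, b)] = run_tests(stat, adjusted)
    return out


def table1_report(
    cv: CVResult,
    models: list[str],
    reference: str,
    margin: MarginConfig,
    scale: str = "accuracy",
    q: float | None = None,
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-comparison report against a reference model.

    One row per model with the mean fold difference to the reference and its
    bootstrap interval, conventional significance letters (models share a
    letter when the sd null was *not* rejected for the pair), equivalence
    letters (shared letter = confidently equivalent) and the superiority
    ordinal (higher = confidently superior), all derived from all-pairs
    paired tests at the supplied margin.
    """
    if reference not in models:
        raise ValueError(f"reference {reference!r} not among models")
    pairwise = all_pairs_tests(cv, models, margin, scale=scale, q=q)
    eq_edges = {
        frozenset(p): o["eq"].null_rejected for p, o in pairwise.items() if p[0] < p[1]
    }
    sd_nonsig = {
        frozenset(p): not o["sd"].null_rejected
        for p, o in pairwise.items()
        if p[0] < p[1]
    }
    sup_edges = {p: o["sup"].null_rejected for p, o in pairwise.items()}
    eq_letters = equivalence_letters(models, eq_edges)
    sd_letters = {
        m: v.lower() for m, v in equivalence_letters(models, sd_nonsig).items()
    }
    sup_rank = build_ranking(models, sup_edges, mode="sup")

    rows = []
    for i, m in enumerate(models):
        if m == reference:
            mean = 0.0
            lo = hi = float("nan")
        else:
            stat = paired_differences(
                cv, m, reference, scale=scale, q=q, B=B, seed=seed + i
            )
            mean, lo, hi = stat.mean_d, stat.ci_low, stat.ci_high
        rows.append(
            {
                "model": m,
                "mean": mean,
                "lower": lo,
                "upper": hi,
                "sd": sd_letters[m],
                "eq": eq_letters[m],
                "sup": sup_rank[m],
            }
        )
    return pd.DataFrame(rows).sort_values(["sup", "mean"]).reset_index(drop=True)
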