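"""Replicated k-fold cross validation with shared fold plans.

The pairing device of the whole package lives here: a :class:`FoldPlan`
fixes r random partitions of the n lines into k near-equal folds, and
:func:`run_paired_cv` evaluates *every* candidate model on exactly the same
train/test splits.  Per-fold predictive accuracy is the Pearson correlation
between predictions and observed phenotypes — invariant to the scale and
location shifts that inflate MSE without changing rankings (MSE is recorded
too, as a secondary measure).

Accuracy measured against phenotypes understates accuracy against the
(unobserved) genetic values by a factor of the square root of heritability;
:func:`rescale_by_heritability` applies that correction, and
:func:`to_genetic_gain` converts accuracy to expected genetic gain per
phenotypic standard deviation under truncation selection,
``DeltaG / sigma_P = i_q * r_ph``, with ``i_q`` the selection intensity at
selected fraction q.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import Kernel
from .models import (
    PriorSpec,
    elicit_prior,
    fit_bayes,
    fit_kernel_reml,
    predict_bayes,
    predict_kernel,
)

__all__ = [
    "FoldPlan",
    "CVResult",
    "GainScale",
    "ModelSpec",
    "make_fold_plan",
    "fold_accuracy",
    "run_paired_cv",
    "estimate_h2_reml",
    "rescale_by_heritability",
    "selection_intensity",
    "to_genetic_gain",
]


class UndefinedAccuracyError(ValueError):
    """A fold where the correlation is undefined (zero variance)."""


@dataclass
class FoldPlan:
    """r replicates x k folds over n cases, reproducible from its seed.

    ``assignment[rep][i]`` is the 1-based fold of case ``i`` in replicate
    ``rep``.
    """

    n: int
    k: int
    r: int
    seed: int
    assignment: np.ndarray  # (r, n) of folds in 1..k

    def test_indices(self, rep: int, fold: int) -> np.ndarray:
        return np.where(self.assignment[rep] == fold)[0]

    def train_indices(self, rep: int, fold: int) -> np.ndarray:
        return np.where(self.assignment[rep] != fold)[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n": self.n,
                    "k": self.k,
                    "r": self.r,
                    "seed": self.seed,
                    "assignment": self.assignment.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["n"], d["k"], d["r"], d["seed"], np.asarray(d["assignment"]))


def make_fold_plan(n: int, k: int, r: int = 1, seed: int = 0) -> FoldPlan:
    """Randomly partition n cases into k near-equal folds, r times.

    Fold sizes differ by at most one; the first ``n mod k`` folds of each
    replicate receive the extra case.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if r < 1:
        raise ValueError("r must be >= 1")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    assignment = np.empty((r, n), dtype=np.int64)
    for rep in range(r):
        perm = rng.permutation(n)
        start = 0
        for fold, size in enumerate(sizes, start=1):
            assignment[rep, perm[start : start + size]] = fold
            start += size
    return FoldPlan(n=n, k=k, r=r, seed=seed, assignment=assignment)


def fold_accuracy(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation between predictions and observations on one fold."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("pred and obs must be equal-length vectors of length >= 3")
    if np.isnan(pred).any() or np.isnan(obs).any():
        raise ValueError("NaN in fold predictions or observations")
    if pred.std() == 0 or obs.std() == 0:
        raise UndefinedAccuracyError("zero variance in predictions or observations")
    return float(np.corrcoef(pred, obs)[0, 1])


@dataclass
class ModelSpec:
    """One candidate model in a paired comparison.

    kind:
      * ``"kernel"`` — REML mixed model on ``kernels`` (full n x n matrices,
        sliced per fold so centering never changes between folds);
      * ``"bayes"`` — Bayesian-alphabet regression on the marker matrix
        ``X`` with prior ``prior`` (MCMC settings in ``mcmc``);
      * ``"oracle"`` — a fixed vector of values (e.g. the true genetic
        values of a simulated trait) used directly as predictions.
    """

    name: str
    kind: str
    kernels: list[Kernel] | None = None
    X: np.ndarray | None = None
    prior: PriorSpec | None = None
    values: np.ndarray | None = None
    mcmc: dict = field(default_factory=lambda: {"iters": 3000, "burnin": 500, "thin": 5})

    def __post_init__(self) -> None:
        if self.kind not in ("kernel", "bayes", "oracle"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "kernel" and not self.kernels:
            raise ValueError(f"{self.name}: kernel model needs kernels")
        if self.kind == "bayes" and self.X is None:
            raise ValueError(f"{self.name}: bayes model needs a marker matrix")
        if self.kind == "oracle" and self.values is None:
            raise ValueError(f"{self.name}: oracle model needs a value vector")


@dataclass
class CVResult:
    """Tidy per-(replicate, fold, model) records plus provenance."""

    records: pd.DataFrame  # replicate, fold, model, accuracy, mse, n_test
    plan_seed: int
    model_names: list[str]
    failed_folds: list[tuple[int, int, str]] = field(default_factory=list)
    predictions: pd.DataFrame | None = None  # replicate, model, case, pred, obs

    def accuracies(self, model: str) -> pd.DataFrame:
        out = self.records[self.records["model"] == model]
        if out.empty:
            raise KeyError(f"model {model!r} not present in CV result")
        return out.sort_values(["replicate", "fold"]).reset_index(drop=True)

    def mean_accuracy(self, model: str) -> float:
        """Primary summary: unweighted mean of per-fold accuracies."""
        return float(self.accuracies(model)["accuracy"].mean())

    def pooled_accuracy(self, model: str) -> float:
        """Secondary summary: correlation of all held-out predictions with
        their observations, pooled within replicate, averaged over replicates."""
        if self.predictions is None:
            raise ValueError("this CV result was loaded without predictions")
        sub = self.predictions[self.predictions["model"] == model]
        if sub.empty:
            raise KeyError(f"model {model!r} not present in CV result")
        per_rep = sub.groupby("replicate").apply(
            lambda g: np.corrcoef(g["pred"], g["obs"])[0, 1], include_groups=False
        )
        return float(per_rep.mean())

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _fit_predict(
    spec: ModelSpec, y: np.ndarray, train: np.ndarray, test: np.ndarray, seed: int
) -> np.ndarray:
    if spec.kind == "oracle":
        return np.asarray(spec.values, dtype=float)[test]
    if spec.kind == "kernel":
        train_blocks = [k.matrix[np.ix_(train, train)] for k in spec.kernels]
        cross_blocks = [k.matrix[np.ix_(test, train)] for k in spec.kernels]
        fit = fit_kernel_reml(
            y[train],
            train_blocks,
            training_ids=[str(i) for i in train],
        )
        return predict_kernel(fit, cross_blocks, train_blocks)
    # bayes
    prior = spec.prior
    if prior is None or prior.S is None:
        fam = prior.family if prior is not None else "BRR"
        kw = {}
        if prior is not None:
            kw = {"R2geno": prior.R2geno, "nu": prior.nu, "pi": prior.pi}
        prior = elicit_prior(y[train], spec.X[train], fam, **kw)
    fit = fit_bayes(y[train], spec.X[train], prior, seed=seed, **spec.mcmc)
    return predict_bayes(fit, spec.X[test])


def run_paired_cv(
    y: np.ndarray,
    model_specs: Sequence[ModelSpec],
    plan: FoldPlan,
    progress: Callable[[str], None] | None = None,
) -> CVResult:
    """Evaluate every model on the identical fold partitions.

    For each replicate and fold, each model is trained on the other k-1
    folds and predicts the held-out fold; per-fold accuracy (Pearson) and
    MSE are recorded.  If any model fails on a fold, the fold is dropped for
    *all* models — an unbalanced drop would break the paired variance
    argument — and logged in ``failed_folds``.
    """
    y = np.asarray(y, dtype=float)
    if plan.n != len(y):
        raise ValueError("fold plan does not cover this phenotype vector")
    names = [m.name for m in model_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names")

    rows: list[dict] = []
    pred_rows: list[dict] = []
    failed: list[tuple[int, int, str]] = []
    for rep in range(plan.r):
        for fold in range(1, plan.k + 1):
            train = plan.train_indices(rep, fold)
            test = plan.test_indices(rep, fold)
            fold_rows = []
            fold_preds = []
            ok = True
            for spec in model_specs:
                # per-fold seed keeps MCMC reproducible and distinct per task
                seed = (plan.seed * 1_000_003 + rep * 1009 + fold * 31) % (2**31)
                try:
                    pred = _fit_predict(spec, y, train, test, seed)
                    acc = fold_accuracy(pred, y[test])
                except Exception as exc:  # pairing: drop the fold everywhere
                    ok = False
                    failed.append((rep, fold, f"{spec.name}: {exc}"))
                    if progress:
                        progress(f"rep {rep} fold {fold} {spec.name} failed: {exc}")
                    break
                mse = float(np.mean((pred - y[test]) ** 2))
                fold_rows.append(
                    {
                        "replicate": rep,
                        "fold": fold,
                        "model": spec.name,
                        "accuracy": acc,
                        "mse": mse,
                        "n_test": len(test),
                    }
                )
                fold_preds.append(
                    pd.DataFrame(
                        {
                            "replicate": rep,
                            "fold": fold,
                            "model": spec.name,
                            "case": test,
                            "pred": pred,
                            "obs": y[test],
                        }
                    )
                )
            if ok:
                rows.extend(fold_rows)
                pred_rows.extend(fold_preds)
                if progress:
                    progress(f"rep {rep} fold {fold} done")
    return CVResult(
        records=pd.DataFrame(
            rows,
            columns=["replicate", "fold", "model", "accuracy", "mse", "n_test"],
        ),
        plan_seed=plan.seed,
        model_names=names,
        failed_folds=failed,
        predictions=(
            pd.concat(pred_rows, ignore_index=True) if pred_rows else None
        ),
    )


def estimate_h2_reml(y: np.ndarray, G: Kernel) -> float:
    """One common heritability estimate per trait: full-data REML on G."""
    return fit_kernel_reml(np.asarray(y, dtype=float), [G]).h2_hat


def rescale_by_heritability(accuracy: float | np.ndarray, h2_hat: float):
    """Phenotype-scale accuracy -> genetic-value-scale accuracy: r / sqrt(h2).

    Use one common ``h2_hat`` for every accuracy being compared; a positive
    rescaling factor preserves the ranking.
    """
    if not 0.0 < h2_hat <= 1.0:
        raise ValueError(f"h2_hat must lie in (0, 1], got {h2_hat}")
    return accuracy / np.sqrt(h2_hat)


def selection_intensity(q: float) -> float:
    """Mean of a standard normal truncated to its upper-q tail: phi(z_q)/q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"selection quantile must lie in (0, 1), got {q}")
    z = stats.norm.ppf(1.0 - q)
    return float(stats.norm.pdf(z) / q)


def to_genetic_gain(accuracy: float | np.ndarray, q: float):
    """Expected genetic gain in phenotypic SDs: i_q * accuracy.

    Assumes truncation selection of the best fraction q and random mating.
    Linear in accuracy, so paired differences transform by the same factor.
    """
    return selection_intensity(q) * accuracy


@dataclass
class GainScale:
    """Selection quantile with its implied intensity."""

    q: float
    i_q: float = 0.0

    def __post_init__(self) -> None:
        self.i_q = selection_intensity(self.q)
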