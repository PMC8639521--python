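"""Genomic prediction models: Bayesian-alphabet regressions and kernel mixed models.

Two families are implemented.

**Marker regressions** ``y = mu + X beta + e`` with a shrinkage prior on the
marker effects, fitted by Gibbs sampling with the standard conjugate full
conditionals:

* ``BRR`` — beta_j ~ N(0, sigma_b^2), one pooled variance (ridge regression);
* ``BayesA`` — per-marker variances sigma_bj^2 ~ scaled-inv-chi^2(nu, S),
  marginally a scaled-t prior on each effect;
* ``BayesB`` — spike-slab: effect exactly zero with probability pi, otherwise
  the BayesA per-marker-variance prior;
* ``BayesC`` — spike-slab with a pooled normal slab.

**Kernel mixed models** ``y = X b + sum_i Z u_i + e`` with
``u_i ~ N(0, K_i sigma_ui^2)``, fitted by REML: a profiled 1-D search on the
spectral decomposition for a single kernel, and bounded quasi-Newton on
log variance components for several kernels fitted jointly.

The scaled-inverse-chi-square is parameterized throughout by density
``p(s2) propto s2^-(nu/2+1) exp(-S/(2 s2))`` (mode ``S/(nu+2)``), and the
hyper-parameter elicitation sets the prior mode of the genomic variance to a
chosen share ``R2geno`` of the phenotypic variance — the weakly-informative
default rule of the mainstream whole-genome-regression software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kernels import Kernel, check_psd

__all__ = [
    "PriorSpec",
    "BayesFit",
    "MixedModelFit",
    "elicit_prior",
    "fit_bayes",
    "predict_bayes",
    "ridge_predict",
    "fit_kernel_reml",
    "predict_kernel",
]

BAYES_FAMILIES = ("BRR", "BayesA", "BayesB", "BayesC")
_SPIKE_SLAB = ("BayesB", "BayesC")
_PER_MARKER_VAR = ("BayesA", "BayesB")


@dataclass
class PriorSpec:
    """Hyper-parameters of a Bayesian-alphabet prior.

    ``nu`` and ``S`` are the degrees of freedom and scale of the
    scaled-inverse-chi-square on the marker-effect variance; ``pi`` is the
    point-mass (exclusion) probability of the spike-slab families; ``R2geno``
    is the prior share of phenotypic variance attributed to markers, used to
    elicit ``S`` when it is not given explicitly.
    """

    family: str
    nu: float = 5.0
    S: float | None = None
    pi: float = 0.5
    R2geno: float = 0.5
    nu_e: float = 5.0
    S_e: float | None = None

    def __post_init__(self) -> None:
        if self.family not in BAYES_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {BAYES_FAMILIES}"
            )
        if self.nu <= 0 or (self.S is not None and self.S <= 0):
            raise ValueError("nu and S must be positive")
        if not 0.0 <= self.pi <= 1.0:
            # pi = 1 (empty slab) is degenerate but allowed for testing
            raise ValueError("pi must lie in [0, 1]")
        if not 0.0 < self.R2geno < 1.0:
            raise ValueError("R2geno must lie in (0, 1)")


@dataclass
class BayesFit:
    """Posterior summaries of a Gibbs run."""

    family: str
    mu_hat: float
    beta_hat: np.ndarray
    residual_var_hat: float
    inclusion_prob: np.ndarray
    x_center: np.ndarray
    beta_sd: np.ndarray | None = None  # posterior SDs, for MC-error bounds
    chain_meta: dict = field(default_factory=dict)


@dataclass
class MixedModelFit:
    """REML estimates for a (multi-)kernel mixed model."""

    fixed_hat: np.ndarray
    var_components: list[float]  # one sigma_u^2 per kernel
    sigma2_e: float
    blups: list[np.ndarray]  # one BLUP vector per kernel
    h2_hat: float
    training_ids: list[str]
    y_train: np.ndarray
    X_train: np.ndarray
    reml_neg2loglik: float


def elicit_prior(
    y: np.ndarray,
    X: np.ndarray,
    family: str,
    R2geno: float = 0.5,
    nu: float = 5.0,
    pi: float = 0.5,
    nu_e: float = 5.0,
) -> PriorSpec:
    """Choose the scale S so the prior mode of the genomic variance is R2geno*var(y).

    With ``MSx = sum_j var(x_j)`` (sum of centered-marker variances) the
    expected genomic variance under the prior mode of sigma_b^2 is
    ``MSx * S / (nu + 2)``; solving for S gives
    ``S = var(y) * R2geno / MSx * (nu + 2)``.  Spike-slab families only keep
    a ``(1 - pi)`` fraction of markers in the slab, so their slab scale is
    inflated by ``1 / (1 - pi)`` to preserve the same total genomic variance.
    The residual scale is set analogously from the non-genomic share.
    """
    if not 0.0 < R2geno < 1.0:
        raise ValueError("R2geno must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    ms_x = float(np.sum(Xc.var(axis=0)))
    if ms_x <= 0:
        raise ValueError("all markers are constant; cannot elicit a prior")
    var_y = float(y.var())
    S = var_y * R2geno / ms_x * (nu + 2.0)
    if family in _SPIKE_SLAB:
        if pi >= 1.0:
            raise ValueError("cannot elicit a slab scale with pi = 1 (empty slab)")
        S /= 1.0 - pi
    S_e = var_y * (1.0 - R2geno) * (nu_e + 2.0)
    return PriorSpec(family, nu=nu, S=S, pi=pi, R2geno=R2geno, nu_e=nu_e, S_e=S_e)


def _sample_scaled_inv_chi2(rng: np.random.Generator, nu: float, S: float) -> float:
    return S / rng.chisquare(nu)


def fit_bayes(
    y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec,
    iters: int = 12_000,
    burnin: int = 2_000,
    thin: int = 5,
    seed: int = 0,
    fix_variances: bool = False,
) -> BayesFit:
    """Gibbs sampler for the Bayesian-alphabet regressions.

    Marker columns are centered internally (the centering constants are kept
    on the fit for prediction).  One iteration updates, in order: the
    intercept, every marker effect from its normal full conditional (with a
    Bernoulli inclusion step for the spike-slab families), the effect
    variance(s) from their scaled-inverse-chi-square full conditionals, and
    the residual variance.  Posterior means are taken over the post-burn-in
    thinned samples.  ``fix_variances`` freezes sigma_b^2 and sigma_e^2 at
    their prior-mode values, which makes BRR a Monte-Carlo ridge regression
    with a closed-form reference solution — useful for validation.
    """
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing phenotypes in training set")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X disagree on n")
    if prior.S is None:
        prior = elicit_prior(
            y, X, prior.family, R2geno=prior.R2geno, nu=prior.nu, pi=prior.pi,
            nu_e=prior.nu_e,
        )

    rng = np.random.default_rng(seed)
    x_center = X.mean(axis=0)
    Xc = X - x_center
    col_ss = np.einsum("ij,ij->j", Xc, Xc)  # x_j'x_j
    active = col_ss > 0  # constant markers carry no information

    family = prior.family
    spike = family in _SPIKE_SLAB
    per_marker = family in _PER_MARKER_VAR
    prior_mode_b = prior.S / (prior.nu + 2.0)
    prior_mode_e = (
        prior.S_e / (prior.nu_e + 2.0) if prior.S_e is not None else float(y.var())
    )

    mu = float(y.mean())
    beta = np.zeros(p)
    delta = np.ones(p, dtype=bool) if not spike else np.zeros(p, dtype=bool)
    s2b = np.full(p, prior_mode_b) if per_marker else prior_mode_b
    s2e = prior_mode_e
    e = y - mu  # running residual

    keep = range(burnin, iters, thin)
    n_keep = len(keep)
    sum_mu = 0.0
    sum_beta = np.zeros(p)
    sum_beta2 = np.zeros(p)
    sum_s2e = 0.0
    sum_incl = np.zeros(p)
    keep_set = set(keep)

    log_pi_ratio = (
        np.log1p(-prior.pi) - np.log(prior.pi)
        if spike and 0.0 < prior.pi < 1.0
        else np.inf
    )

    for it in range(iters):
        # intercept
        e += mu
        mu = rng.normal(e.mean(), np.sqrt(s2e / n))
        e -= mu

        for j in range(p):
            if not active[j]:
                continue
            xj = Xc[:, j]
            cj = col_ss[j]
            s2bj = s2b[j] if per_marker else s2b
            r = xj @ e + cj * beta[j]  # x_j' residual-without-j
            lhs = cj + s2e / s2bj
            if spike:
                if prior.pi >= 1.0:
                    include = False
                else:
                    # log Bayes factor of slab vs spike given the rest
                    log_bf = 0.5 * (
                        np.log(s2e) - np.log(s2bj * cj + s2e)
                    ) + r * r / (2.0 * s2e * lhs)
                    z = log_pi_ratio + log_bf
                    include = rng.random() < 1.0 / (1.0 + np.exp(-z)) if z < 35 else True
                delta[j] = include
            else:
                include = True
            if include:
                new_b = rng.normal(r / lhs, np.sqrt(s2e / lhs))
            else:
                new_b = 0.0
            if new_b != beta[j]:
                e += xj * (beta[j] - new_b)
                beta[j] = new_b

        if not fix_variances:
            if per_marker:
                # included markers: conjugate update; excluded: prior draw
                post_S = prior.S + beta**2
                s2b = post_S / rng.chisquare(prior.nu + 1.0, size=p)
                if spike:
                    excl = ~delta
                    n_excl = int(excl.sum())
                    if n_excl:
                        s2b[excl] = prior.S / rng.chisquare(prior.nu, size=n_excl)
            else:
                m = int(delta.sum()) if spike else int(active.sum())
                ssb = float(beta @ beta)
                s2b = _sample_scaled_inv_chi2(rng, prior.nu + m, prior.S + ssb)
            Se = prior.S_e if prior.S_e is not None else 0.0
            nu_e = prior.nu_e if prior.S_e is not None else 0.0
            s2e = _sample_scaled_inv_chi2(rng, nu_e + n, Se + float(e @ e))
            if not np.isfinite(s2e) or s2e <= 0:
                raise FloatingPointError(
                    f"residual variance diverged at iteration {it}: {s2e}"
                )

        if it in keep_set:
            sum_mu += mu
            sum_beta += beta
            sum_beta2 += beta * beta
            sum_s2e += s2e
            sum_incl += delta

    return BayesFit(
        family=family,
        mu_hat=sum_mu / n_keep,
        beta_hat=sum_beta / n_keep,
        residual_var_hat=sum_s2e / n_keep,
        inclusion_prob=sum_incl / n_keep,
        x_center=x_center,
        beta_sd=np.sqrt(np.maximum(sum_beta2 / n_keep - (sum_beta / n_keep) ** 2, 0.0)),
        chain_meta={
            "iters": iters,
            "burnin": burnin,
            "thin": thin,
            "seed": seed,
            "n_samples": n_keep,
            "fix_variances": fix_variances,
            "prior": {"nu": prior.nu, "S": prior.S, "pi": prior.pi},
        },
    )


def predict_bayes(fit: BayesFit, X_new: np.ndarray) -> np.ndarray:
    """Predict phenotypes for new lines: ``mu_hat + (X_new - center) beta_hat``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(fit.beta_hat):
        raise ValueError(
            f"X_new has {X_new.shape[1]} markers, fit has {len(fit.beta_hat)}"
        )
    return fit.mu_hat + (X_new - fit.x_center) @ fit.beta_hat


def ridge_predict(
    y: np.ndarray,
    X: np.ndarray,
    X_new: np.ndarray,
    sigma2_beta: float,
    sigma2_e: float,
) -> np.ndarray:
    """Closed-form rrBLUP prediction with known variance components.

    Solves ``beta = (Xc'Xc + lambda I)^-1 Xc'(y - ybar)`` with
    ``lambda = sigma2_e / sigma2_beta`` on centered markers and predicts
    ``ybar + Xc_new beta``.  This is the deterministic counterpart of a
    fixed-variance BRR Gibbs run, and — through ``G = Xc Xc' / c`` with
    ``sigma2_u = c sigma2_beta`` — of the additive-kernel BLUP.
    """
    y = np.asarray(y, dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    lam = sigma2_e / sigma2_beta
    p = Xc.shape[1]
    beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ (y - y.mean()))
    return y.mean() + (np.asarray(X_new, dtype=float) - center) @ beta


# ---------------------------------------------------------------------------
# kernel mixed models (REML)
# ---------------------------------------------------------------------------


def _as_matrices(kernels: list[Kernel] | list[np.ndarray]) -> list[np.ndarray]:
    mats = []
    for k in kernels:
        m = k.matrix if isinstance(k, Kernel) else np.asarray(k, dtype=float)
        mats.append(m)
    return mats


def _neg2_reml_single(log_lam, d, yt, Xt):
    """Profiled -2 restricted log-likelihood for V = s2e (lam K + I)."""
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ (w * resid))
    nq = len(yt) - Xt.shape[1]
    s2e = rss / nq
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    return nq * (np.log(s2e) + 1.0) - float(np.sum(np.log(w))) + logdet_xwx


def _neg2_reml_multi(log_s2, mats, y, X):
    s2 = np.exp(log_s2)
    n = len(y)
    V = s2[-1] * np.eye(n)
    for s, K in zip(s2[:-1], mats):
        V += s * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid_quad = float(y @ Vi_y - y @ Vi_X @ beta)
    _, logdet_xvx = np.linalg.slogdet(XtViX)
    return logdet_V + logdet_xvx + resid_quad


def fit_kernel_reml(
    y: np.ndarray,
    kernels: list[Kernel],
    fixed_design: np.ndarray | None = None,
    training_ids: list[str] | None = None,
    tol: float = 1e-8,
) -> MixedModelFit:
    """REML fit of a mixed model with one random effect per kernel.

    A single kernel is handled on its spectral decomposition by a bounded
    1-D search over the log variance ratio (residual variance profiled out);
    several kernels by L-BFGS-B on log variance components, which enforces
    nonnegativity.  ``h2_hat`` weights each component by its kernel's mean
    diagonal, so it is invariant to the arbitrary multiplicative constant of
    any GRM.
    """
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    if not mask.all():  # missing phenotypes are dropped, not imputed
        idx = np.where(mask)[0]
        y = y[idx]
        kernels = [
            Kernel(k.name, k.matrix[np.ix_(idx, idx)], [k.line_ids[i] for i in idx],
                   bandwidth=k.bandwidth, scaling_note=k.scaling_note)
            if isinstance(k, Kernel) else np.asarray(k)[np.ix_(idx, idx)]
            for k in kernels
        ]
        if fixed_design is not None:
            fixed_design = np.asarray(fixed_design)[idx]
        if training_ids is not None:
            training_ids = [training_ids[i] for i in idx]
    n = len(y)
    X = (
        np.ones((n, 1))
        if fixed_design is None
        else np.atleast_2d(np.asarray(fixed_design, dtype=float))
    )
    if X.shape[0] != n:
        raise ValueError("fixed design rows do not match y")
    mats = _as_matrices(kernels)
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("kernel order does not match training set size")
        if not check_psd(m, rtol=1e-6):
            raise ValueError("kernel is not positive semidefinite within tolerance")
    if training_ids is None:
        k0 = kernels[0]
        training_ids = (
            list(k0.line_ids) if isinstance(k0, Kernel) else [str(i) for i in range(n)]
        )

    if len(mats) == 1:
        d, U = np.linalg.eigh(mats[0])
        d = np.maximum(d, 0.0)
        yt = U.T @ y
        Xt = U.T @ X
        res = optimize.minimize_scalar(
            _neg2_reml_single,
            bounds=(-12.0, 12.0),
            args=(d, yt, Xt),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        w = 1.0 / (lam * d + 1.0)
        XtW = Xt * w[:, None]
        beta = np.linalg.solve(Xt.T @ XtW, XtW.T @ yt)
        resid = yt - Xt @ beta
        nq = n - X.shape[1]
        s2e = float(resid @ (w * resid)) / nq
        s2u = lam * s2e
        s2 = np.array([s2u, s2e])
        neg2ll = float(res.fun) + nq * np.log(2 * np.pi)
    else:
        v0 = float(y.var())
        ku = len(mats)
        x0 = np.log(np.full(ku + 1, v0 / (ku + 1)))
        res = optimize.minimize(
            _neg2_reml_multi,
            x0,
            args=(mats, y, X),
            method="L-BFGS-B",
            bounds=[(-25.0, 25.0)] * (ku + 1),
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise RuntimeError(f"REML did not converge: {res.message}")
        s2 = np.exp(res.x)
        V = s2[-1] * np.eye(n)
        for s, K in zip(s2[:-1], mats):
            V += s * K
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        s2e = float(s2[-1])
        neg2ll = float(res.fun)

    # BLUPs: u_i = s2_ui K_i V^-1 (y - X beta)
    V = s2e * np.eye(n)
    for s, K in zip(s2[:-1], mats):
        V += s * K
    r = np.linalg.solve(V, y - X @ beta)
    blups = [s * (K @ r) for s, K in zip(s2[:-1], mats)]

    diag_means = np.array([float(np.mean(np.diag(K))) for K in mats])
    genetic_var = float(np.sum(s2[:-1] * diag_means))
    h2_hat = genetic_var / (genetic_var + s2e) if genetic_var + s2e > 0 else 0.0

    return MixedModelFit(
        fixed_hat=np.atleast_1d(beta),
        var_components=[float(s) for s in s2[:-1]],
        sigma2_e=s2e,
        blups=blups,
        h2_hat=float(h2_hat),
        training_ids=list(training_ids),
        y_train=y,
        X_train=X,
        reml_neg2loglik=neg2ll,
    )


def fixed_variance_kernel_fit(
    y: np.ndarray,
    kernels: list[Kernel] | list[np.ndarray],
    var_components: list[float],
    sigma2_e: float,
    gls_intercept: bool = True,
) -> MixedModelFit:
    """Assemble a :class:`MixedModelFit` at *known* variance components.

    No REML search is run: the variance components are taken as given and
    only the intercept is estimated (by GLS, or by the plain sample mean
    when ``gls_intercept=False`` — the centering convention of the
    closed-form ridge solution, which makes the marker-based and the
    kernel-based routes of the rrBLUP/G-BLUP identity exactly comparable).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    mats = _as_matrices(kernels)
    X = np.ones((n, 1))
    if gls_intercept:
        V = sigma2_e * np.eye(n)
        for s, K in zip(var_components, mats):
            V += s * K
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    else:
        beta = np.array([y.mean()])
    V = sigma2_e * np.eye(n)
    for s, K in zip(var_components, mats):
        V += s * K
    r = np.linalg.solve(V, y - X @ beta)
    blups = [s * (K @ r) for s, K in zip(var_components, mats)]
    diag_means = [float(np.mean(np.diag(K))) for K in mats]
    gvar = float(np.sum(np.asarray(var_components) * np.asarray(diag_means)))
    return MixedModelFit(
        fixed_hat=np.atleast_1d(beta),
        var_components=[float(s) for s in var_components],
        sigma2_e=float(sigma2_e),
        blups=blups,
        h2_hat=gvar / (gvar + sigma2_e),
        training_ids=[str(i) for i in range(n)],
        y_train=y,
        X_train=X,
        reml_neg2loglik=float("nan"),
    )


def predict_kernel(
    fit: MixedModelFit,
    cross_kernels: list[np.ndarray],
    train_kernels: list[np.ndarray],
    X_new: np.ndarray | None = None,
) -> np.ndarray:
    """BLUP prediction for held-out lines from test-by-train kernel blocks.

    ``u_test = (sum_i s2_ui K_cross_i) (sum_i s2_ui K_train_i + s2_e I)^-1
    (y - X beta)``; the returned prediction adds the fixed part for the new
    lines (intercept-only when ``X_new`` is omitted).
    """
    cross = _as_matrices(cross_kernels)
    train = _as_matrices(train_kernels)
    if len(cross) != len(fit.var_components) or len(train) != len(fit.var_components):
        raise ValueError("kernel block count does not match fitted components")
    n = len(fit.y_train)
    C_train = fit.sigma2_e * np.eye(n)
    C_cross = np.zeros((cross[0].shape[0], n))
    for s, Kc, Kt in zip(fit.var_components, cross, train):
        C_train += s * Kt
        C_cross += s * Kc
    r = np.linalg.solve(C_train, fit.y_train - fit.X_train @ fit.fixed_hat)
    u_test = C_cross @ r
    if X_new is None:
        X_new = np.ones((u_test.shape[0], fit.X_train.shape[1]))
    return np.asarray(X_new, dtype=float) @ fit.fixed_hat + u_test
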