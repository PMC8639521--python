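"""Synthetic marker panels, traits, and fold scores.

Every downstream stage of the package (kernel construction, model fitting,
paired cross validation, equivalence testing) is exercised on data produced
here, so each generator is a pure function of its arguments including the
seed.  Markers are simulated at Hardy-Weinberg proportions, independently
across loci (no linkage disequilibrium): none of the methods implemented in
this package require LD, and independence keeps the sampling distributions
analytically tractable for the test oracles.

Traits are built from an additive component (random QTL effects on centered
dosages) plus a pairwise-epistatic component (products of centered dosages),
each rescaled to a target share of the phenotypic variance, with Gaussian
noise filling the remainder.  The simulator returns the true total genetic
values alongside the phenotypes so that parameter-recovery tests can compare
estimates against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "TraitSimSpec",
    "SimulatedTrait",
    "sim_genotypes",
    "sim_phenotypes",
    "sim_fold_scores",
]


@dataclass
class GenotypeMatrix:
    """A biallelic dosage panel: ``n`` lines by ``p`` markers.

    ``M[i, j]`` counts copies of the alternate allele carried by line ``i``
    at marker ``j`` (0, 1 or 2).
    """

    line_ids: list[str]
    marker_ids: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        if self.M.ndim != 2:
            raise ValueError("M must be a 2-D dosage matrix")
        n, p = self.M.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 lines and p >= 1 markers, got {n}x{p}")
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lists do not match matrix dimensions")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line_ids")
        if not np.isin(self.M, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def p(self) -> int:
        return self.M.shape[1]


@dataclass
class TraitSimSpec:
    """Architecture of a simulated trait.

    ``h2_additive`` and ``h2_epistatic`` are the target shares of phenotypic
    variance contributed by the additive and the pairwise-interaction genetic
    components; their sum is the target broad-sense heritability.
    """

    n_qtl_additive: int = 50
    n_pairs_epistatic: int = 0
    h2_additive: float = 0.5
    h2_epistatic: float = 0.0
    seed: int = 0

    def validate(self, geno: GenotypeMatrix) -> None:
        if not (0 <= self.h2_additive <= 1 and 0 <= self.h2_epistatic <= 1):
            raise ValueError("heritability components must lie in [0, 1]")
        if self.h2_additive + self.h2_epistatic > 1 + 1e-12:
            raise ValueError("h2_additive + h2_epistatic must not exceed 1")
        if self.n_qtl_additive < 0 or self.n_pairs_epistatic < 0:
            raise ValueError("QTL counts must be nonnegative")
        if self.n_qtl_additive > geno.p:
            raise ValueError("more additive QTL than markers")
        if self.n_pairs_epistatic > geno.p * (geno.p - 1) // 2:
            raise ValueError("more epistatic pairs than available marker pairs")


@dataclass
class SimulatedTrait:
    """Phenotypes plus the simulation truth used by recovery tests."""

    y: np.ndarray
    g: np.ndarray
    sigma_P: float
    sigma_G: float
    realized_h2: float
    truth: dict = field(default_factory=dict)


def sim_genotypes(
    n: int, p: int, maf_low: float = 0.05, maf_high: float = 0.5, *, seed: int = 0
) -> GenotypeMatrix:
    """Draw an ``n`` x ``p`` dosage panel at Hardy-Weinberg proportions.

    Each marker's alternate-allele frequency is drawn uniformly in
    ``[maf_low, maf_high]``; each dosage is then Binomial(2, freq),
    independently across lines and markers.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError(
            f"require 0 < maf_low <= maf_high <= 0.5, got [{maf_low}, {maf_high}]"
        )
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 and p >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=p)
    M = rng.binomial(2, freqs, size=(n, p)).astype(np.int8)
    line_ids = [f"L{i:04d}" for i in range(n)]
    marker_ids = [f"M{j:05d}" for j in range(p)]
    return GenotypeMatrix(line_ids, marker_ids, M)


def _scaled_component(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center x and rescale it to the requested variance (zero stays zero)."""
    x = x - x.mean()
    v = x.var()
    if v <= 0 or target_var <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def sim_phenotypes(geno: GenotypeMatrix, spec: TraitSimSpec) -> SimulatedTrait:
    """Simulate a trait with additive + pairwise-epistatic architecture.

    QTL positions are sampled uniformly without replacement; effect sizes are
    standard normal.  Additive contributions use centered dosages
    ``M_ij - 2 p_j``; epistatic contributions use products of centered
    dosages for the sampled pairs.  Each genetic part is rescaled so its
    realized variance matches its target share of a unit phenotypic variance,
    then Gaussian noise tops the total up to variance one.  With a total
    heritability of one the phenotype equals the genetic value exactly.
    """
    spec.validate(geno)
    rng = np.random.default_rng(spec.seed)
    n = geno.n
    freqs = geno.M.mean(axis=0) / 2.0
    W = geno.M - 2.0 * freqs  # centered dosages

    g = np.zeros(n)
    add_part = np.zeros(n)
    epi_part = np.zeros(n)

    if spec.n_qtl_additive > 0 and spec.h2_additive > 0:
        qtl = rng.choice(geno.p, size=spec.n_qtl_additive, replace=False)
        effects = rng.standard_normal(spec.n_qtl_additive)
        add_part = _scaled_component(W[:, qtl] @ effects, spec.h2_additive)

    if spec.n_pairs_epistatic > 0 and spec.h2_epistatic > 0:
        # sample distinct unordered marker pairs
        pairs: set[tuple[int, int]] = set()
        while len(pairs) < spec.n_pairs_epistatic:
            a, b = rng.choice(geno.p, size=2, replace=False)
            pairs.add((min(a, b), max(a, b)))
        idx = np.array(sorted(pairs))
        effects = rng.standard_normal(len(idx))
        inter = W[:, idx[:, 0]] * W[:, idx[:, 1]]
        epi_part = _scaled_component(inter @ effects, spec.h2_epistatic)

    g = add_part + epi_part
    h2_total = spec.h2_additive + spec.h2_epistatic
    noise_var = max(0.0, 1.0 - h2_total)
    if noise_var == 0.0:
        e = np.zeros(n)
    else:
        e = rng.normal(0.0, np.sqrt(noise_var), size=n)
    y = g + e

    var_y = y.var()
    var_g = g.var()
    realized_h2 = float(var_g / var_y) if var_y > 0 else float("nan")
    return SimulatedTrait(
        y=y,
        g=g,
        sigma_P=float(np.sqrt(var_y)),
        sigma_G=float(np.sqrt(var_g)),
        realized_h2=realized_h2,
        truth={"h2_additive": spec.h2_additive, "h2_epistatic": spec.h2_epistatic},
    )


def sim_fold_scores(
    r: int,
    k: int,
    rho: float,
    mean_a: float,
    mean_b: float,
    sd_fold: float,
    *,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated per-fold accuracy scores for two models.

    The r*k fold scores of model A and model B are bivariate normal with the
    stated means, a common per-fold standard deviation and correlation
    ``rho``.  This feeds the comparison machinery directly, without fitting
    any model: the variance of the paired difference is
    ``2 * sd_fold**2 * (1 - rho)``, the quantity the paired design exploits.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    if sd_fold <= 0:
        raise ValueError("sd_fold must be positive")
    if r < 1 or k < 1:
        raise ValueError("need r >= 1 and k >= 1")
    rng = np.random.default_rng(seed)
    m = r * k
    if abs(rho) == 1.0:  # singular boundary: perfectly (anti)correlated scores
        z = rng.standard_normal(m) * sd_fold
        return mean_a + z, mean_b + rho * z
    cov = sd_fold**2 * np.array([[1.0, rho], [rho, 1.0]])
    draws = rng.multivariate_normal([mean_a, mean_b], cov, size=m, method="cholesky")
    return draws[:, 0], draws[:, 1]
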