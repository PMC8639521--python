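"""Genomic relationship matrices and RKHS kernels.

Four families of n x n covariance structures over lines are built from a
dosage panel:

* ``G`` — VanRaden's additive GRM, ``(M - 2 1P)(M - 2 1P)' / (2 sum p(1-p))``;
* ``H`` — the epistatic GRM ``G (.) G`` (elementwise/Hadamard square), PSD by
  the Schur product theorem whenever ``G`` is;
* ``Cm``/``Ce`` — categorical-match kernels: ``Cm_ij`` is the fraction of
  markers at which lines i and j carry the same genotype category, and
  ``Ce = (Cm (.) Cm + Cm) / 2`` adds pairwise categorical interactions;
* ``K`` — the Gaussian kernel ``exp(-D_ij / h)`` on the mean squared dosage
  distance ``D``, with bandwidth ``h``.

All of these are defined up to a multiplicative constant, which the mixed
model absorbs into its variance component; the constants fixed here (the
VanRaden divisor, the 1/p match average, the unit Gaussian constant) are the
conventional ones and are recorded on each ``Kernel``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix

__all__ = [
    "Kernel",
    "DistanceMatrix",
    "allele_frequencies",
    "vanraden_grm",
    "egblup_grm",
    "categorical_kernels",
    "squared_distance",
    "gaussian_kernel",
    "bandwidth_grid",
    "check_psd",
    "write_kernel",
    "read_kernel",
]

#: relative eigenvalue tolerance below which a kernel counts as PSD
PSD_RTOL = 1e-8


class DegenerateKernelError(ValueError):
    """Raised when a kernel cannot be built (e.g. all markers monomorphic)."""


@dataclass
class Kernel:
    """A named symmetric relationship matrix with its provenance."""

    name: str
    matrix: np.ndarray
    line_ids: list[str]
    bandwidth: float | None = None
    scaling_note: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kernel matrix must be square")
        if len(self.line_ids) != m.shape[0]:
            raise ValueError("line_ids length does not match matrix order")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def scaled(self, c: float) -> "Kernel":
        """Return the kernel multiplied by c > 0 (same covariance family)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return Kernel(
            self.name,
            self.matrix * c,
            list(self.line_ids),
            bandwidth=self.bandwidth,
            scaling_note=f"{self.scaling_note}; rescaled by {c}",
        )


@dataclass
class DistanceMatrix:
    """Mean squared dosage distance between lines (zero diagonal)."""

    matrix: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) > 1e-10) or np.any(m < -1e-10):
            raise ValueError("distances must be nonnegative with zero diagonal")
        self.matrix = m


def check_psd(matrix: np.ndarray, rtol: float = PSD_RTOL) -> bool:
    """True when the smallest eigenvalue is >= -rtol * largest."""
    w = np.linalg.eigvalsh(matrix)
    return w[0] >= -rtol * max(w[-1], 1e-300)


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per marker: mean dosage / 2."""
    return geno.M.mean(axis=0) / 2.0


def vanraden_grm(geno: GenotypeMatrix) -> Kernel:
    """Additive GRM: centered cross-products over ``2 sum_j p_j (1 - p_j)``."""
    p = allele_frequencies(geno)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise DegenerateKernelError("all markers are monomorphic; G undefined")
    W = geno.M - 2.0 * p
    G = (W @ W.T) / denom
    return Kernel(
        "G", G, list(geno.line_ids), scaling_note="divided by 2*sum p(1-p)"
    )


def egblup_grm(G: Kernel) -> Kernel:
    """Epistatic GRM: the Hadamard square of the additive GRM."""
    return Kernel(
        "EGBLUP_H",
        G.matrix * G.matrix,
        list(G.line_ids),
        scaling_note="Hadamard square of G",
    )


def categorical_kernels(geno: GenotypeMatrix) -> tuple[Kernel, Kernel]:
    """Categorical match kernel Cm and its epistatic extension Ce.

    Genotypes are compared as categories (exact dosage equality), so
    ``Cm_ii = 1`` and entries lie in [0, 1].
    """
    M = geno.M
    n, p = M.shape
    # count matches via indicator expansion over the 3 dosage categories
    Cm = np.zeros((n, n))
    for dose in (0, 1, 2):
        ind = (M == dose).astype(float)
        Cm += ind @ ind.T
    Cm /= p
    Ce = 0.5 * (Cm * Cm + Cm)
    ids = list(geno.line_ids)
    return (
        Kernel("Cm", Cm, ids, scaling_note="match fraction over p markers"),
        Kernel("Ce", Ce, ids, scaling_note="(Cm.Cm + Cm)/2"),
    )


def squared_distance(geno: GenotypeMatrix) -> DistanceMatrix:
    """Mean squared dosage difference per marker between every pair of lines."""
    M = geno.M.astype(float)
    sq = np.sum(M * M, axis=1)
    D = (sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)) / geno.p
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    return DistanceMatrix(0.5 * (D + D.T), list(geno.line_ids))


def gaussian_kernel(D: DistanceMatrix, h: float) -> Kernel:
    """Gaussian kernel ``K_ij = exp(-D_ij / h)`` with bandwidth h > 0.

    The exponent carries a negative sign so that similarity decays with
    distance; this is the standard RKHS Gaussian kernel and the only version
    that yields a valid (PSD) covariance.
    """
    if h <= 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    K = np.exp(-D.matrix / h)
    return Kernel(
        "GaussianK",
        K,
        list(D.line_ids),
        bandwidth=float(h),
        scaling_note="unit constant",
    )


def bandwidth_grid(
    D: DistanceMatrix, scales: tuple[float, ...] = (0.2, 1.0, 5.0)
) -> list[float]:
    """Bandwidths as multiples of the median off-diagonal distance.

    Used for multi-kernel Gaussian models (kernel averaging): one kernel per
    bandwidth, fitted jointly so REML weights the contribution of each.  The
    default spans a narrow (median/5), a reference (median) and a flat
    (5 * median) kernel — the usual spread in the kernel-averaging
    literature.  Bandwidths anchored to the *median* distance keep a genuine
    contrast between kernels even when the pairwise distances concentrate,
    as they do for unstructured panels with many independent markers.
    """
    n = D.matrix.shape[0]
    med = float(np.median(D.matrix[np.triu_indices(n, k=1)]))
    if med <= 0:
        raise ValueError("degenerate distance matrix: median distance is zero")
    return [med * s for s in scales]


def write_kernel(kernel: Kernel, path: str | Path) -> None:
    """Write a kernel as TSV (line ids on both margins) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(kernel.matrix, index=kernel.line_ids, columns=kernel.line_ids)
    df.to_csv(path, sep="\t", index_label="id")
    meta = {
        "name": kernel.name,
        "bandwidth": kernel.bandwidth,
        "scaling_note": kernel.scaling_note,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_kernel(path: str | Path) -> Kernel:
    """Read a kernel written by :func:`write_kernel`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids disagree")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Kernel(
        meta.get("name", "custom"),
        df.to_numpy(),
        [str(i) for i in df.index],
        bandwidth=meta.get("bandwidth"),
        scaling_note=meta.get("scaling_note", ""),
    )
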