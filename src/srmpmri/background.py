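"""Normal-prostate background (clutter) statistics and the signal-to-clutter ratio.

The normal prostate outlined on the registered hypercube provides the
clutter model: mean spectral vector mu_b and band covariance CM.  The
signal-to-clutter ratio (SCR) of a tumor signature s is the Mahalanobis
distance sqrt((s - mu_b)' CM^-1 (s - mu_b)) — how far the tumor sits from
normal tissue once inter-band correlations are accounted for.

The sample covariance of a small region is imperfect, so three repaired
inverses are provided alongside the dense one:

* principal-component filtering — drop the K smallest-eigenvalue (noise)
  components and invert on the retained subspace;
* shrinkage regularization CM(gamma) = (1-gamma) CM + gamma * D with the
  scaled identity D = (trace(CM)/B) I ("standard") or D = diag(CM)
  ("modified"); both preserve the trace;
* gamma selection: background voxels of a multivariate normal have squared
  Mahalanobis distances ~ chi-square(B), so gamma* minimizes the
  Kolmogorov-Smirnov distance of the observed distances to chi2_B over the
  grid 0, 0.01, ..., 1 (ties -> smallest gamma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .hypercube import Hypercube, ProstateMask

__all__ = [
    "BackgroundModel",
    "InverseSpec",
    "estimate_background",
    "background_from_voxels",
    "pc_filtered_inverse",
    "regularize",
    "select_gamma",
    "inverse_operator",
    "scr",
    "mahalanobis_sq",
]

log = logging.getLogger(__name__)

GAMMA_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)

#: condition number beyond which the dense inverse is refused
COND_LIMIT = 1e12


@dataclass
class BackgroundModel:
    """Clutter statistics: mean, covariance and its eigen-decomposition."""

    mean: np.ndarray
    cov: np.ndarray
    eigenvalues: np.ndarray  # sorted descending
    eigenvectors: np.ndarray  # columns, matching order
    n_voxels: int

    @property
    def n_bands(self) -> int:
        return self.mean.size


@dataclass
class InverseSpec:
    """Which repaired covariance inverse to use.

    mode is one of ``full``, ``pc_filtered`` (with ``k_removed`` smallest
    components dropped), ``regularized`` or ``modified_regularized`` (with
    mixing parameter ``gamma``; None means select it from data).
    """

    mode: str = "full"
    k_removed: int = 0
    gamma: float | None = None

    MODES = ("full", "pc_filtered", "regularized", "modified_regularized")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"unknown inverse mode {self.mode!r}")
        if self.gamma is not None and not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.k_removed < 0:
            raise ValueError("k_removed must be non-negative")


def background_from_voxels(voxels: np.ndarray) -> BackgroundModel:
    """Clutter model from an (n, B) array of background spectral vectors."""
    voxels = np.asarray(voxels, dtype=float)
    n, b = voxels.shape
    if n < b + 1:
        raise ValueError(
            f"only {n} background voxels for {b} bands; the covariance is rank "
            "deficient and regularization cannot rescue rank — outline more tissue"
        )
    mean = voxels.mean(axis=0)
    cov = np.cov(voxels, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return BackgroundModel(mean, cov, evals[order], evecs[:, order], n)


def estimate_background(cube: Hypercube, mask: ProstateMask) -> BackgroundModel:
    """Estimate the clutter model from voxels labeled normal prostate (1)."""
    if mask.labels.shape != cube.grid_shape:
        raise ValueError("mask grid does not match hypercube grid")
    return background_from_voxels(cube.voxel_vectors(mask.background))


def pc_filtered_inverse(bg: BackgroundModel, k_removed: int) -> np.ndarray:
    """Covariance inverse restricted to the B - k_removed leading components.

    The smallest-eigenvalue principal components carry mostly noise;
    dropping them yields sum_i 1/lambda_i v_i v_i' over the retained
    (largest) eigenpairs — a positive semi-definite pseudo-inverse.
    """
    b = bg.n_bands
    keep = b - k_removed
    if keep < 1:
        raise ValueError("must retain at least one principal component")
    lam = bg.eigenvalues[:keep]
    if np.any(lam <= 0):
        raise ValueError("retained eigenvalue is not positive; filter more components")
    v = bg.eigenvectors[:, :keep]
    return (v / lam) @ v.T


def regularize(bg: BackgroundModel, mode: str, gamma: float) -> np.ndarray:
    """Shrink the covariance toward a diagonal target with mixing parameter gamma.

    standard: CM(gamma) = (1-gamma) CM + gamma (trace(CM)/B) I
    modified: CM(gamma) = (1-gamma) CM + gamma diag(CM)

    Both targets preserve trace(CM); either yields a symmetric
    positive-definite matrix for gamma in (0, 1] whenever diag(CM) > 0.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    cm = bg.cov
    if mode == "standard":
        target = np.eye(bg.n_bands) * (np.trace(cm) / bg.n_bands)
    elif mode == "modified":
        target = np.diag(np.diag(cm))
    else:
        raise ValueError(f"unknown regularization mode {mode!r}")
    return (1.0 - gamma) * cm + gamma * target


def mahalanobis_sq(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distances of rows of x under (mean, cov)."""
    d = np.atleast_2d(x) - mean
    L = np.linalg.cholesky(cov)
    y = linalg.solve_triangular(L, d.T, lower=True)
    return np.einsum("ij,ij->j", y, y)


def select_gamma(
    bg: BackgroundModel,
    mode: str,
    voxels: np.ndarray,
    grid: np.ndarray = GAMMA_GRID,
) -> float:
    """Choose the shrinkage mixing parameter that makes the background most normal.

    For each gamma on the grid, the squared Mahalanobis distances of the
    background voxels under CM(gamma) are compared with the chi-square
    distribution with B degrees of freedom by the Kolmogorov-Smirnov
    statistic; the minimizing gamma wins, ties going to the smallest.
    A singular CM(gamma) (possible at gamma = 0) is skipped with a notice.
    """
    voxels = np.asarray(voxels, dtype=float)
    b = bg.n_bands
    if voxels.shape[0] < 10 * b:
        raise ValueError("need at least 10*B background voxels to select gamma")
    chi2 = stats.chi2(df=b)
    best_gamma, best_ks = None, np.inf
    for g in np.asarray(grid, dtype=float):
        cm_g = regularize(bg, mode, g)
        try:
            d2 = mahalanobis_sq(voxels, bg.mean, cm_g)
        except np.linalg.LinAlgError:
            log.info("skipping gamma=%.2f: singular covariance", g)
            continue
        ks = stats.kstest(d2, chi2.cdf).statistic
        if ks < best_ks - 1e-15:
            best_gamma, best_ks = float(g), float(ks)
    if best_gamma is None:
        raise ValueError("no gamma on the grid yielded an invertible covariance")
    return best_gamma


def inverse_operator(
    bg: BackgroundModel,
    spec: InverseSpec,
    voxels: np.ndarray | None = None,
) -> np.ndarray:
    """Materialize the covariance inverse requested by an InverseSpec.

    ``voxels`` is only needed when a regularized mode must select gamma
    from data (spec.gamma is None).
    """
    if spec.mode == "full":
        cond = np.linalg.cond(bg.cov)
        if not np.isfinite(cond) or cond > COND_LIMIT:
            raise np.linalg.LinAlgError(
                f"background covariance is ill-conditioned (condition number "
                f"{cond:.3g}); use PC filtering or shrinkage regularization"
            )
        return np.linalg.inv(bg.cov)
    if spec.mode == "pc_filtered":
        return pc_filtered_inverse(bg, spec.k_removed)
    mode = "standard" if spec.mode == "regularized" else "modified"
    gamma = spec.gamma
    if gamma is None:
        if voxels is None:
            raise ValueError("gamma selection requires background voxels")
        gamma = select_gamma(bg, mode, voxels)
    return np.linalg.inv(regularize(bg, mode, gamma))


def scr(
    signature: np.ndarray,
    bg: BackgroundModel,
    spec: InverseSpec = InverseSpec(),
    voxels: np.ndarray | None = None,
    squared: bool = False,
) -> float:
    """Signal-to-clutter ratio of a tumor signature against the background.

    SCR = sqrt((s - mu_b)' CM^-1 (s - mu_b)) with the inverse per ``spec``;
    ``squared=True`` returns the quadratic form itself.
    """
    d = np.asarray(signature, dtype=float) - bg.mean
    minv = inverse_operator(bg, spec, voxels)
    q = float(d @ minv @ d)
    q = max(q, 0.0)
    return q if squared else float(np.sqrt(q))
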