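"""Supervised target detection and blob shape metrics.

The adaptive cosine estimator (ACE) scores every prostate voxel by the
squared cosine between its spectral vector and a tumor signature, both
measured in background-whitened coordinates — a scale-invariant match
score in [0, 1].  Supra-threshold voxels are grouped into connected blobs;
each blob gets a physical volume and an eccentricity derived from the
eigenvalues of its second-central-moment (scatter) matrix in mm
coordinates: E = sqrt(1 - s/l) with l >= s the two leading eigenvalues,
so a sphere scores 0 and a line scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .background import BackgroundModel, InverseSpec, inverse_operator
from .hypercube import Hypercube, ProstateMask

__all__ = [
    "TumorSignature",
    "AceMap",
    "Blob",
    "BlobSet",
    "ace_map",
    "threshold_blobs",
    "blob_volume",
    "eccentricity",
    "largest_blob",
]


@dataclass
class TumorSignature:
    """Mean spectral vector of voxels identified as tumor on the hypercube."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).ravel()
        if not np.all(np.isfinite(self.s)):
            raise ValueError("signature must be finite")

    @classmethod
    def from_voxels(cls, voxels: np.ndarray) -> "TumorSignature":
        return cls(np.asarray(voxels, dtype=float).mean(axis=0))


@dataclass
class AceMap:
    """ACE scores aligned to the hypercube grid (zero outside the mask)."""

    scores: np.ndarray
    mask: np.ndarray  # boolean: voxels that were scored
    spacing_mm: tuple[float, float, float]


@dataclass
class Blob:
    """A connected component of detected voxels with its shape summary."""

    label: int
    coords: np.ndarray  # (n, 3) voxel indices
    n_voxels: int
    volume_cc: float
    l_mm2: float  # largest scatter eigenvalue
    s_mm2: float  # second scatter eigenvalue
    eccentricity: float


@dataclass
class BlobSet:
    blobs: list[Blob] = field(default_factory=list)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __len__(self) -> int:
        return len(self.blobs)

    def __iter__(self):
        return iter(self.blobs)

    @property
    def total_voxels(self) -> int:
        return sum(b.n_voxels for b in self.blobs)

    @property
    def total_volume_cc(self) -> float:
        return sum(b.volume_cc for b in self.blobs)


def ace_map(
    cube: Hypercube,
    mask: ProstateMask,
    sig: TumorSignature,
    bg: BackgroundModel,
    spec: InverseSpec = InverseSpec(),
) -> AceMap:
    """Score every masked voxel with the adaptive cosine estimator.

    ACE(x) = [(s-mu)' M (x-mu)]^2 / ([(s-mu)' M (s-mu)] [(x-mu)' M (x-mu)])
    with M the (possibly PC-filtered or regularized) covariance inverse.
    Because M is positive semi-definite this is a squared cosine in
    whitened coordinates and lies in [0, 1]; a voxel with no whitened
    energy (x = mu_b) scores 0.
    """
    if mask.labels.shape != cube.grid_shape:
        raise ValueError("mask grid does not match hypercube grid")
    minv = inverse_operator(bg, spec)
    d = sig.s - bg.mean
    md = minv @ d
    sden = float(d @ md)
    if sden <= 0:
        raise ValueError("signature coincides with the background mean")

    inside = mask.inside
    x = cube.values[inside] - bg.mean
    num = (x @ md) ** 2
    xden = np.einsum("ij,ij->i", x @ minv, x)
    den = sden * xden
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(den > 0, num / den, 0.0)
    s = np.clip(s, 0.0, 1.0)

    scores = np.zeros(cube.grid_shape)
    scores[inside] = s
    return AceMap(scores, inside, cube.spacing_mm)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def blob_volume(n_voxels: int, spacing_mm) -> float:
    """Volume in cc of n voxels at the given spacing (mm^3 -> cc)."""
    r, c, s = spacing_mm
    return n_voxels * r * c * s / 1000.0


def eccentricity(
    coords: np.ndarray,
    spacing_mm,
    metric: str = "sqrt",
) -> tuple[float, float, float]:
    """Blob eccentricity from scatter-matrix eigenvalues in mm coordinates.

    Returns (E, l, s): the second-central-moment matrix of the voxel world
    coordinates is eigen-decomposed, the largest eigenvalue l is the major
    axis moment, the second s the transverse moment, and
    E = sqrt(1 - s/l) (default) or (l-s)/(l+s) with ``metric="ratio"``.
    A single-voxel or degenerate blob scores 0 by convention.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    world = coords * np.asarray(spacing_mm, dtype=float)
    if world.shape[0] < 2:
        return 0.0, 0.0, 0.0
    centered = world - world.mean(axis=0)
    scatter = centered.T @ centered / world.shape[0]
    evals = np.sort(np.linalg.eigvalsh(scatter))[::-1]
    l, s = float(evals[0]), float(evals[1])
    if l <= 0:
        return 0.0, l, s
    if metric == "sqrt":
        e = float(np.sqrt(max(0.0, 1.0 - s / l)))
    elif metric == "ratio":
        e = (l - s) / (l + s)
    else:
        raise ValueError("metric must be 'sqrt' or 'ratio'")
    return e, l, s


def threshold_blobs(
    ace: AceMap,
    tau: float,
    connectivity: int = 26,
    ecc_metric: str = "sqrt",
) -> BlobSet:
    """Connected components of voxels with ACE score strictly above tau.

    Components use 26-connectivity by default (corner-touching voxels
    merge) and are labeled deterministically in scan order.  An empty
    result is legitimate: nothing exceeded the threshold.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    binary = ace.scores > tau
    labels, n = ndimage.label(binary, structure=_structure(connectivity))
    blobs = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        e, l, s = eccentricity(coords, ace.spacing_mm, metric=ecc_metric)
        blobs.append(
            Blob(
                label=lab,
                coords=coords,
                n_voxels=coords.shape[0],
                volume_cc=blob_volume(coords.shape[0], ace.spacing_mm),
                l_mm2=l,
                s_mm2=s,
                eccentricity=e,
            )
        )
    return BlobSet(blobs, ace.spacing_mm)


def largest_blob(blobs: BlobSet) -> Blob:
    """The blob with the most voxels; ties go to the smallest label."""
    if len(blobs) == 0:
        raise ValueError("no detection")
    return max(blobs, key=lambda b: (b.n_voxels, -b.label))
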