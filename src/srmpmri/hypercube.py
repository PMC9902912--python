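"""Spatially registered multi-parametric MRI hypercubes.

A hypercube is a 3-D voxel grid (rows, cols, slices) whose every voxel
carries a spectral vector — one value per registered MRI band (T1
pre-contrast, T1 maximum contrast, T2, ADC, high-B DWI, DCE washout rate,
...).  This module provides the container types, rigid resampling of native
per-modality images onto the common 1 x 1 x 6 mm grid, stitching of
registered cubes along the slice axis, and the exponential washout fit that
turns a dynamic contrast-enhanced (DCE) time series into a k_ep band.

Conventions: voxel indices are 0-based; world coordinate (mm) of index
(i, j, k) is ``index * spacing + origin_offset``; the slice axis is axis 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "Hypercube",
    "ProstateMask",
    "DceSeries",
    "WashoutFit",
    "resample_to_grid",
    "stack_and_stitch",
    "fit_washout",
    "save_hypercube",
    "load_hypercube",
    "save_mask",
    "load_mask",
]

#: washout decay rates are bounded to this interval (1/min)
KEP_MAX_PER_MIN = 10.0


@dataclass
class Hypercube:
    """Registered multi-band voxel grid.

    values has shape (rows, cols, slices, bands); spacing_mm is the
    physical voxel pitch along (row, col, slice).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    band_names: list[str]
    origin_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("hypercube values must be 4-D (rows, cols, slices, bands)")
        if self.values.shape[3] < 1:
            raise ValueError("hypercube needs at least one band")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if len(self.band_names) != self.values.shape[3]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.values.shape[3]} bands"
            )

    @property
    def n_bands(self) -> int:
        return self.values.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def voxel_vectors(self, where: np.ndarray) -> np.ndarray:
        """Spectral vectors of the voxels selected by a 3-D boolean array."""
        return self.values[np.asarray(where, dtype=bool)]


@dataclass
class ProstateMask:
    """Voxel labels on the hypercube grid: 0 outside, 1 normal prostate, 2 tumor."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not np.isin(np.unique(self.labels), (0, 1, 2)).all():
            raise ValueError("mask labels must be 0, 1 or 2")

    @property
    def background(self) -> np.ndarray:
        return self.labels == 1

    @property
    def tumor(self) -> np.ndarray:
        return self.labels == 2

    @property
    def inside(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class DceSeries:
    """Per-voxel contrast-agent concentration curves.

    values has shape (n_voxels, n_times); times_s is strictly increasing.
    """

    values: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size == 0:
            raise ValueError("empty time grid")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[1] != self.times_s.size:
            raise ValueError("values/time length mismatch")


@dataclass
class WashoutFit:
    """Result of the post-peak exponential decay fit, one entry per voxel."""

    kep_per_min: np.ndarray
    amplitude: np.ndarray
    t_peak_s: np.ndarray
    ok: np.ndarray  # False where too few post-peak samples

    def __len__(self) -> int:
        return self.kep_per_min.size


def resample_to_grid(
    image: np.ndarray,
    native_spacing_mm: tuple[float, float, float],
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 6.0),
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Rigidly resample a native-resolution 3-D image onto the target grid.

    In-plane (axes 0, 1) values are linearly interpolated; slices are
    aligned by table position, i.e. each output slice takes the nearest
    native slice.  ``translation_mm`` shifts the native image in world
    coordinates before resampling (the only rigid adjustment supported).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("expected a 3-D image")
    nat = np.asarray(native_spacing_mm, dtype=float)
    tgt = np.asarray(target_spacing_mm, dtype=float)
    if np.any(nat <= 0) or np.any(tgt <= 0):
        raise ValueError("spacings must be positive")
    tr = np.asarray(translation_mm, dtype=float)

    # output grid spans the translated native extent
    extent = (np.array(image.shape) - 1) * nat + tr
    n_out = np.maximum(np.floor(extent / tgt + 1e-9).astype(int) + 1, 1)

    axes = [np.arange(n) * tgt[a] for a, n in enumerate(n_out)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    src = [
        (ii - tr[0]) / nat[0],
        (jj - tr[1]) / nat[1],
        np.round((kk - tr[2]) / nat[2]),  # nearest-slice reslice
    ]
    lo_ok = [(c >= -0.5).any() for c in src]
    hi_ok = [(src[a] <= image.shape[a] - 0.5).any() for a in range(3)]
    if not (all(lo_ok) and all(hi_ok)):
        raise ValueError("grids do not overlap")
    return ndimage.map_coordinates(image, src, order=1, mode="nearest")


def stack_and_stitch(
    cubes: list[np.ndarray],
    spacing_mm: tuple[float, float, float],
    band_names: list[str],
) -> tuple[Hypercube, list[tuple[int, int]]]:
    """Concatenate registered multi-band cubes along the slice axis.

    Each cube is (rows, cols, slices, bands) or (rows, cols, bands) for a
    single slice.  Returns the stitched hypercube and a provenance map
    giving, for every output slice, the (cube index, slice index) it came
    from.  All downstream statistics are voxel-set based, so they are
    invariant to the stitching layout.
    """
    if not cubes:
        raise ValueError("no cubes to stitch")
    arrs = []
    for c in cubes:
        a = np.asarray(c, dtype=float)
        if a.ndim == 3:
            a = a[:, :, None, :]
        if a.ndim != 4:
            raise ValueError("each cube must be 3-D (single slice) or 4-D")
        arrs.append(a)
    bands = arrs[0].shape[3]
    plane = arrs[0].shape[:2]
    for a in arrs:
        if a.shape[3] != bands:
            raise ValueError("band count mismatch between cubes")
        if a.shape[:2] != plane:
            raise ValueError("in-plane shape mismatch between cubes")
    if bands != len(band_names):
        raise ValueError("band_names length mismatch")
    provenance = [
        (ci, si) for ci, a in enumerate(arrs) for si in range(a.shape[2])
    ]
    stitched = np.concatenate(arrs, axis=2)
    return Hypercube(stitched, tuple(spacing_mm), list(band_names)), provenance


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, np.log(c), 1)
    return float(slope), float(intercept)


def fit_washout(series: DceSeries, post_peak_delay_s: float = 50.0) -> WashoutFit:
    """Fit the post-peak exponential washout, voxel by voxel.

    For each voxel the peak time is the argmax of the curve; samples more
    than ``post_peak_delay_s`` after the peak are fitted with
    ``A * exp(-k_ep * t)`` by least squares on the log concentrations
    (exact for the noiseless model).  Voxels with non-positive samples in
    the fit window fall back to bounded nonlinear least squares initialized
    from the log-linear fit on the positive samples.  Voxels with fewer
    than 3 usable post-peak samples are flagged and get NaN estimates.

    Rates are reported in 1/min; the returned amplitude is the fitted
    concentration extrapolated to t = 0.
    """
    t = series.times_s
    curves = series.values
    n = curves.shape[0]
    kep = np.full(n, np.nan)
    amp = np.full(n, np.nan)
    tpk = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)

    for v in range(n):
        c = curves[v]
        ip = int(np.argmax(c))
        tpk[v] = t[ip]
        win = t > t[ip] + post_peak_delay_s
        if win.sum() < 3:
            continue
        tw, cw = t[win], c[win]
        ok[v] = True
        if np.all(cw > 0):
            slope, intercept = _loglinear(tw, cw)
            kps = max(-slope, 0.0)
            amp[v] = np.exp(intercept)
        else:
            pos = cw > 0
            if pos.sum() >= 2:
                slope, intercept = _loglinear(tw[pos], cw[pos])
                k0 = min(max(-slope, 0.0), KEP_MAX_PER_MIN / 60.0)
                a0 = max(np.exp(intercept), 1e-12)
            else:
                k0, a0 = 0.01, max(float(cw.max()), 1e-12)
            try:
                popt, _ = optimize.curve_fit(
                    lambda tt, a, k: a * np.exp(-k * tt),
                    tw,
                    cw,
                    p0=(a0, k0),
                    bounds=([1e-12, 0.0], [np.inf, KEP_MAX_PER_MIN / 60.0]),
                    maxfev=2000,
                )
                amp[v], kps = float(popt[0]), float(popt[1])
            except RuntimeError:
                ok[v] = False
                continue
        kep[v] = min(kps * 60.0, KEP_MAX_PER_MIN)
    return WashoutFit(kep, amp, tpk, ok)


# ---------------------------------------------------------------------------
# NIfTI I/O.  The affine is diagonal in the voxel spacing; band names travel
# in a JSON sidecar next to the image.


def _affine(spacing_mm, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_hypercube(cube: Hypercube, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(cube.values.astype(np.float32), _affine(cube.spacing_mm, cube.origin_offset_mm))
    img.header.set_zooms(tuple(cube.spacing_mm) + (1.0,))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "band_names": cube.band_names,
                "spacing_mm": list(cube.spacing_mm),
                "origin_offset_mm": list(cube.origin_offset_mm),
            },
            indent=2,
        )
    )


def load_hypercube(path: str | Path) -> Hypercube:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = meta["band_names"]
        spacing = tuple(meta["spacing_mm"])
        origin = tuple(meta.get("origin_offset_mm", (0.0, 0.0, 0.0)))
    else:
        names = [f"band{i}" for i in range(values.shape[3])]
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = (0.0, 0.0, 0.0)
    return Hypercube(values, spacing, names, origin)


def save_mask(mask: ProstateMask, spacing_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(spacing_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> ProstateMask:
    img = nib.load(str(path))
    return ProstateMask(np.asarray(img.dataobj).astype(int))
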