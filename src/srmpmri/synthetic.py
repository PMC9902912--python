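"""Synthetic multi-parametric prostate MRI cohorts.

Generates registered hypercubes with the statistical structure the
downstream analysis assumes: a multivariate-Gaussian normal-prostate
background with correlated band statistics on a 1 x 1 x 6 mm grid, an
ellipsoidal tumor of controllable volume, axis ratio (hence eccentricity)
and spectral contrast, per-voxel DCE concentration curves with an
exponential washout, and a clinically-significant-cancer label drawn from
a logistic model on the true (generator-side) shape, contrast and volume
features.  The label model uses the *true* features, so measurement error
in the imaging pipeline attenuates — never inflates — downstream accuracy.

Every patient is reproducible in isolation: patient i of a cohort with
seed S uses the generator ``default_rng([S, i])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hypercube import DceSeries, Hypercube, ProstateMask, save_hypercube, save_mask

__all__ = [
    "CohortParams",
    "TumorTruth",
    "CohortBundle",
    "default_background_cov",
    "simulate_patient",
    "simulate_dce_series",
    "simulate_cohort",
]

BAND_NAMES = ["t1_pre", "t1_max", "t2", "adc", "dwi_b1000", "dce_kep", "spare"]

# Band scales chosen to look like clinical units: T1/T2/DWI in arbitrary
# scanner intensity, ADC in 1e-6 mm^2/s, washout k_ep in 1/min.
_BG_MEAN = np.array([350.0, 700.0, 500.0, 1100.0, 160.0, 0.40, 100.0])
_BG_SD = np.array([40.0, 90.0, 80.0, 140.0, 25.0, 0.12, 15.0])
_BG_CORR = np.array(
    [
        [1.00, 0.55, 0.10, 0.05, 0.05, 0.10, 0.05],
        [0.55, 1.00, 0.10, 0.05, 0.05, 0.35, 0.05],
        [0.10, 0.10, 1.00, 0.45, -0.20, 0.05, 0.05],
        [0.05, 0.05, 0.45, 1.00, -0.55, -0.10, 0.05],
        [0.05, 0.05, -0.20, -0.55, 1.00, 0.15, 0.05],
        [0.10, 0.35, 0.05, -0.10, 0.15, 1.00, 0.05],
        [0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 1.00],
    ]
)

# Tumor spectral contrast: stronger enhancement and washout, darker T2,
# restricted diffusion (ADC down, high-B DWI up).  Magnitudes follow the
# clinical picture of significant lesions (ADC ~0.6 of normal, dark T2,
# avid enhancement), which makes the signature conspicuous to ACE.
_TUMOR_OFFSET = np.array([0.0, 300.0, -265.0, -490.0, 115.0, 0.50, 0.0])


def default_background_cov() -> np.ndarray:
    return _BG_CORR * np.outer(_BG_SD, _BG_SD)


@dataclass
class CohortParams:
    """Study conditions for a synthetic cohort.

    label_coefficients are (b0, b_ecc, b_scr, b_vol) of the logistic model
    generating the clinically-significant-cancer label from the true
    eccentricity, full-inverse SCR and volume (cc); the defaults were
    calibrated once so that the oracle AUC of the generating probabilities
    is ~0.9 at prevalence ~0.4.
    """

    n_patients: int = 26
    band_names: list[str] = field(default_factory=lambda: list(BAND_NAMES))
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 6.0)
    prostate_semi_axes_mm: tuple[float, float, float] = (22.0, 18.0, 15.0)
    background_mean: np.ndarray = field(default_factory=lambda: _BG_MEAN.copy())
    background_cov: np.ndarray = field(default_factory=default_background_cov)
    tumor_signature_offset: np.ndarray = field(default_factory=lambda: _TUMOR_OFFSET.copy())
    tumor_volume_range_cc: tuple[float, float] = (0.3, 3.0)
    tumor_axis_ratio_range: tuple[float, float] = (1.0, 2.5)
    tumor_contrast_range: tuple[float, float] = (0.5, 1.5)
    dce_time_grid_s: np.ndarray = field(default_factory=lambda: np.arange(0.0, 310.0, 10.0))
    kep_range_per_min: tuple[float, float] = (0.2, 1.5)
    background_kep_per_min: float = 0.1
    label_coefficients: tuple[float, float, float, float] = (-11.2, 2.3, 1.05, 0.95)
    heavy_tails_df: float | None = None  # Student-t dof for robustness tests
    seed: int = 0

    def __post_init__(self) -> None:
        self.background_mean = np.asarray(self.background_mean, dtype=float)
        self.background_cov = np.asarray(self.background_cov, dtype=float)
        self.tumor_signature_offset = np.asarray(self.tumor_signature_offset, dtype=float)
        self.dce_time_grid_s = np.asarray(self.dce_time_grid_s, dtype=float)
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        b = len(self.band_names)
        if self.background_mean.size != b or self.background_cov.shape != (b, b):
            raise ValueError("background statistics do not match the band count")
        if not np.allclose(self.background_cov, self.background_cov.T):
            raise ValueError("background covariance must be symmetric")
        if np.linalg.eigvalsh(self.background_cov).min() <= 0:
            raise ValueError("background covariance must be positive definite")

    @property
    def n_bands(self) -> int:
        return len(self.band_names)

    def true_scr(self, contrast: float = 1.0) -> float:
        """Full-inverse SCR of the (scaled) tumor signature offset."""
        d = contrast * self.tumor_signature_offset
        return float(np.sqrt(d @ np.linalg.solve(self.background_cov, d)))


@dataclass
class TumorTruth:
    """Generator-side ground truth for one patient's tumor."""

    center_voxel: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    angle_rad: float
    true_volume_cc: float
    true_eccentricity: float
    signature_offset: np.ndarray
    contrast: float
    true_kep_per_min: float
    true_scr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_eccentricity <= 1.0:
            raise ValueError("eccentricity must lie in [0, 1]")
        if self.true_volume_cc <= 0:
            raise ValueError("volume must be positive")


@dataclass
class CohortBundle:
    """A simulated cohort: parameters plus the per-patient truth table.

    Hypercubes are reproducible on demand via ``patient(i)`` rather than
    held in memory; the truth table has one row per patient with the true
    features, generating probability and drawn CsPCa label.
    """

    params: CohortParams
    truth: pd.DataFrame

    def patient(self, patient_id: int):
        return simulate_patient(self.params, patient_id)


def _prostate_grid(params: CohortParams, margin_mm: float = 4.0):
    semi = np.asarray(params.prostate_semi_axes_mm, dtype=float)
    spacing = np.asarray(params.spacing_mm, dtype=float)
    shape = np.ceil(2 * (semi + margin_mm) / spacing).astype(int) + 1
    center = (shape - 1) / 2.0 * spacing
    idx = [np.arange(n) * spacing[a] for a, n in enumerate(shape)]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1)
    rel = (world - center) / semi
    prostate = (rel**2).sum(axis=-1) <= 1.0
    return shape, center, world, prostate


def _tumor_voxels(world, center_mm, semi_axes_mm, angle_rad):
    """Boolean array of voxels inside the in-plane-rotated ellipsoid."""
    rel = world - center_mm
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x = c * rel[..., 0] + s * rel[..., 1]
    y = -s * rel[..., 0] + c * rel[..., 1]
    z = rel[..., 2]
    a, b, cz = semi_axes_mm
    return (x / a) ** 2 + (y / b) ** 2 + (z / cz) ** 2 <= 1.0


def simulate_patient(
    params: CohortParams, patient_seed: int
) -> tuple[Hypercube, ProstateMask, TumorTruth]:
    """Simulate one registered hypercube, its mask and the tumor ground truth.

    Background voxels inside the prostate are multivariate-normal draws;
    tumor voxels additionally carry the (contrast-scaled) signature offset;
    voxels outside the organ are zero.  The tumor is a solid ellipsoid with
    its major axis in-plane, rasterized at the grid spacing, and must fit
    inside the prostate.
    """
    rng = np.random.default_rng([params.seed, patient_seed])
    shape, center, world, prostate = _prostate_grid(params)

    vol_cc = rng.uniform(*params.tumor_volume_range_cc)
    ratio = rng.uniform(*params.tumor_axis_ratio_range)
    contrast = rng.uniform(*params.tumor_contrast_range)
    kep = rng.uniform(*params.kep_range_per_min)
    # prolate ellipsoid: semi-axes (a, b, b) with a = ratio * b
    b_mm = (3.0 * vol_cc * 1000.0 / (4.0 * np.pi * ratio)) ** (1.0 / 3.0)
    a_mm = ratio * b_mm
    semi = np.asarray(params.prostate_semi_axes_mm, dtype=float)
    # major axis lies in-plane, minor axes through-plane
    if a_mm >= min(semi[0], semi[1]) or b_mm >= semi[2]:
        raise ValueError("tumor exceeds organ")
    ecc_true = float(np.sqrt(max(0.0, 1.0 - 1.0 / ratio**2)))

    # admissible center offsets shrink as the tumor approaches the capsule
    max_off = np.minimum(0.35 * semi, 0.9 * (semi - np.array([a_mm, a_mm, b_mm])))
    max_off = np.maximum(max_off, 0.0)
    tumor = None
    for _ in range(200):
        angle = rng.uniform(0.0, np.pi)
        offset = rng.uniform(-1.0, 1.0, size=3) * max_off
        cand = _tumor_voxels(world, center + offset, (a_mm, b_mm, b_mm), angle)
        if cand.any() and not np.any(cand & ~prostate):
            tumor = cand
            break
    if tumor is None:
        raise ValueError("tumor exceeds organ")

    labels = np.zeros(shape, dtype=np.int16)
    labels[prostate] = 1
    labels[tumor] = 2

    values = np.zeros(shape.tolist() + [params.n_bands])
    n_in = int(prostate.sum())
    if params.heavy_tails_df is None:
        draws = rng.multivariate_normal(
            params.background_mean, params.background_cov, size=n_in, method="cholesky"
        )
    else:
        # multivariate Student-t via scale mixture, same location/scatter
        g = rng.chisquare(params.heavy_tails_df, size=n_in) / params.heavy_tails_df
        z = rng.multivariate_normal(
            np.zeros(params.n_bands), params.background_cov, size=n_in, method="cholesky"
        )
        draws = params.background_mean + z / np.sqrt(g)[:, None]
    values[prostate] = draws
    values[tumor] += contrast * params.tumor_signature_offset

    truth = TumorTruth(
        center_voxel=tuple((center / np.asarray(params.spacing_mm)).tolist()),
        semi_axes_mm=(a_mm, b_mm, b_mm),
        angle_rad=float(angle),
        true_volume_cc=float(vol_cc),
        true_eccentricity=ecc_true,
        signature_offset=contrast * params.tumor_signature_offset,
        contrast=float(contrast),
        true_kep_per_min=float(kep),
        true_scr=params.true_scr(contrast),
    )
    cube = Hypercube(values, params.spacing_mm, list(params.band_names))
    return cube, ProstateMask(labels), truth


def simulate_dce_series(
    truth: TumorTruth,
    params: CohortParams,
    noise_sd: float = 0.0,
    n_voxels: int = 1,
    amplitude: float = 1.0,
    t_peak_s: float = 60.0,
    background_voxels: int = 0,
    seed: int = 0,
) -> DceSeries:
    """Per-voxel DCE concentration curves for a tumor (plus optional background).

    The rise to the peak is a gamma-variate bolus shape
    ``A (t/tp)^2 exp(2 (1 - t/tp))`` peaking at ``t_peak_s`` with value A;
    after the peak the curve decays as ``A exp(-k_ep (t - tp))`` with the
    tumor's true washout rate (background voxels use the slower cohort
    default).  Gaussian noise of sd ``noise_sd`` is added throughout.
    """
    t = params.dce_time_grid_s
    if t.size == 0:
        raise ValueError("empty time grid")
    if t.max() <= t_peak_s:
        raise ValueError("time grid must extend beyond the uptake peak")
    rng = np.random.default_rng([params.seed, seed, 7919])

    def curve(kep_per_min: float) -> np.ndarray:
        rise = amplitude * (t / t_peak_s) ** 2 * np.exp(2.0 * (1.0 - t / t_peak_s))
        decay = amplitude * np.exp(-(kep_per_min / 60.0) * (t - t_peak_s))
        return np.where(t <= t_peak_s, rise, decay)

    rows = [curve(truth.true_kep_per_min) for _ in range(n_voxels)]
    rows += [curve(params.background_kep_per_min) for _ in range(background_voxels)]
    values = np.asarray(rows)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return DceSeries(values, t)


def _true_features(params: CohortParams, n: int) -> pd.DataFrame:
    """Draw the per-patient true features exactly as simulate_patient does.

    Kept in lockstep with simulate_patient by re-deriving each patient's
    own RNG stream, so the truth table matches the rendered hypercubes.
    """
    rows = []
    for pid in range(1, n + 1):
        prng = np.random.default_rng([params.seed, pid])
        vol = prng.uniform(*params.tumor_volume_range_cc)
        ratio = prng.uniform(*params.tumor_axis_ratio_range)
        contrast = prng.uniform(*params.tumor_contrast_range)
        kep = prng.uniform(*params.kep_range_per_min)
        rows.append(
            {
                "patient_id": pid,
                "true_ecc": float(np.sqrt(max(0.0, 1.0 - 1.0 / ratio**2))),
                "true_scr": params.true_scr(contrast),
                "true_vol_cc": float(vol),
                "true_kep_per_min": float(kep),
                "contrast": float(contrast),
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    params: CohortParams,
    out_dir: str | Path | None = None,
) -> CohortBundle:
    """Simulate the cohort truth table and draw the CsPCa labels.

    Labels are Bernoulli draws of logistic(b0 + b_ecc*Ecc + b_scr*SCR +
    b_vol*Vol) on the true features.  If ``out_dir`` is given, each
    patient's hypercube and mask are written as NIfTI with a JSON sidecar
    and the truth table as CSV.
    """
    rng = np.random.default_rng([params.seed, 0])
    table = _true_features(params, params.n_patients)
    b0, be, bs, bv = params.label_coefficients
    eta = b0 + be * table["true_ecc"] + bs * table["true_scr"] + bv * table["true_vol_cc"]
    p = 1.0 / (1.0 + np.exp(-eta))
    table["p_cspca"] = p
    table["cspca"] = (rng.random(len(table)) < p).astype(int)

    bundle = CohortBundle(params, table)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid in table["patient_id"]:
            cube, mask, _ = simulate_patient(params, int(pid))
            save_hypercube(cube, out / f"patient_{pid:03d}_cube.nii.gz")
            save_mask(mask, params.spacing_mm, out / f"patient_{pid:03d}_mask.nii.gz")
        table.to_csv(out / "truth.csv", index=False)
        (out / "cohort.json").write_text(
            json.dumps(
                {
                    "band_names": params.band_names,
                    "spacing_mm": list(params.spacing_mm),
                    "n_patients": params.n_patients,
                    "seed": params.seed,
                    "label_coefficients": list(params.label_coefficients),
                },
                indent=2,
            )
        )
    return bundle
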