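"""End-to-end study: detect tumors, measure features, fit and evaluate models.

``measure_patient_features`` runs the imaging half of the pipeline on one
registered hypercube: estimate the background clutter from the outlined
normal prostate, take the tumor signature as the mean of the
tumor-labeled voxels, score with ACE, and extract largest-blob
eccentricity (threshold 0.45), detected volume (threshold 0.65) and the
four SCR variants.  ``run_study`` maps this over a cohort, assembles the
feature table, fits the configured variable subsets (all patients plus
the even/odd train-test protocol), and reports F, p, R-squared, AUC with
DeLong confidence intervals, a nomogram and decision curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical
from .background import BackgroundModel, InverseSpec, estimate_background, scr, select_gamma
from .detection import TumorSignature, ace_map, largest_blob, threshold_blobs
from .hypercube import Hypercube, ProstateMask
from .synthetic import CohortBundle, CohortParams, simulate_cohort

__all__ = ["StudyConfig", "measure_patient_features", "run_study", "DEFAULT_SUBSETS"]

#: the variable subsets reported by default (full-cohort protocol)
DEFAULT_SUBSETS: list[list[str]] = [
    ["scr_3pc", "vol_065"],
    ["ecc_045", "scr_3pc"],
    ["ecc_045", "scr_modreg", "scr_3pc"],
    ["ecc_045", "scr_reg", "scr_3pc"],
    ["ecc_045", "scr_3pc", "vol_065"],
    ["ecc_045", "scr_reg", "scr_3pc", "vol_065"],
    ["ecc_045", "scr_modreg", "scr_3pc", "vol_065"],
]

#: subsets additionally run through the even/odd train-test protocol
TRAIN_TEST_SUBSETS: list[list[str]] = [
    ["scr_3pc", "vol_065"],
    ["ecc_045", "scr_reg", "scr_3pc"],
    ["ecc_045", "scr_reg", "scr_3pc", "vol_065"],
]


@dataclass
class StudyConfig:
    tau_ecc: float = 0.45
    tau_vol: float = 0.65
    connectivity: int = 26
    subsets: list[list[str]] = field(default_factory=lambda: [list(s) for s in DEFAULT_SUBSETS])
    train_test_subsets: list[list[str]] = field(
        default_factory=lambda: [list(s) for s in TRAIN_TEST_SUBSETS]
    )
    nomogram_subset: list[str] = field(default_factory=lambda: ["ecc_045", "scr_reg", "scr_3pc"])
    dca_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.01, 1.0, 0.01), 2))
    gamma_subsample: int = 5000  # background voxels used for gamma selection
    seed: int = 0


def _subset_name(subset: list[str]) -> str:
    return "+".join(subset)


def measure_patient_features(
    cube: Hypercube,
    mask: ProstateMask,
    config: StudyConfig = StudyConfig(),
    signature: np.ndarray | None = None,
) -> dict:
    """Measure the six imaging features of one patient.

    The tumor signature defaults to the mean spectral vector of the voxels
    labeled tumor (2) in the mask — any voxel-set mean works.  Returns a
    feature record suitable for ``clinical.assemble_features``; a patient
    whose detection yields no blob at the eccentricity threshold comes
    back flagged missing.
    """
    bg = estimate_background(cube, mask)
    if signature is None:
        tumor_voxels = cube.voxel_vectors(mask.tumor)
        if tumor_voxels.shape[0] == 0:
            return {"missing": True, "reason": "no tumor voxels to take a signature from"}
        sig = TumorSignature.from_voxels(tumor_voxels)
    else:
        sig = TumorSignature(signature)

    bg_voxels = cube.voxel_vectors(mask.background)
    if bg_voxels.shape[0] > config.gamma_subsample:
        take = np.random.default_rng(config.seed + 104729).choice(
            bg_voxels.shape[0], config.gamma_subsample, replace=False
        )
        gamma_voxels = bg_voxels[take]
    else:
        gamma_voxels = bg_voxels

    record: dict = {}
    for name, k in (("scr_3pc", 3), ("scr_4pc", 4)):
        record[name] = scr(sig.s, bg, InverseSpec("pc_filtered", k_removed=k))
    for name, mode in (("scr_reg", "standard"), ("scr_modreg", "modified")):
        g = select_gamma(bg, mode, gamma_voxels)
        spec = InverseSpec("regularized" if mode == "standard" else "modified_regularized", gamma=g)
        record[name] = scr(sig.s, bg, spec)
        record[f"gamma_{name}"] = g

    ace = ace_map(cube, mask, sig, bg)
    blobs_ecc = threshold_blobs(ace, config.tau_ecc, connectivity=config.connectivity)
    if len(blobs_ecc) == 0:
        return {"missing": True, "reason": f"no blob above ACE threshold {config.tau_ecc}"}
    record["ecc_045"] = largest_blob(blobs_ecc).eccentricity
    blobs_vol = threshold_blobs(ace, config.tau_vol, connectivity=config.connectivity)
    record["vol_065"] = blobs_vol.total_volume_cc
    return record


def _fit_summary(fit: clinical.LogisticFit, roc: clinical.RocResult) -> dict:
    return {
        "variables": list(fit.variables),
        "k": len(fit.variables),
        "n": fit.n,
        "f_value": fit.f_value,
        "p_value": fit.f_pvalue,
        "r2": fit.r2_linprob,
        "r2_outcome_prob": fit.r2_outcome_prob,
        "r2_mcfadden": fit.r2_mcfadden,
        "r2_nagelkerke": fit.r2_nagelkerke,
        "lrt_pvalue": fit.lrt_pvalue,
        "auc": roc.auc,
        "auc_ci_ll": roc.ci95[0],
        "auc_ci_ul": roc.ci95[1],
    }


def build_feature_table(cohort: CohortBundle, config: StudyConfig = StudyConfig()) -> pd.DataFrame:
    """Render each patient's hypercube, measure features, join the labels."""
    records = []
    labels = cohort.truth.set_index("patient_id")["cspca"]
    for pid in cohort.truth["patient_id"]:
        cube, mask, _ = cohort.patient(int(pid))
        rec = measure_patient_features(cube, mask, config)
        rec["patient_id"] = int(pid)
        rec["cspca"] = int(labels.loc[pid])
        records.append(rec)
    return clinical.assemble_features(records)


def run_study(
    cohort: CohortBundle | CohortParams | pd.DataFrame,
    config: StudyConfig = StudyConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis and return a machine-readable report.

    ``cohort`` may be cohort parameters (simulated on the fly), a simulated
    bundle, or a ready feature table with the columns of
    ``clinical.FEATURE_COLUMNS`` plus patient_id and cspca.
    """
    if isinstance(cohort, CohortParams):
        cohort = simulate_cohort(cohort)
    if isinstance(cohort, CohortBundle):
        table = build_feature_table(cohort, config)
    else:
        table = cohort.copy()

    report: dict = {
        "n_patients": int(len(table)),
        "prevalence": float(table["cspca"].mean()),
        "seed": config.seed,
        "fits": [],
        "train_test": [],
    }

    fits: dict[str, clinical.LogisticFit] = {}
    for subset in config.subsets:
        fit = clinical.fit_logistic(table, subset)
        roc = clinical.roc_auc(fit.fitted.to_numpy(), table["cspca"].to_numpy())
        fits[_subset_name(subset)] = fit
        report["fits"].append(_fit_summary(fit, roc))

    train, test = clinical.split_train_test(table)
    for subset in config.train_test_subsets:
        try:
            fit = clinical.fit_logistic(train, subset)
        except ValueError as exc:
            report["train_test"].append({"variables": subset, "error": str(exc)})
            continue
        before = fit.coef_checksum()
        roc_train = clinical.roc_auc(fit.fitted.to_numpy(), train["cspca"].to_numpy())
        scores_test = fit.predict(test)
        roc_test = clinical.roc_auc(scores_test, test["cspca"].to_numpy())
        assert fit.coef_checksum() == before, "coefficients changed while scoring test set"
        entry = _fit_summary(fit, roc_train)
        entry.update(
            {
                "n_train": len(train),
                "n_test": len(test),
                "auc_train": roc_train.auc,
                "auc_test": roc_test.auc,
                "auc_test_ci_ll": roc_test.ci95[0],
                "auc_test_ci_ul": roc_test.ci95[1],
            }
        )
        report["train_test"].append(entry)

    # nomogram + decision curves for the configured display subset
    nomo_name = _subset_name(config.nomogram_subset)
    nomo_fit = fits.get(nomo_name) or clinical.fit_logistic(table, config.nomogram_subset)
    ranges = {v: (float(table[v].min()), float(table[v].max())) for v in config.nomogram_subset}
    nomogram = clinical.build_nomogram(nomo_fit, ranges)
    total = nomogram.total_points(table)
    report["nomogram"] = {
        "variables": list(config.nomogram_subset),
        "scale": nomogram.scale,
        "max_roundtrip_error": float(np.max(np.abs(nomogram.risk(total) - nomo_fit.fitted.to_numpy()))),
    }

    dca_fits = {nomo_name: nomo_fit}
    for v in config.nomogram_subset:
        dca_fits[v] = clinical.fit_logistic(table, [v])
    dca = clinical.decision_curve(dca_fits, table, pt_grid=config.dca_grid)
    report["dca"] = {
        "grid": [float(dca["pt"].iloc[0]), float(dca["pt"].iloc[-1])],
        "model": nomo_name,
        "nb_at_0.30": float(np.interp(0.30, dca["pt"], dca[nomo_name])),
    }

    if out_dir is not None:
        _write_outputs(Path(out_dir), report, table, nomogram, dca)
    return report


def _write_outputs(out: Path, report: dict, table: pd.DataFrame, nomogram, dca: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    table.to_csv(out / "features.csv", index=False)
    pd.DataFrame(report["fits"]).assign(
        variables=lambda d: d["variables"].map(_subset_name)
    ).to_csv(out / "fits.csv", index=False)
    dca.to_csv(out / "dca.csv", index=False)
    for v, ticks in nomogram.tick_tables.items():
        ticks.to_csv(out / f"nomogram_axis_{v}.csv", index=False)
    nomogram.risk_table.to_csv(out / "nomogram_risk.csv", index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    for col in dca.columns:
        if col != "pt":
            ax.plot(dca["pt"], dca[col], label=col)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(-0.1, max(0.5, float(dca.drop(columns="pt").to_numpy().max()) + 0.05))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "dca.svg")
    plt.close(fig)
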