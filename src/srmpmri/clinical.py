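"""Patient-level risk modeling: logistic fits, ROC, nomograms, decision curves.

The per-patient feature table carries the imaging-derived predictors —
largest-blob eccentricity at ACE threshold 0.45, the four SCR variants
(3 and 4 principal components removed, standard and modified shrinkage
regularization) and detected tumor volume at ACE threshold 0.65 — against
the binary outcome CsPCa (clinically significant prostate cancer,
Gleason >= 4+3).  Logistic regression combines feature subsets into a risk
probability; performance is summarized by the linear-probability F test,
several R-squared conventions, and the ROC AUC with a DeLong confidence
interval; the fitted model is rendered as a points-based nomogram and
evaluated by decision-curve analysis (net benefit over threshold
probabilities).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "FEATURE_COLUMNS",
    "LogisticFit",
    "RocResult",
    "NomogramSpec",
    "label_cspca",
    "assemble_features",
    "split_train_test",
    "fit_logistic",
    "roc_auc",
    "build_nomogram",
    "decision_curve",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["ecc_045", "scr_3pc", "scr_4pc", "scr_reg", "scr_modreg", "vol_065"]


def label_cspca(gleason_primary: int, gleason_secondary: int) -> int:
    """Clinically significant (1) vs insignificant (0) from Gleason grades.

    Significant disease is Gleason >= 4+3 in the primary-then-sum ordering:
    4+3 and above -> 1, 3+4 and below -> 0.
    """
    for g in (gleason_primary, gleason_secondary):
        if g not in (3, 4, 5):
            raise ValueError(f"Gleason grade {g} outside 3-5")
    return int((gleason_primary, gleason_primary + gleason_secondary) >= (4, 7))


def assemble_features(records: list[dict]) -> pd.DataFrame:
    """Build the per-patient feature table, excluding flagged patients.

    Each record needs patient_id, the feature columns and cspca; a record
    with ``missing`` set (or a non-finite feature) is dropped with a logged
    reason, mirroring cohorts where e.g. a patient fails contrast uptake.
    """
    rows, dropped = [], []
    for rec in records:
        if rec.get("missing"):
            dropped.append((rec["patient_id"], str(rec.get("reason", "flagged missing"))))
            continue
        vals = [rec.get(c, np.nan) for c in FEATURE_COLUMNS]
        if not np.all(np.isfinite(vals)):
            dropped.append((rec["patient_id"], "non-finite feature"))
            continue
        rows.append({"patient_id": rec["patient_id"], **dict(zip(FEATURE_COLUMNS, vals)), "cspca": int(rec["cspca"])})
    for pid, why in dropped:
        log.info("excluding patient %s: %s", pid, why)
    if not rows:
        raise ValueError("empty feature table after exclusions")
    table = pd.DataFrame(rows)
    if table["patient_id"].duplicated().any():
        dup = table.loc[table["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id {dup}")
    if not table["cspca"].isin([0, 1]).all():
        raise ValueError("cspca must be binary")
    return table.reset_index(drop=True)


def split_train_test(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Even-numbered patients train, odd-numbered test (1-based enrollment ids)."""
    even = table["patient_id"].astype(int) % 2 == 0
    train, test = table[even].copy(), table[~even].copy()
    if train.empty or test.empty:
        log.warning("parity split left one side empty (n=%d patients)", len(table))
    return train, test


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass
class LogisticFit:
    """A fitted logistic model with the fit-quality statistics reported here.

    The headline F and its p-value come from the linear-probability
    companion fit (OLS of the 0/1 outcome on the same covariates):
    F = (R2/k) / ((1-R2)/(n-k-1)).  r2_outcome_prob is the squared Pearson
    correlation between outcome and fitted probability; McFadden and
    Nagelkerke pseudo-R2 and the likelihood-ratio test are also carried.
    """

    variables: list[str]
    intercept: float
    coef: pd.Series
    fitted: pd.Series  # indexed by patient_id
    n: int
    converged: bool
    r2_outcome_prob: float
    r2_linprob: float
    r2_mcfadden: float
    r2_nagelkerke: float
    f_value: float
    f_pvalue: float
    lrt_chi2: float
    lrt_pvalue: float
    llf: float

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.variables].to_numpy(dtype=float)
        return self.intercept + x @ self.coef.to_numpy()

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Risk probabilities for new patients from the frozen coefficients."""
        return 1.0 / (1.0 + np.exp(-np.clip(self.linear_predictor(table), -500, 500)))

    def coef_checksum(self) -> str:
        payload = np.r_[self.intercept, self.coef.to_numpy()].tobytes()
        return hashlib.sha256(payload).hexdigest()


def _find_separating_variable(x: pd.DataFrame, y: np.ndarray) -> str | None:
    for col in x.columns:
        v = x[col].to_numpy(dtype=float)
        lo1, hi0 = v[y == 1].min(), v[y == 0].max()
        lo0, hi1 = v[y == 0].min(), v[y == 1].max()
        if lo1 > hi0 or lo0 > hi1:
            return col
    return None


def _firth_fit(x: np.ndarray, y: np.ndarray, tol: float = 1e-8, maxiter: int = 200) -> np.ndarray:
    """Jeffreys-prior penalized logistic fit (handles separation)."""
    beta = np.zeros(x.shape[1])
    for _ in range(maxiter):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        xw = x * w[:, None]
        fisher = x.T @ xw
        cov = np.linalg.inv(fisher)
        h = np.einsum("ij,jk,ik->i", xw, cov, x)  # hat diagonal
        score = x.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_logistic(
    table: pd.DataFrame,
    variables: list[str],
    outcome: str = "cspca",
    firth: bool = False,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of the outcome on a feature subset.

    Fitting is Newton/IRLS to tolerance 1e-8.  Complete separation raises
    an explicit error naming the separating variable unless ``firth=True``,
    which switches to the Jeffreys-penalized fit.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"unknown variables {missing}")
    y = table[outcome].to_numpy(dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 events and 2 non-events")
    x = table[list(variables)].astype(float)
    if (x.nunique() <= 1).any():
        const = x.columns[(x.nunique() <= 1)][0]
        raise ValueError(f"covariate {const!r} is constant")

    design = sm.add_constant(x.to_numpy(), has_constant="add")
    k, n = len(variables), len(y)

    sep = _find_separating_variable(x, y)
    if sep is not None and not firth:
        raise ValueError(
            f"complete separation on variable {sep!r}; refit with firth=True "
            "or drop the variable"
        )

    def _penalized():
        beta = _firth_fit(design, y)
        p = 1.0 / (1.0 + np.exp(-np.clip(design @ beta, -500, 500)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        return beta, p, llf, True

    if firth and sep is not None:
        beta, p, llf, converged = _penalized()
    else:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, design).fit(
                    method="newton", tol=tol, maxiter=maxiter, disp=False
                )
            beta = res.params
            p = res.predict(design)
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
        except (np.linalg.LinAlgError, PerfectSeparationWarning) as exc:
            # multivariate (quasi-)separation: no single variable separates,
            # but the likelihood still has no interior maximum
            if firth:
                beta, p, llf, converged = _penalized()
            else:
                raise ValueError(
                    "complete separation in the joint covariate space; "
                    "refit with firth=True or drop variables"
                ) from exc

    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll0 = float(np.sum(y * np.log(y.mean()) + (1 - y) * np.log1p(-y.mean())))
    lrt = max(2.0 * (llf - ll0), 0.0)
    lrt_p = float(stats.chi2.sf(lrt, df=k))
    r2_mcf = 1.0 - llf / ll0 if ll0 != 0 else np.nan
    r2_nag = (1.0 - np.exp(2.0 * (ll0 - llf) / n)) / (1.0 - np.exp(2.0 * ll0 / n))
    r2_out = float(np.corrcoef(y, p)[0, 1] ** 2)

    ols = sm.OLS(y, design).fit()
    r2_lin = float(ols.rsquared)
    dfree = n - k - 1
    f_val = (r2_lin / k) / ((1.0 - r2_lin) / dfree) if dfree > 0 else np.nan
    f_p = float(stats.f.sf(f_val, k, dfree)) if np.isfinite(f_val) else np.nan

    idx = table["patient_id"] if "patient_id" in table.columns else table.index
    return LogisticFit(
        variables=list(variables),
        intercept=float(beta[0]),
        coef=pd.Series(beta[1:], index=list(variables)),
        fitted=pd.Series(p, index=idx),
        n=n,
        converged=converged,
        r2_outcome_prob=r2_out,
        r2_linprob=r2_lin,
        r2_mcfadden=float(r2_mcf),
        r2_nagelkerke=float(r2_nag),
        f_value=float(f_val),
        f_pvalue=f_p,
        lrt_chi2=float(lrt),
        lrt_pvalue=lrt_p,
        llf=llf,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci95: tuple[float, float]
    auc_se: float
    ci95_bootstrap: tuple[float, float] | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via mid-rank placements."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    alls = np.r_[pos, neg]
    rank_all = stats.rankdata(alls)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n  # placement of each positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_auc(
    scores,
    labels,
    bootstrap: int = 0,
    seed: int = 0,
    alpha: float = 0.05,
) -> RocResult:
    """Empirical ROC curve with trapezoid AUC and DeLong 95% CI.

    The trapezoid AUC over all thresholds equals the Mann-Whitney statistic
    with ties counted one half.  ``bootstrap > 0`` adds a stratified
    percentile bootstrap interval as a secondary CI.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc, var = _delong_auc_variance(scores, labels)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1)))
    boot_ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        ipos = np.flatnonzero(labels == 1)
        ineg = np.flatnonzero(labels == 0)
        reps = np.empty(bootstrap)
        for b in range(bootstrap):
            take = np.r_[rng.choice(ipos, len(ipos)), rng.choice(ineg, len(ineg))]
            reps[b], _ = _delong_auc_variance(scores[take], labels[take])
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        boot_ci = (float(lo), float(hi))
    return RocResult(fpr, tpr, thr, auc, ci, se, boot_ci)


# ---------------------------------------------------------------------------
# Nomogram


@dataclass
class NomogramSpec:
    """Points-based rendering of a logistic model.

    Each variable axis maps its observed range onto 0..100*|b_i|*range_i/M
    points (M = the largest such span, so the strongest variable spans a
    full 0-100); summed points map back to risk through
    risk(T) = logistic(eta_min + M*T/100).
    """

    variables: list[str]
    reference: pd.Series  # per-variable value mapping to 0 points
    scale: float  # M
    eta_min: float
    ranges: pd.DataFrame  # columns lo, hi per variable
    fit: LogisticFit
    tick_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    risk_table: pd.DataFrame | None = None

    def points(self, variable: str, value) -> np.ndarray:
        b = self.fit.coef[variable]
        return 100.0 * b * (np.asarray(value, dtype=float) - self.reference[variable]) / self.scale

    def total_points(self, table: pd.DataFrame) -> np.ndarray:
        return sum(self.points(v, table[v]) for v in self.variables)

    def risk(self, total_points) -> np.ndarray:
        eta = self.eta_min + self.scale * np.asarray(total_points, dtype=float) / 100.0
        return 1.0 / (1.0 + np.exp(-eta))


def build_nomogram(
    fit: LogisticFit,
    ranges: pd.DataFrame | dict,
    n_ticks: int = 11,
) -> NomogramSpec:
    """Lay out the points axes of a fitted logistic model.

    ``ranges`` gives per-variable observed (lo, hi); the reference (zero
    point) end of each axis is the end minimizing b_i * x, so points are
    never negative, and the scale M = max_i |b_i| * (hi_i - lo_i) maps the
    most influential variable onto the full 0-100 axis.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if isinstance(ranges, dict):
        ranges = pd.DataFrame(ranges, index=["lo", "hi"]).T
    ranges = ranges.loc[fit.variables, ["lo", "hi"]].astype(float)
    span = ranges["hi"] - ranges["lo"]
    if (span <= 0).any():
        bad = span.index[span <= 0][0]
        raise ValueError(f"variable {bad!r} has zero observed range")
    scale = float((fit.coef.abs() * span).max())
    ref = pd.Series(
        np.where(fit.coef.to_numpy() > 0, ranges["lo"], ranges["hi"]),
        index=fit.variables,
    )
    eta_min = float(fit.intercept + (fit.coef * ref).sum())
    spec = NomogramSpec(
        variables=list(fit.variables),
        reference=ref,
        scale=scale,
        eta_min=eta_min,
        ranges=ranges,
        fit=fit,
    )
    for v in fit.variables:
        grid = np.linspace(ranges.loc[v, "lo"], ranges.loc[v, "hi"], n_ticks)
        spec.tick_tables[v] = pd.DataFrame({"value": grid, "points": spec.points(v, grid)})
    max_total = sum(max(spec.points(v, ranges.loc[v, "lo"]), spec.points(v, ranges.loc[v, "hi"])) for v in fit.variables)
    tgrid = np.linspace(0.0, float(max_total), 101)
    spec.risk_table = pd.DataFrame({"total_points": tgrid, "risk": spec.risk(tgrid)})
    return spec


# ---------------------------------------------------------------------------
# Decision-curve analysis


def decision_curve(
    fits: dict[str, LogisticFit],
    table: pd.DataFrame,
    outcome: str = "cspca",
    pt_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit of each model across threshold probabilities.

    A patient is called positive when the model's predicted probability is
    at least the threshold pt; NB(pt) = TP/N - (FP/N) * pt/(1-pt).  The
    treat-all and treat-none reference strategies are always included
    (treat-none is identically zero; treat-all tends to the prevalence as
    pt -> 0).
    """
    if pt_grid is None:
        pt_grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    pt_grid = np.asarray(pt_grid, dtype=float)
    if pt_grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((pt_grid <= 0) | (pt_grid >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    y = table[outcome].to_numpy(dtype=int)
    n = len(y)
    prev = y.mean()
    out = {"pt": pt_grid}
    w = pt_grid / (1.0 - pt_grid)
    out["treat_all"] = prev - (1.0 - prev) * w
    out["treat_none"] = np.zeros_like(pt_grid)
    for name, fit in fits.items():
        p = fit.predict(table)
        tp = ((p[:, None] >= pt_grid[None, :]) & (y[:, None] == 1)).sum(axis=0)
        fp = ((p[:, None] >= pt_grid[None, :]) & (y[:, None] == 0)).sum(axis=0)
        out[name] = tp / n - (fp / n) * w
    return pd.DataFrame(out)
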