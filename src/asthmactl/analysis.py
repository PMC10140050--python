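"""Descriptive tables and prevalence-ratio estimation (modified Poisson).

The outcome is the binary indicator of not-well-controlled asthma (ACT
score <= 19) at index.  Because the outcome is common (~30%), odds ratios
from logistic regression would overstate the prevalence ratio; instead a
Poisson regression with log link is fitted to the binary outcome and the
variance is corrected with the robust (sandwich) estimator — the "modified
Poisson" approach of Zou.  The model is fitted by iteratively reweighted
least squares (Newton scoring), converging on max |score| < 1e-8, and the
covariance is the HC0 sandwich

    cov = A^-1 B A^-1,   A = sum_i mu_i x_i x_i',   B = sum_i (y_i - mu_i)^2 x_i x_i'

with mu_i = exp(x_i' beta).  Prevalence ratios are exp(beta) with Wald 95%
confidence intervals exp(beta +/- 1.959964 SE).

Percentages in the descriptive tables are rounded half-up to one decimal.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import covariates as cov
from .act import NOT_WELL_CONTROLLED, classify_control, score_act
from .cohort import build_cohort
from .covariates import derive_covariates
from .data_model import EmrDataset, read_dataset
from .gina import STEPS, classify_patient, impute_sig_fields, load_dose_thresholds

__all__ = [
    "tabulate",
    "build_design",
    "fit_modified_poisson",
    "PrevalenceModelFit",
    "assemble_cohort_table",
    "run_analysis",
    "forest_plot",
    "round_half_up",
    "Z_95",
]

Z_95 = 1.959964
STEP_COLUMNS = [f"step_{s}" if s != "undefined" else "undefined" for s in STEPS]

#: model reference levels (largest / most interpretable categories; the
#: Step-1 reference is the stated choice of the study design)
REFERENCE_LEVELS = {
    "gina_step": "1",
    "race": "white",
    "ethnicity": "non_hispanic",
    "smoking": "non_smoker",
    "bmi_category": "normal",
    "visit_type": "primary_care",
}

_CATEGORY_ORDERS = {
    "race": cov.RACE_LEVELS,
    "ethnicity": cov.ETHNICITY_LEVELS,
    "smoking": cov.SMOKING_LEVELS,
    "bmi_category": cov.BMI_LEVELS,
    "visit_type": cov.VISIT_LEVELS,
}


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: int, total: int) -> Optional[float]:
    if total == 0:
        return None
    return float((Decimal(100 * n) / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# --- descriptive tables -------------------------------------------------

_TABLE_CHARACTERISTICS = [
    "control_status",
    "gina_step",
    "sex",
    "ethnicity",
    "race",
    "smoking",
    "bmi_category",
    "visit_type",
]


def _one_table(cohort: pd.DataFrame, column_var: str) -> pd.DataFrame:
    """Tidy count/percent table of each characteristic against *column_var*."""
    groups = {"overall": cohort}
    if column_var == "gina_step":
        for s in STEPS:
            label = f"step_{s}" if s != "undefined" else "undefined"
            groups[label] = cohort[cohort["gina_step"] == s]
    else:
        for status in ("well_controlled", "not_well_controlled"):
            groups[status] = cohort[cohort["control_status"] == status]
    rows = []
    for char in _TABLE_CHARACTERISTICS:
        if char == column_var or char not in cohort.columns:
            continue
        levels = (
            [f"step_{s}" if s != "undefined" else "undefined" for s in STEPS]
            if char == "gina_step"
            else sorted(cohort[char].astype(str).unique())
        )
        for level in levels:
            raw_level = level.replace("step_", "") if char == "gina_step" else level
            for col, frame in groups.items():
                n = int((frame[char].astype(str) == raw_level).sum())
                rows.append(
                    {
                        "characteristic": char,
                        "level": level,
                        "column": col,
                        "n": n,
                        "pct": _pct(n, len(frame)),
                    }
                )
    return pd.DataFrame(rows, columns=["characteristic", "level", "column", "n", "pct"])


def tabulate(cohort: pd.DataFrame) -> dict:
    """Both descriptive orientations: characteristics by GINA step and by
    control status, with counts and half-up 1-decimal percentages.

    Percentages are within-column (the column group is the denominator).
    An empty cohort yields tables with zero counts and blank percentages.
    """
    return {
        "by_step": _one_table(cohort, "gina_step"),
        "by_control": _one_table(cohort, "control_status"),
    }


def lookup(table: pd.DataFrame, characteristic: str, level: str, column: str):
    """Convenience accessor returning (n, pct) for one cell."""
    m = table[
        (table["characteristic"] == characteristic)
        & (table["level"] == level)
        & (table["column"] == column)
    ]
    if len(m) != 1:
        raise KeyError((characteristic, level, column))
    r = m.iloc[0]
    return int(r["n"]), (None if pd.isna(r["pct"]) else float(r["pct"]))


# --- design matrix ------------------------------------------------------

DEFAULT_COVARIATES = ("age_years", "race", "ethnicity", "smoking", "bmi_category", "visit_type")


def build_design(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Outcome vector and named design matrix for the prevalence model.

    Always includes the intercept and the five GINA-step indicators
    (Step 1 reference).  Categorical covariates enter as indicator blocks
    with the documented reference levels; age enters in years, continuous.
    Levels absent from the cohort are dropped (their coefficients are not
    estimable), as any factor-aware model matrix would do.
    """
    y = (cohort["control_status"] == NOT_WELL_CONTROLLED).to_numpy(dtype=float)
    cols = {"intercept": np.ones(len(cohort))}
    for s in ("2", "3", "4", "5", "undefined"):
        cols[f"step_{s}"] = (cohort["gina_step"] == s).to_numpy(dtype=float)
    for var in covariates:
        if var == "age_years":
            cols["age_years"] = cohort["age_years"].to_numpy(dtype=float)
            continue
        ref = REFERENCE_LEVELS[var]
        for level in _CATEGORY_ORDERS[var]:
            if level == ref:
                continue
            cols[f"{var}_{level}"] = (cohort[var] == level).to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    # drop unused step/category levels (all-zero indicators)
    empty = [c for c in X.columns if c != "intercept" and not X[c].any()]
    return y, X.drop(columns=empty)


# --- modified Poisson fit -----------------------------------------------

@dataclass
class PrevalenceModelFit:
    terms: list
    beta: np.ndarray
    robust_cov: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    @property
    def pr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.beta - Z_95 * self.se_robust)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.beta + Z_95 * self.se_robust)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se_robust": self.se_robust,
                "pr": self.pr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "beta": self.beta[i],
            "se_robust": self.se_robust[i],
            "pr": self.pr[i],
            "ci_low": self.ci_low[i],
            "ci_high": self.ci_high[i],
        }


class ModelError(ValueError):
    pass


def _collinear_columns(X: np.ndarray, terms) -> list:
    # QR with pivoting unavailable in numpy; flag columns whose removal does
    # not drop the rank (reported set, not a minimal one)
    r = np.linalg.matrix_rank(X)
    flagged = []
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == r:
            flagged.append(terms[j])
    return flagged


def fit_modified_poisson(y, X, tol: float = 1e-8, max_iter: int = 100) -> PrevalenceModelFit:
    """Poisson log-link ML fit with HC0 sandwich covariance.

    IRLS/Newton scoring initialized at beta = 0 except the intercept at
    log(mean(y)); convergence on max absolute score < *tol*.  Raises
    :class:`ModelError` for rank-deficient designs (naming collinear
    columns), degenerate outcomes (all 0 or all 1) and non-convergence.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        terms = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ModelError(f"need more observations ({n}) than parameters ({p})")
    if y.sum() == 0 or y.sum() == n:
        raise ModelError("outcome is constant (all 0 or all 1): model is separated")
    if np.linalg.matrix_rank(Xm) < p:
        raise ModelError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(_collinear_columns(Xm, terms))
        )

    beta = np.zeros(p)
    try:
        i0 = terms.index("intercept")
    except ValueError:
        i0 = None
    if i0 is not None:
        beta[i0] = np.log(y.mean())

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        mu = np.exp(eta)
        score = Xm.T @ (y - mu)
        max_score = np.max(np.abs(score))
        trace.append(max_score)
        if max_score < tol:
            converged = True
            # Newton polish: keep iterating while the score still shrinks,
            # so group means are reproduced to machine precision
            if max_score < 1e-13 or (len(trace) > 1 and max_score >= trace[-2]):
                break
        A = (Xm * mu[:, None]).T @ Xm
        step = np.linalg.solve(A, score)
        # step-halving guard against overshoot of the log link
        for _ in range(30):
            cand = beta + step
            if np.max(Xm @ cand) < 500:  # keep exp() finite
                beta = cand
                break
            step = step / 2
        else:
            raise ModelError("step-halving failed; linear predictor diverged")
    if not converged:
        raise ModelError(
            f"IRLS did not converge in {max_iter} iterations; |score| trace tail: "
            + ", ".join(f"{v:.3g}" for v in trace[-5:])
        )

    mu = np.exp(Xm @ beta)
    A = (Xm * mu[:, None]).T @ Xm
    resid2 = (y - mu) ** 2
    B = (Xm * resid2[:, None]).T @ Xm
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    cov = (cov + cov.T) / 2.0
    return PrevalenceModelFit(
        terms=terms, beta=beta, robust_cov=cov, converged=converged, n_iter=it, n_obs=n
    )


# --- end-to-end pipeline ------------------------------------------------

def assemble_cohort_table(dataset: EmrDataset, thresholds=None):
    """Run cohort -> ACT -> GINA -> covariates; return (cohort frame, attrition).

    The cohort frame has one analysis-ready row per retained patient:
    index date, ACT score, control status, GINA step with rationale, and
    the adjustment-set covariates.
    """
    if thresholds is None:
        thresholds = load_dose_thresholds()
    indexed, attrition = build_cohort(dataset)
    imputed = impute_sig_fields(dataset.prescriptions)
    rx_by_patient: dict = {}
    for rx in imputed:
        rx_by_patient.setdefault(rx.patient_id, []).append(rx)

    covs = derive_covariates(indexed, dataset).set_index("patient_id") if indexed else None
    rows = []
    for ip in indexed:
        window_rxs = [
            rx
            for rx in rx_by_patient.get(ip.patient_id, [])
            if ip.window_start <= rx.date <= ip.window_end
        ]
        assignment = classify_patient(window_rxs, ip.index_date, thresholds)
        score = score_act(ip.index_act.items)
        status = classify_control(score)
        row = {
            "patient_id": ip.patient_id,
            "index_date": ip.index_date,
            "act_score": score,
            "control_status": status.status,
            "gina_step": assignment.step,
            "gina_rationale": "; ".join(assignment.rationale),
        }
        row.update(covs.loc[ip.patient_id].to_dict())
        rows.append(row)
    columns = [
        "patient_id",
        "index_date",
        "act_score",
        "control_status",
        "gina_step",
        "gina_rationale",
        "age_years",
        "sex",
        "race",
        "ethnicity",
        "smoking",
        "bmi_value",
        "bmi_category",
        "visit_type",
    ]
    cohort = pd.DataFrame(rows, columns=columns)
    return cohort, attrition


def run_analysis(dataset_dir, out_dir, covariates=DEFAULT_COVARIATES, thresholds_path=None) -> dict:
    """Full pipeline on a dataset directory; writes all analysis artifacts.

    Outputs under *out_dir*: cohort.csv, attrition.csv, table1.csv (by GINA
    step), table2.csv (by control status), prevalence_ratios.csv and
    run_log.json.  The model stage is skipped with a warning when the cohort
    is empty or the outcome degenerate.  Byte-identical across reruns on
    identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = read_dataset(dataset_dir)
    thresholds = load_dose_thresholds(thresholds_path)
    cohort, attrition = assemble_cohort_table(dataset, thresholds)

    cohort.to_csv(out_dir / "cohort.csv", index=False)
    attrition.to_frame().to_csv(out_dir / "attrition.csv", index=False)
    tables = tabulate(cohort)
    tables["by_step"].to_csv(out_dir / "table1.csv", index=False)
    tables["by_control"].to_csv(out_dir / "table2.csv", index=False)

    report = {
        "n_patients_input": len(dataset.patients),
        "n_cohort": len(cohort),
        "model_fitted": False,
    }
    fit = None
    if len(cohort) > 0 and cohort["control_status"].nunique() > 1:
        y, X = build_design(cohort, covariates)
        try:
            fit = fit_modified_poisson(y, X)
        except ModelError as exc:
            warnings.warn(f"model stage skipped: {exc}")
    else:
        warnings.warn("model stage skipped: empty cohort or constant outcome")
    if fit is not None:
        frame = fit.to_frame()
        frame.to_csv(out_dir / "prevalence_ratios.csv", index=False, float_format="%.10g")
        report.update(
            model_fitted=True,
            converged=fit.converged,
            n_iter=fit.n_iter,
            prevalence_ratios={
                t: round(float(v), 6) for t, v in zip(fit.terms, fit.pr)
            },
        )
    log = {
        "inputs_sha256": _dir_hash(dataset_dir),
        "covariates": list(covariates),
        **{k: v for k, v in report.items() if k != "prevalence_ratios"},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    report["fit"] = fit
    report["cohort"] = cohort
    report["attrition"] = attrition
    return report


def _dir_hash(directory) -> str:
    h = hashlib.sha256()
    for path in sorted(Path(directory).glob("*.csv")):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()


def forest_plot(fit: PrevalenceModelFit, path, terms=None):
    """Forest plot of prevalence ratios (step terms by default) to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if terms is None:
        terms = [t for t in fit.terms if t.startswith("step_")]
    rows = [fit[t] for t in terms]
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(terms) + 1.2))
    ypos = np.arange(len(terms))[::-1]
    for yv, r in zip(ypos, rows):
        ax.plot([r["ci_low"], r["ci_high"]], [yv, yv], color="0.3")
        ax.plot(r["pr"], yv, "s", color="tab:blue")
    ax.axvline(1.0, color="0.6", linestyle="--", linewidth=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels([t.replace("step_", "GINA Step ") for t in terms])
    ax.set_xscale("log")
    ax.set_xlabel("Prevalence ratio of not-well-controlled asthma (vs Step 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
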