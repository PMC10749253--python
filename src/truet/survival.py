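"""Threshold/majority-vote survival stratification and the Cox predictor.

Patients are labelled Low when at least two of their available marker
densities fall strictly below the per-marker cutoffs (the working defaults
are 500 / 300 / 700 cells/mm^2 for CD3 / CD4 / CD8; a density exactly equal
to its cutoff votes High). Cutoffs can instead be derived per marker by ROC
analysis against five-year mortality, maximising Youden's J. Group survival
is summarised by Kaplan-Meier curves and compared with the two-sample
log-rank test; the proof-of-concept predictor is a Cox proportional-hazards
model of the Low indicator plus age, stage, MSI and chemotherapy, reporting
each patient's five-year survival probability.

Kaplan-Meier, log-rank and Cox fitting are delegated to lifelines (Efron
tie handling, Breslow baseline); this module owns the thresholding, voting
and endpoint construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .types import StratificationResult

__all__ = [
    "ThresholdSet",
    "DEFAULT_THRESHOLDS",
    "roc_threshold",
    "derive_thresholds",
    "truet_status",
    "km_curve",
    "logrank_test",
    "stratify",
    "fit_cox",
    "predict_survival_5yr",
]

DEFAULT_THRESHOLDS = {"cd3": 500.0, "cd4": 300.0, "cd8": 700.0}
FIVE_YEARS = 5.0


@dataclass
class ThresholdSet:
    cd3: float = 500.0
    cd4: float = 300.0
    cd8: float = 700.0
    derivation: str = "fixed"

    def __post_init__(self):
        if min(self.cd3, self.cd4, self.cd8) < 0:
            raise ValueError("cutoffs must be >= 0")

    def as_dict(self):
        return {"cd3": self.cd3, "cd4": self.cd4, "cd8": self.cd8}


def five_year_outcome(time, event, horizon: float = FIVE_YEARS):
    """Binary death-within-horizon endpoint.

    Returns (outcome, usable): patients censored alive before the horizon
    carry no five-year label and are flagged unusable.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    died_by = (event == 1) & (time <= horizon)
    alive_at = time >= horizon
    usable = died_by | alive_at
    return died_by.astype(int), usable


def roc_threshold(densities, outcomes_5yr) -> float:
    """Density cutoff maximising Youden's J for predicting 5-year death.

    Low density predicts death: at cutoff c the positive (death) call is
    density < c. Candidate cutoffs are the observed densities; among ties
    the lowest cutoff is returned.
    """
    d = np.asarray(densities, dtype=float)
    y = np.asarray(outcomes_5yr, dtype=int)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("densities and outcomes must be 1-D and aligned")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("both outcome classes must be present")
    best_j, best_c = -np.inf, None
    for c in np.unique(d):
        call = d < c
        sens = np.sum(call & (y == 1)) / n_pos
        spec = np.sum(~call & (y == 0)) / (y.size - n_pos)
        j = sens + spec - 1.0
        if j > best_j:           # unique() is ascending: first max = lowest c
            best_j, best_c = j, float(c)
    return best_c


def derive_thresholds(cohort: pd.DataFrame, horizon: float = FIVE_YEARS
                      ) -> ThresholdSet:
    """Per-marker ROC cutoffs from a cohort table with time/event columns."""
    y, usable = five_year_outcome(cohort["time"], cohort["event"], horizon)
    cuts = {}
    for m in ("cd3", "cd4", "cd8"):
        col = cohort[f"{m}_density"].to_numpy(dtype=float)
        ok = usable & ~np.isnan(col)
        cuts[m] = roc_threshold(col[ok], y[ok])
    return ThresholdSet(**cuts, derivation="roc")


def truet_status(record, thresholds=None, markers=("cd3", "cd4", "cd8")) -> str:
    """Majority vote over available markers: "Low" when at least half vote low.

    With the standard three markers this is the >= 2-below rule; in the
    two-marker CD3+CD8 mode Low requires both below. Density exactly equal
    to the cutoff is not below. Fewer than two available markers ->
    ValueError (status undetermined).
    """
    thr = (thresholds.as_dict() if isinstance(thresholds, ThresholdSet)
           else dict(thresholds or DEFAULT_THRESHOLDS))
    votes = []
    for m in markers:
        value = record.get(f"{m}_density", record.get(m, np.nan))
        value = np.nan if value is None else float(value)
        if not np.isnan(value):
            votes.append(value < thr[m])
    if len(votes) < 2:
        raise ValueError("fewer than 2 marker densities available")
    return "Low" if sum(votes) >= 2 else "High"


def km_curve(times, events):
    """Kaplan-Meier product-limit curve as (times, survival) step arrays.

    The returned arrays start at (0, 1); survival drops only at event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(group1, group2):
    """Two-group log-rank chi-square (1 df) and its p-value.

    Each group is a (times, events) pair. Returns (statistic, p); with no
    events in either group the statistic is undefined -> (nan, nan).
    """
    t1, e1 = (np.asarray(a) for a in group1)
    t2, e2 = (np.asarray(a) for a in group2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        return float("nan"), float("nan")
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def stratify(cohort: pd.DataFrame, thresholds=None,
             markers=("cd3", "cd4", "cd8")) -> StratificationResult:
    """Label every patient High/Low, estimate per-group KM, run log-rank."""
    thr = thresholds if thresholds is not None else ThresholdSet()
    status, undetermined = {}, 0
    for _, row in cohort.iterrows():
        try:
            status[row["patient_id"]] = truet_status(row, thr, markers)
        except ValueError:
            undetermined += 1
    status = pd.Series(status, name="truet_status")
    labelled = cohort[cohort["patient_id"].isin(status.index)].copy()
    labelled["truet_status"] = status.loc[labelled["patient_id"]].to_numpy()

    flags = []
    curves, sizes = {}, {}
    groups = {}
    for name, sub in labelled.groupby("truet_status"):
        curves[name] = km_curve(sub["time"], sub["event"])
        sizes[name] = len(sub)
        groups[name] = (sub["time"].to_numpy(), sub["event"].to_numpy())
    stat = p = None
    if len(groups) == 2:
        stat, p = logrank_test(groups["High"], groups["Low"])
        if np.isnan(stat):
            flags.append("no events in either group; log-rank undefined")
            stat = p = None
    else:
        flags.append("single status group; log-rank test skipped")
    if undetermined:
        flags.append(f"{undetermined} patients undetermined (<2 markers)")
    thr_dict = thr.as_dict() if isinstance(thr, ThresholdSet) else dict(thr)
    return StratificationResult(
        thresholds=thr_dict, status=status, group_sizes=sizes,
        km_curves=curves, logrank_statistic=stat, logrank_p=p,
        n_undetermined=undetermined, flags=flags,
    )


def _design_matrix(cohort: pd.DataFrame, status: pd.Series | None):
    df = cohort.copy()
    if status is not None:
        df = df[df["patient_id"].isin(status.index)].copy()
        df["truet_low"] = (status.loc[df["patient_id"]] == "Low").astype(int).to_numpy()
    cols = {"time": df["time"].astype(float), "event": df["event"].astype(int)}
    if "truet_low" in df:
        cols["truet_low"] = df["truet_low"]
    if "age" in df:
        cols["age"] = df["age"].astype(float)
    if "stage" in df:
        stage = df["stage"].astype(str)
        cols["stage_III"] = (stage == "III").astype(int)
        cols["stage_IV"] = (stage == "IV").astype(int)
    for c in ("msi", "chemo"):
        if c in df:
            cols[c] = df[c].astype(int)
    return pd.DataFrame(cols, index=df.index)


def fit_cox(cohort: pd.DataFrame, thresholds=None, status: pd.Series | None = None,
            covariates: list | None = None) -> CoxPHFitter:
    """Cox proportional-hazards fit of True-T status plus clinical covariates.

    ``status`` defaults to majority-vote labels under ``thresholds``. Ties
    are handled by Efron's method and the baseline cumulative hazard by the
    Breslow estimator (lifelines defaults). Constant covariates are dropped
    with a warning recorded on the returned fitter as ``dropped_covariates``.
    """
    if status is None:
        status = stratify(cohort, thresholds).status
    df = _design_matrix(cohort, status)
    if df["event"].sum() == 0:
        raise ValueError("no events in cohort; Cox model unidentifiable")
    if covariates is not None:
        df = df[["time", "event"] + list(covariates)]
    dropped = [c for c in df.columns.drop(["time", "event"])
               if df[c].nunique() <= 1]
    df = df.drop(columns=dropped)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    cph.dropped_covariates = dropped
    return cph


def predict_survival_5yr(model: CoxPHFitter, patient_covariates,
                         horizon: float = FIVE_YEARS):
    """S(horizon | x) = S0(horizon)^exp(beta'x) plus the full step curve.

    Returns (probability, times, survival). When the horizon exceeds the
    last observed time the last value is carried forward and
    ``extrapolated=True`` is signalled via the third flag element.
    """
    x = (pd.DataFrame([patient_covariates]) if isinstance(
        patient_covariates, dict) else pd.DataFrame(patient_covariates))
    beta = model.params_
    xvec = x.iloc[0].reindex(beta.index).astype(float)
    if xvec.isna().any():
        raise ValueError(f"missing covariates: "
                         f"{list(xvec.index[xvec.isna()])}")
    # lifelines centres covariates at the training mean; rescale its
    # baseline cumulative hazard to the at-zero baseline H0(t)
    mean = pd.Series(model._norm_mean).reindex(beta.index).astype(float)
    h0 = model.baseline_cumulative_hazard_.iloc[:, 0] * float(
        np.exp(-(beta @ mean)))
    times = h0.index.to_numpy(dtype=float)
    surv = np.exp(-h0.to_numpy(dtype=float) * np.exp(float(beta @ xvec)))
    extrapolated = horizon > times.max()
    idx = np.searchsorted(times, horizon, side="right") - 1
    prob = float(surv[max(idx, 0)]) if idx >= 0 else 1.0
    return prob, (times, surv), extrapolated
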