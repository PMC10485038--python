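"""Head-to-head diagnostic and survival comparison of classifications.

A classification system (fused-cluster membership, or the clinical
SGA/FGR rule) flags patients as high risk; against each binary outcome
this yields a 2x2 contingency table and the usual diagnostic summary
(sensitivity, specificity, predictive values, likelihood ratios and the
diagnostic odds ratio DOR = LR+/LR-), with Wilson intervals for
proportions and log-scale Wald intervals for the ratios. Systems are
compared by bootstrap CIs of paired LR+/DOR differences and by the
DeLong test on correlated ROC curves. Time-to-delivery is analysed by
Kaplan-Meier curves with the log-rank test and Cox proportional-hazards
regression (proportionality checked against log(time)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .datatypes import ContingencyTable


class Estimate(NamedTuple):
    """Point estimate with a two-sided confidence interval (NaN = NA)."""

    value: float
    lo: float
    hi: float


@dataclass
class DiagnosticSummary:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    lr_positive: Estimate
    lr_negative: Estimate
    dor: Estimate

    def as_dict(self) -> dict[str, Estimate]:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "lr_positive": self.lr_positive,
            "lr_negative": self.lr_negative, "dor": self.dor,
        }


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.dtype == bool:
        arr = arr.astype(int)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1, got values {vals}")
    return arr.astype(int)


def contingency(highrisk_flags, outcome_flags) -> ContingencyTable:
    """Four-way tally of a high-risk flag against a binary outcome."""
    h = _as_binary(highrisk_flags, "highrisk_flags")
    y = _as_binary(outcome_flags, "outcome_flags")
    if h.shape != y.shape:
        raise ValueError("flag vectors must have equal length")
    return ContingencyTable(
        tp=int(((h == 1) & (y == 1)).sum()),
        fp=int(((h == 1) & (y == 0)).sum()),
        tn=int(((h == 0) & (y == 0)).sum()),
        fn=int(((h == 0) & (y == 1)).sum()),
    )


def _wilson(count: int, nobs: int, alpha: float) -> Estimate:
    if nobs == 0:
        return Estimate(np.nan, np.nan, np.nan)
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return Estimate(count / nobs, float(lo), float(hi))


def _lr_ci(value: float, se2: float, alpha: float) -> Estimate:
    """Log-scale Wald CI for a likelihood/odds ratio.

    A ratio of exactly 0 gets the one-sided interval (0, NA); an
    undefined (NaN/inf) ratio is reported NA throughout.
    """
    if not np.isfinite(value):
        return Estimate(np.nan, np.nan, np.nan)
    if value == 0:
        return Estimate(0.0, 0.0, np.nan)
    if not np.isfinite(se2):
        return Estimate(value, np.nan, np.nan)
    z = norm.ppf(1 - alpha / 2)
    se = np.sqrt(se2)
    return Estimate(value, float(value * np.exp(-z * se)),
                    float(value * np.exp(z * se)))


def diagnostic_stats(ct: ContingencyTable, alpha: float = 0.05,
                     haldane: bool = False) -> DiagnosticSummary:
    """Diagnostic summary of a 2x2 table.

    Proportion CIs are Wilson; ratio CIs are log-scale Wald with the
    Simel variance for the likelihood ratios. Statistics with a zero
    denominator are NA (NaN); ``haldane`` instead applies the +0.5
    continuity correction to every cell before computing the ratios.
    """
    tp, fp, tn, fn = float(ct.tp), float(ct.fp), float(ct.tn), float(ct.fn)
    if haldane:
        tp, fp, tn, fn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)

    lr_pos = lr_neg = dor = np.nan
    se2_pos = se2_neg = se2_dor = np.nan
    if np.isfinite(sens) and np.isfinite(spec):
        lr_pos = ratio(sens, 1 - spec)  # NaN when spec == 1
        lr_neg = ratio(1 - sens, spec)  # NaN when spec == 0
        if tp > 0 and fp > 0:
            se2_pos = 1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn)
        if fn > 0 and tn > 0:
            se2_neg = 1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (tn + fp)
        if fp > 0 and fn > 0:
            dor = (tp * tn) / (fp * fn)
            if tp > 0 and tn > 0:
                se2_dor = 1 / tp + 1 / fp + 1 / tn + 1 / fn

    return DiagnosticSummary(
        sensitivity=_wilson(ct.tp, ct.tp + ct.fn, alpha),
        specificity=_wilson(ct.tn, ct.tn + ct.fp, alpha),
        ppv=_wilson(ct.tp, ct.tp + ct.fp, alpha),
        npv=_wilson(ct.tn, ct.tn + ct.fn, alpha),
        lr_positive=_lr_ci(lr_pos, se2_pos, alpha),
        lr_negative=_lr_ci(lr_neg, se2_neg, alpha),
        dor=_lr_ci(dor, se2_dor, alpha),
    )


@dataclass
class BootstrapComparison:
    """Percentile CIs of paired diagnostic differences (system A - B)."""

    lr_positive_diff: Estimate
    dor_diff: Estimate
    n_used: int
    n_skipped: int


def bootstrap_compare(flags_a, flags_b, outcomes, B: int = 2000,
                      seed: int = 0, alpha: float = 0.05
                      ) -> BootstrapComparison:
    """Compare two classification systems by bootstrapped LR+/DOR differences.

    Patients are resampled with replacement B times; each replicate's
    paired difference in LR+ and DOR (computed with the Haldane +0.5
    correction so that replicates with a zero cell stay finite) feeds a
    percentile CI. Resamples that lose an outcome class are skipped and
    counted. Point estimates come from the full sample, uncorrected.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    a = _as_binary(flags_a, "flags_a")
    b = _as_binary(flags_b, "flags_b")
    y = _as_binary(outcomes, "outcomes")
    if not (a.shape == b.shape == y.shape):
        raise ValueError("flag and outcome vectors must align")

    def _pair(aa, bb, yy, haldane):
        sa = diagnostic_stats(contingency(aa, yy), haldane=haldane)
        sb = diagnostic_stats(contingency(bb, yy), haldane=haldane)
        return (sa.lr_positive.value - sb.lr_positive.value,
                sa.dor.value - sb.dor.value)

    point_lr, point_dor = _pair(a, b, y, haldane=False)
    rng = np.random.default_rng(seed)
    n = y.size
    lr_diffs, dor_diffs = [], []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        if y[idx].min() == y[idx].max():
            skipped += 1
            continue
        dlr, ddor = _pair(a[idx], b[idx], y[idx], haldane=True)
        lr_diffs.append(dlr)
        dor_diffs.append(ddor)
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    lr_lo, lr_hi = np.percentile(lr_diffs, qs)
    dor_lo, dor_hi = np.percentile(dor_diffs, qs)
    return BootstrapComparison(
        lr_positive_diff=Estimate(point_lr, float(lr_lo), float(lr_hi)),
        dor_diff=Estimate(point_dor, float(dor_lo), float(dor_hi)),
        n_used=len(lr_diffs), n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# DeLong comparison of correlated ROC curves

def _placement_values(scores: np.ndarray, y: np.ndarray
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values (midrank construction)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    r_all = rankdata(allv)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n          # per-positive placements
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # per-negative placements
    auc = v10.mean()
    return float(auc), v10, v01


def roc_delong(scores_a, scores_b, outcomes) -> dict:
    """DeLong test for two correlated ROC curves on the same patients.

    Returns AUCs, the covariance matrix of the AUC estimates, the z
    statistic and the two-sided p value (normal approximation). Two
    identical score vectors give difference 0 and p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _as_binary(outcomes, "outcomes")
    if not (sa.shape == sb.shape == y.shape):
        raise ValueError("scores and outcomes must align")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both outcome classes must be present")
    auc_a, v10_a, v01_a = _placement_values(sa, y)
    auc_b, v10_b, v01_b = _placement_values(sb, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            z, p = 0.0, 1.0
        else:
            raise ValueError("degenerate DeLong variance with unequal AUCs")
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "cov": cov, "diff": diff,
            "z": float(z), "p": p}


# ---------------------------------------------------------------------------
# survival: Kaplan-Meier / log-rank / Cox

@dataclass
class SurvivalComparison:
    curves: dict
    logrank_statistic: float
    logrank_p: float


def km_logrank(time, event, group) -> SurvivalComparison:
    """Kaplan-Meier curves per group and the log-rank test."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    if not (t.shape == e.shape == g.shape):
        raise ValueError("time, event and group must align")
    if (t <= 0).any():
        raise ValueError("times must be strictly positive")
    if e.sum() == 0:
        raise ValueError("log-rank is undefined with no events")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    curves = {}
    for lab in labels:
        sel = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(lab))
        curves[lab] = kmf.survival_function_
    res = multivariate_logrank_test(t, g, e)
    return SurvivalComparison(curves, float(res.test_statistic),
                              float(res.p_value))


@dataclass
class CoxResult:
    hazard_ratio: float
    ci: tuple[float, float]
    coef: float
    p: float
    ph_test_p: float


def cox_hr(time, event, group, covariates: Optional[pd.DataFrame] = None,
           ph_check: bool = True) -> CoxResult:
    """Cox proportional-hazards HR of the (binary) group indicator.

    Optionally adjusted for a covariate frame. The proportionality of
    the group effect is checked against log(time) via the Schoenfeld-
    residual score test. Monotone-likelihood failures raise with a
    diagnostic rather than returning a divergent estimate.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = _as_binary(group, "group")
    for lab in (0, 1):
        if e[g == lab].sum() < 2:
            raise ValueError(f"group {lab} has fewer than 2 events")
    df = pd.DataFrame({"time": t, "event": e, "group": g})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        df = pd.concat([df, cov], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ValueError(
            "Cox fit failed to converge (possibly monotone likelihood: all "
            f"events ordered by group): {err}") from err
    row = cph.summary.loc["group"]
    ph_p = np.nan
    if ph_check:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = proportional_hazard_test(cph, df, time_transform="log")
        ph_p = float(np.atleast_1d(ph.p_value)[
            list(ph.summary.index.get_level_values(0)).index("group")])
    return CoxResult(
        hazard_ratio=float(row["exp(coef)"]),
        ci=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        coef=float(row["coef"]),
        p=float(row["p"]),
        ph_test_p=ph_p,
    )


# ---------------------------------------------------------------------------
# clinical SGA/FGR rule on the synthetic feature panel

#: feature -> (direction, cutoff); "ge" flags values >= cutoff, "le" <= cutoff
DEFAULT_CLINICAL_CUTOFFS = {
    "efw_centile": ("le", 3.0),   # EFW below the 3rd centile
    "ua_pi_z": ("ge", 2.0),       # abnormal umbilical artery Doppler
    "uta_pi_z": ("ge", 2.0),      # abnormal uterine artery Doppler
    "cpr_z": ("le", -2.0),        # abnormal cerebroplacental ratio
}


def clinical_classification(ultrasound_values: pd.DataFrame,
                            cutoffs: Optional[dict] = None) -> np.ndarray:
    """Binary FGR flag from the clinical rule: EFW < 3rd centile and/or
    any abnormal fetoplacental Doppler; everything else is mild SGA."""
    cutoffs = DEFAULT_CLINICAL_CUTOFFS if cutoffs is None else cutoffs
    flag = np.zeros(len(ultrasound_values), dtype=bool)
    used = 0
    for feat, (direction, cut) in cutoffs.items():
        if feat not in ultrasound_values.columns:
            continue
        used += 1
        x = ultrasound_values[feat].to_numpy(dtype=float)
        flag |= (x >= cut) if direction == "ge" else (x <= cut)
    if used == 0:
        raise ValueError("no cutoff feature found in the ultrasound table")
    return flag.astype(int)
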