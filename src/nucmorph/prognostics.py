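"""Outcome statistics: ROC/AUC, sensitivity-anchored dichotomization,
univariate Cox regression, Kaplan–Meier / log-rank, and inter-rater kappa.

The clinical question is whether a morphometric parameter (e.g. the SD of
the nuclear area, a proxy for anisokaryosis) predicts tumor-specific
mortality within a fixed follow-up horizon (250 days by default).  Cases
are prepared by the horizon rules, scored per case, evaluated by AUC, and
dichotomized at the threshold that reaches a target sensitivity (70 %,
i.e. a fixed fraction of the tumor-death cases classified correctly) with
the highest attainable specificity, so specificities are comparable across
tests.  Survival contrasts use the Cox proportional-hazards model (Efron
tie handling) and Kaplan–Meier curves with the log-rank test.  Agreement
among raters is summarized by Light's kappa — the mean of all pairwise
unweighted Cohen kappas — with the conventional verbal interpretation
bins.

Score orientation: larger values are taken as worse prognosis (positive
call at score ≥ threshold); an orientation flag flips this per test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

EVENT_CATEGORIES = ("tumor-death", "other-death", "lost", "alive")


# --------------------------------------------------------------------------
# cohort preparation
# --------------------------------------------------------------------------

def prepare_cohort(records: pd.DataFrame, horizon_days: float = 250.0) -> pd.DataFrame:
    """Apply the fixed-horizon survival rules to raw outcome records.

    Input columns: ``case_id``, ``time_days`` (> 0), ``status`` (one of
    ``tumor-death | other-death | lost | alive``) plus any score columns,
    which pass through untouched.  Rules within the horizon: tumor death →
    event at its time; tumor-unrelated death → censored at its time; lost
    to follow-up → excluded.  Everyone still under observation at the
    horizon is censored there.  The output adds

    * ``time`` / ``event`` — the horizon-limited survival pair, and
    * ``label250`` — the binary endpoint for ROC: 1 = tumor death within
      the horizon, 0 = survived the horizon, NaN = not in the binary set
      (tumor-unrelated death within the horizon).
    """
    df = records.copy()
    if (df["time_days"] <= 0).any():
        raise ValueError("all follow-up times must be positive")
    bad = set(df["status"]) - set(EVENT_CATEGORIES)
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")

    h = float(horizon_days)
    before = df["time_days"] < h
    lost = before & (df["status"] == "lost")
    alive_short = before & (df["status"] == "alive")
    if alive_short.any():
        warnings.warn(
            f"{int(alive_short.sum())} cases last seen alive before the horizon; "
            "treated as lost to follow-up (excluded)",
            stacklevel=2,
        )
    df = df[~(lost | alive_short)].copy()

    tumor_death = (df["status"] == "tumor-death") & (df["time_days"] <= h)
    other_death = (df["status"] == "other-death") & (df["time_days"] < h)

    df["event"] = tumor_death.astype(int)
    df["time"] = np.where(tumor_death | other_death, df["time_days"], h)
    df["label250"] = np.where(
        tumor_death, 1.0, np.where(other_death, np.nan, 0.0)
    )
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    # tie-corrected rank-sum probability P(X+ > X-) + 0.5 P(=)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    # structural components: V10 over positives, V01 over negatives
    v10 = np.array([
        np.mean((x > neg) + 0.5 * (x == neg)) for x in pos
    ])
    v01 = np.array([
        np.mean((pos > y) + 0.5 * (pos == y)) for y in neg
    ])
    s10 = np.var(v10, ddof=1) if len(pos) > 1 else 0.0
    s01 = np.var(v01, ddof=1) if len(neg) > 1 else 0.0
    return s10 / len(pos) + s01 / len(neg)


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    ci_method: str = "delong",
    higher_is_worse: bool = True,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> AucResult:
    """AUC (tie-corrected rank probability) with a 95 % CI.

    ``ci_method``: "delong" (asymptotic rank-based variance, the default)
    or "bootstrap" (stratified percentile bootstrap, preferable for very
    small samples).  A degenerate DeLong variance of zero falls back to
    the bootstrap automatically.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    mask = ~np.isnan(s) & ~pd.isna(y).astype(bool)
    s, y = s[mask], y[mask].astype(int)
    if not higher_is_worse:
        s = -s
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")

    auc = _auc_mann_whitney(pos, neg)
    z = stats.norm.ppf(1 - alpha / 2)

    if ci_method == "delong":
        var = _delong_variance(pos, neg, auc)
        if var > 0:
            half = z * np.sqrt(var)
            return AucResult(auc, max(0.0, auc - half), min(1.0, auc + half),
                             len(pos), len(neg), "delong")
        logger.info("DeLong variance degenerate; using stratified bootstrap CI")
        ci_method = "bootstrap"

    if ci_method != "bootstrap":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        boots[b] = _auc_mann_whitney(bp, bn)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return AucResult(auc, float(lo), float(hi), len(pos), len(neg), "bootstrap")


# --------------------------------------------------------------------------
# threshold selection / confusion arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def _confusion_at(scores: np.ndarray, labels: np.ndarray, thr: float) -> ConfusionSummary:
    call = scores >= thr
    tp = int(np.sum(call & (labels == 1)))
    fp = int(np.sum(call & (labels == 0)))
    tn = int(np.sum(~call & (labels == 0)))
    fn = int(np.sum(~call & (labels == 1)))
    return ConfusionSummary(thr, tp, fp, tn, fn)


def select_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    target_sensitivity: float = 0.70,
    higher_is_worse: bool = True,
) -> ConfusionSummary:
    """Sensitivity-anchored dichotomization.

    Candidate thresholds are the midpoints between adjacent distinct
    scores plus ±∞; a case is called positive at score ≥ threshold.
    Among candidates achieving sensitivity ≥ the target, those with the
    *minimal* such sensitivity are kept (the anchor: just enough
    tumor-death cases correctly classified), and of these the one with
    the highest specificity wins; remaining ties go to the larger
    threshold.  A target ≤ 1 is always reachable (the −∞ threshold calls
    everyone positive).
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    mask = ~np.isnan(s) & ~pd.isna(y).astype(bool)
    s, y = s[mask], y[mask].astype(int)
    if not higher_is_worse:
        s = -s
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")

    uniq = np.unique(s)
    candidates = [-np.inf, np.inf]
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)

    best: ConfusionSummary | None = None
    for thr in candidates:
        c = _confusion_at(s, y, thr)
        if c.sensitivity < target_sensitivity:
            continue
        if best is None:
            best = c
            continue
        key_new = (c.sensitivity, -c.specificity, -c.threshold)
        key_old = (best.sensitivity, -best.specificity, -best.threshold)
        if key_new < key_old:
            best = c
    if best is None:  # unreachable for target ≤ 1: -inf calls everyone positive
        raise RuntimeError("no threshold attains the target sensitivity")
    return best


def precision_from_rates(sen: float, sp: float, n_pos: int, n_neg: int) -> float:
    """Reconstruct precision from printed Sen/Sp values and class sizes.

    Published sensitivity/specificity percentages are rounded from integer
    confusion cells, so TP = round(sen·n_pos) and FP = round((1−sp)·n_neg)
    must land within 0.51 of an integer; the precision TP/(TP+FP) is then
    exact.
    """
    tp_f, fp_f = sen * n_pos, (1.0 - sp) * n_neg
    tp, fp = round(tp_f), round(fp_f)
    if abs(tp_f - tp) > 0.51 or abs(fp_f - fp) > 0.51:
        raise ValueError("rates are inconsistent with integer confusion cells")
    if tp + fp == 0:
        raise ValueError("no positive calls: precision undefined")
    return tp / (tp + fp)


# --------------------------------------------------------------------------
# survival models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    se: float
    p_value: float
    n: int
    n_events: int
    estimable: bool = True


def cox_univariate(
    covariate: np.ndarray, times: np.ndarray, events: np.ndarray
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Returns the hazard ratio exp(β̂) with its Wald 95 % CI.  A monotone
    partial likelihood (complete separation) is reported as non-estimable
    rather than raising.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    df = pd.DataFrame({"x": x, "time": t, "event": e})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
    except Exception as exc:
        logger.warning("Cox fit failed: %s", exc)
        coef, se = float("nan"), float("nan")

    # a monotone partial likelihood (complete separation) drives the
    # coefficient and its standard error off to infinity
    if not (np.isfinite(coef) and np.isfinite(se)) or se > 50 or abs(coef) > 20:
        logger.warning("Cox fit non-estimable (monotone likelihood or failure)")
        return CoxResult(float("nan"), float("nan"), float("nan"),
                         coef, se, float("nan"),
                         len(df), int(e.sum()), estimable=False)
    z = stats.norm.ppf(0.975)
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        coef=coef,
        se=se,
        p_value=float(cph.summary.loc["x", "p"]),
        n=len(df),
        n_events=int(e.sum()),
    )


def kaplan_meier(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> pd.DataFrame:
    """Product-limit survival curves per group.

    Returns a long table (group, time, survival, n_at_risk); censored
    subjects leave the risk set without a drop in the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    frames = []
    for grp in pd.unique(g):
        sel = g == grp
        if sel.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        surv = kmf.survival_function_.reset_index()
        surv.columns = ["time", "survival"]
        at_risk = [int((t[sel] >= tt).sum()) for tt in surv["time"]]
        surv.insert(0, "group", grp)
        surv["n_at_risk"] = at_risk
        frames.append(surv)
    return pd.concat(frames, ignore_index=True)


def log_rank(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Log-rank test across groups (chi-square, k−1 df). Returns (statistic, p)."""
    g = np.asarray(groups)
    if len(pd.unique(g)) < 2:
        raise ValueError("log-rank needs at least two groups")
    res = multivariate_logrank_test(np.asarray(times, dtype=float),
                                    g, np.asarray(events, dtype=int))
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------------------
# inter-rater agreement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    lights_kappa: float
    pairwise: dict[tuple[str, str], float]
    interpretation: str


def cohens_kappa(ratings_a: np.ndarray, ratings_b: np.ndarray) -> float:
    """Unweighted Cohen's kappa: (p_o − p_e) / (1 − p_e).

    Chance agreement p_e comes from the raters' marginal category
    frequencies.  When both raters are constant (p_e = 1): kappa is 1 if
    they agree everywhere, otherwise undefined (raises).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("rating vectors must be equal-length and non-empty")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("degenerate marginals: kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def lights_kappa(panel: pd.DataFrame) -> AgreementResult:
    """Light's kappa: the mean of all pairwise unweighted Cohen kappas.

    ``panel`` holds one column per rater (any non-rater ``case_id`` column
    is ignored), one row per case.
    """
    raters = [c for c in panel.columns if c != "case_id"]
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    pairwise = {}
    for ra, rb in itertools.combinations(raters, 2):
        pairwise[(ra, rb)] = cohens_kappa(panel[ra].to_numpy(), panel[rb].to_numpy())
    k = float(np.mean(list(pairwise.values())))
    return AgreementResult(k, pairwise, interpret_kappa(k))


def interpret_kappa(k: float) -> str:
    """Verbal agreement bins (applied after rounding to 2 decimals):
    ≤0 poor, 0.01–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate,
    0.61–0.80 substantial, 0.81–1.00 almost perfect."""
    if not -1.0 <= k <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    kr = round(k, 2)
    if kr <= 0.0:
        return "poor"
    if kr <= 0.20:
        return "slight"
    if kr <= 0.40:
        return "fair"
    if kr <= 0.60:
        return "moderate"
    if kr <= 0.80:
        return "substantial"
    return "almost perfect"
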