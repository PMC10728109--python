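"""Panel evaluation: logistic-regression ROC metrics, PCA score plots, and
multivariate Cox risk scores with a Kaplan-Meier log-rank comparison.

AUC is computed by the rank (Mann-Whitney) formulation with half credit for
ties; its standard error uses the Hanley-McNeil formula and the 95% CI is
the normal approximation auc +/- 1.96 SE clipped to [0, 1].  The "best"
cutoff maximises Youden's J (sensitivity + specificity - 1), ties broken
toward higher sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ROCReport",
    "SurvivalReport",
    "rank_auc",
    "hanley_mcneil_se",
    "roc_curve_points",
    "panel_roc",
    "panel_pca",
    "cox_km",
    "km_estimate",
]


@dataclass
class ROCReport:
    auc: float
    se: float
    ci95: tuple[float, float]
    best_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    n_pos: int
    n_neg: int
    scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci95": list(self.ci95),
            "best_cutoff": self.best_cutoff,
            "sensitivity": self.sensitivity_at_cutoff,
            "specificity": self.specificity_at_cutoff,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class SurvivalReport:
    coefficients: dict[str, float]
    risk_scores: np.ndarray
    threshold: float
    group_of: np.ndarray  # "high"/"low" per sample
    logrank_p: float | None
    logrank_statistic: float | None
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "threshold": self.threshold,
            "n_high": int(np.sum(self.group_of == "high")),
            "n_low": int(np.sum(self.group_of == "low")),
            "logrank_p": self.logrank_p,
            "logrank_statistic": self.logrank_statistic,
        }


# ----------------------------------------------------------------------
def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation, ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Sensitivity/specificity at every candidate cutoff (score >= cutoff
    calls positive); cutoffs are the unique scores plus a +inf endpoint."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    cutoffs = np.concatenate([np.unique(scores), [np.inf]])
    rows = []
    for c in cutoffs:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        rows.append({"cutoff": c, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def _logistic_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unpenalised logistic-regression linear predictor; on perfect
    separation (non-converging ML fit) fall back to the OLS linear
    combination, which preserves the rank-based AUC."""
    import warnings

    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is handled below; the warning is expected there
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = fit.params
        if not np.all(np.isfinite(params)):
            raise np.linalg.LinAlgError
        if getattr(fit, "mle_retvals", {}).get("converged", True) is False and X.shape[1] >= 1:
            # likely separation; linear predictor still usable if finite
            pass
        return np.asarray(Xc @ params, dtype=float)
    except Exception:
        logger.warning("logistic fit failed (perfect separation?); using unpenalised linear combination")
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        return np.asarray(Xc @ beta, dtype=float)


def panel_roc(panel_values: np.ndarray, labels: np.ndarray) -> ROCReport:
    """Binary logistic model on the panel (samples x ratios), ROC on its
    fitted scores.

    Returns AUC (rank formulation), Hanley-McNeil SE, normal 95% CI, and the
    Youden-optimal cutoff with its sensitivity and specificity.
    """
    X = np.asarray(panel_values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 3 or n_neg < 3:
        raise ValueError("need at least 3 samples per label")
    scores = _logistic_scores(X, y)
    auc = rank_auc(scores, y)
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    lo, hi = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)
    pts = roc_curve_points(scores, y)
    j = pts["sensitivity"] + pts["specificity"] - 1.0
    # maximise J; ties toward higher sensitivity
    order = np.lexsort((pts["sensitivity"].to_numpy(), j.to_numpy()))
    best = pts.iloc[order[-1]]
    return ROCReport(
        auc=auc,
        se=se,
        ci95=(lo, hi),
        best_cutoff=float(best["cutoff"]),
        sensitivity_at_cutoff=float(best["sensitivity"]),
        specificity_at_cutoff=float(best["specificity"]),
        n_pos=n_pos,
        n_neg=n_neg,
        scores=scores,
    )


# ----------------------------------------------------------------------
def panel_pca(panel_values: np.ndarray, n_components: int = 2, scale: bool = True):
    """PCA score plot input: columns autoscaled (centred, unit variance) by
    default, zero-variance columns dropped with a warning.

    Returns (scores, explained_variance_ratio).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(panel_values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 ratios")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        logger.warning("dropping %d zero-variance ratio column(s) before PCA", int(np.sum(sd == 0)))
        X = X[:, sd > 0]
        sd = sd[sd > 0]
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant ratios for PCA")
    Xs = X - X.mean(axis=0)
    if scale:
        Xs = Xs / sd
    n_components = min(n_components, Xs.shape[1], Xs.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    return scores, pca.explained_variance_ratio_


# ----------------------------------------------------------------------
def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier survival curve as a step-function table (time, survival)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def cox_km(
    panel_values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ratio_names: list[str] | None = None,
) -> SurvivalReport:
    """Multivariate Cox fit on the panel; risk score = linear predictor;
    median split into high/low groups; two-group log-rank test.

    Uses Breslow tie handling (the survival-ecosystem default).  With no
    events in a group the log-rank test is reported as undefined (None).
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    X = np.asarray(panel_values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    n = X.shape[0]
    if n < 10:
        raise ValueError("Cox evaluation needs at least 10 samples")
    if events.sum() < 3:
        raise ValueError("Cox evaluation needs at least 3 events")
    if ratio_names is None:
        ratio_names = [f"r{i}" for i in range(X.shape[1])]

    df = pd.DataFrame(X, columns=ratio_names)
    df["time"], df["event"] = times, events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coefs = cph.params_.to_dict()
    risk = X @ cph.params_.to_numpy()

    threshold = float(np.median(risk))
    # median split by rank: lower half low, upper half high; ties at the
    # threshold resolved by sample order so group sizes differ by <= 1
    order = np.argsort(risk, kind="stable")
    group = np.empty(n, dtype=object)
    half = n // 2
    group[order[:half + (n % 2)]] = "low"
    group[order[half + (n % 2):]] = "high"

    high, low = group == "high", group == "low"
    if events[high].sum() == 0 or events[low].sum() == 0:
        logger.warning("no events in one risk group; log-rank undefined")
        p = stat = None
    else:
        res = logrank_test(times[high], times[low], events[high], events[low])
        p, stat = float(res.p_value), float(res.test_statistic)

    curves = {
        "high": km_estimate(times[high], events[high]),
        "low": km_estimate(times[low], events[low]),
    }
    return SurvivalReport(
        coefficients=coefs,
        risk_scores=risk,
        threshold=threshold,
        group_of=group,
        logrank_p=p,
        logrank_statistic=stat,
        km_curves=curves,
    )
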