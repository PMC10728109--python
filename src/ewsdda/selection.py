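"""Degree-ranked subnetwork extraction and biomarker-selection funnels.

The early-stage network G_q is mined for warning signals: nodes are ranked
by degree (ties broken by feature-list order), the top-k nodes and their
first linking nodes form the crucial subnetwork, and the ratios on
hub-incident edges become candidate biomarkers.  Candidates then pass a
design-specific statistical funnel:

* staged (cross-sectional) designs: two-sample t-tests require at least
  ``min_significant_other_stages`` significant early-vs-later-stage
  comparisons and significance of every disease stage against the reference
  (normal) class, followed by a trajectory-shape filter;
* paired longitudinal designs: unpaired model-vs-control t-tests at every
  disease time point and subject-paired t-tests between the last pre-onset
  time point and every disease time point, followed by the onset-persistent
  trajectory filter.

Every funnel stage logs its survivor count so the selection is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import OmicsDataset
from .network import (
    DynamicNetworkBuilder,
    RatioKey,
    compute_ratios,
    ratio_pairs,
)

logger = logging.getLogger(__name__)

#: onset-persistent band gate, in sigmas of a difference of two class means
TRAJECTORY_BAND_SIGMA = 3.0

__all__ = [
    "Subnetwork",
    "CandidateRatio",
    "BiomarkerPanel",
    "extract_subnetwork",
    "trajectory_filter",
    "staged_selection",
    "timeseries_selection",
    "StagedBiomarkerSelector",
    "TimeSeriesBiomarkerSelector",
]


@dataclass
class Subnetwork:
    """Top-degree hubs of the focus-class graph plus their first neighbors."""

    focus_class: str
    hubs: list[str]
    members: list[str]
    edges: list[tuple[str, str]]
    candidate_ratios: list[RatioKey]
    per_class_views: dict[str, nx.Graph]


@dataclass
class CandidateRatio:
    ratio: RatioKey
    p_values: dict[str, float] = field(default_factory=dict)
    trajectory: dict[str, tuple[float, float]] = field(default_factory=dict)
    passed_filters: list[str] = field(default_factory=list)


@dataclass
class BiomarkerPanel:
    ratios: list[RatioKey]
    candidates: list[CandidateRatio]
    funnel: dict[str, int]

    def labels(self) -> list[str]:
        return [k.label() for k in self.ratios]

    def results_frame(self) -> pd.DataFrame:
        recs = []
        for c in self.candidates:
            rec = {"ratio": c.ratio.label(), "selected": c.ratio in self.ratios}
            rec.update(c.p_values)
            rec["passed_filters"] = ";".join(c.passed_filters)
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


def rank_by_degree(net: nx.Graph, node_order: list[str]) -> list[str]:
    """Nodes by descending degree; ties broken by position in node_order."""
    pos = {f: i for i, f in enumerate(node_order)}
    return sorted(node_order, key=lambda f: (-net.degree(f), pos[f]))


def extract_subnetwork(
    nets: dict[str, nx.Graph],
    focus_class: str,
    top_k: int,
    node_order: list[str] | None = None,
) -> Subnetwork:
    """Hubs = top_k nodes of G_focus by degree; members = hubs + neighbors;
    candidate ratios = every edge incident to a hub."""
    if focus_class not in nets:
        raise ValueError(f"focus class {focus_class!r} has no network")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    g = nets[focus_class]
    if node_order is None:
        node_order = list(g.nodes)
    if g.number_of_edges() == 0:
        logger.warning("focus network %s is empty; empty candidate set", focus_class)
        return Subnetwork(focus_class, [], [], [], [], {c: nx.Graph() for c in nets})
    ranked = rank_by_degree(g, node_order)
    hubs = ranked[:top_k]
    logger.info(
        "degree ranking in G_%s (ties by feature order): %s",
        focus_class,
        [(f, g.degree(f)) for f in ranked[: top_k + 3]],
    )
    members_set = set(hubs)
    for h in hubs:
        members_set.update(g.neighbors(h))
    members = [f for f in node_order if f in members_set]
    pos = {f: i for i, f in enumerate(node_order)}
    cand = set()
    for h in hubs:
        for nbr in g.neighbors(h):
            a, b = (h, nbr) if pos[h] < pos[nbr] else (nbr, h)
            cand.add(RatioKey(a, b))
    candidate_ratios = sorted(cand, key=lambda k: (pos[k.numerator], pos[k.denominator]))
    views = {c: net.subgraph(members).copy() for c, net in nets.items()}
    edges = [tuple(e) for e in g.subgraph(members).edges]
    return Subnetwork(focus_class, hubs, members, edges, candidate_ratios, views)


# ----------------------------------------------------------------------
# statistical tests with degenerate-variance guards
# ----------------------------------------------------------------------
def two_sample_p(x: np.ndarray, y: np.ndarray, variant: str = "welch") -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.pvalue)


def paired_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired t-test; all-zero differences give t = 0, p = 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired test requires equal-length pairs")
    if x.shape[0] < 3:
        raise ValueError("paired t-test needs at least 3 complete pairs")
    diff = x - y
    if np.ptp(diff) == 0:
        return 1.0 if diff[0] == 0 else 0.0
    return float(stats.ttest_rel(x, y).pvalue)


# ----------------------------------------------------------------------
def _class_trajectory(
    values: np.ndarray, classes: np.ndarray, class_order: list[str]
) -> dict[str, tuple[float, float]]:
    """Per-class (mean, standard error) of one ratio."""
    out = {}
    for c in class_order:
        v = values[classes == c]
        out[c] = (float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0)
    return out


def trajectory_filter(
    trajectory: dict[str, tuple[float, float]],
    class_order: list[str],
    rule: str,
    onset_class: str | None = None,
) -> bool:
    """Trajectory-shape filter on per-class (mean, SE).

    strict_monotone: class means strictly increasing or strictly decreasing
    along class_order.  onset_persistent: pre-onset means stay within a
    band around the first class's mean, and every mean from the onset class
    onward lies outside the band on one common side.  The band half-width is
    ``TRAJECTORY_BAND_SIGMA * sqrt(2) *`` the pooled pre-onset SE: the
    difference of two class means has SE ~ sqrt(2) times a single mean's SE,
    and a 3-sigma gate keeps a genuinely stable pre-onset trajectory inside
    the band with high probability while a plateau shift of a few
    within-class SDs clears it.
    """
    means = np.array([trajectory[c][0] for c in class_order])
    if rule == "strict_monotone":
        d = np.diff(means)
        return bool(np.all(d > 0) or np.all(d < 0))
    if rule == "onset_persistent":
        if onset_class is None:
            raise ValueError("onset_persistent rule needs an onset_class")
        q = class_order.index(onset_class)
        if q == 0:
            raise ValueError("onset class cannot be the first class")
        ses = np.array([trajectory[c][1] for c in class_order])
        pooled_se = float(np.sqrt(np.mean(ses[:q] ** 2)))
        band = TRAJECTORY_BAND_SIGMA * np.sqrt(2.0) * pooled_se
        ref = means[0]
        pre_ok = np.all(np.abs(means[1:q] - ref) <= band)
        above = np.all(means[q:] > ref + band)
        below = np.all(means[q:] < ref - band)
        return bool(pre_ok and (above or below))
    raise ValueError(f"unknown trajectory rule {rule!r}")


# ----------------------------------------------------------------------
def staged_selection(
    candidates: list[RatioKey],
    ratios: pd.DataFrame,
    classes: np.ndarray,
    class_order: list[str],
    alpha: float = 0.05,
    min_significant_other_stages: int = 2,
    test_variant: str = "welch",
    trajectory_rule: str = "strict_monotone",
) -> BiomarkerPanel:
    """Cross-sectional funnel.  class_order = (reference, early, later...);
    keep candidates with (a) >= min_significant_other_stages significant
    early-vs-later comparisons, (b) significance of *every* disease class
    against the reference, then (c) the trajectory filter."""
    if len(class_order) < 3:
        raise ValueError("staged selection needs a reference, an early and later classes")
    classes = np.asarray(classes)
    reference, early = class_order[0], class_order[1]
    later = class_order[2:]
    disease = class_order[1:]

    cands: list[CandidateRatio] = []
    survivors_tests: list[CandidateRatio] = []
    for key in candidates:
        row = ratios.loc[key.label()].to_numpy(dtype=float)
        c = CandidateRatio(ratio=key)
        c.trajectory = _class_trajectory(row, classes, class_order)
        n_sig_later = 0
        for lc in later:
            p = two_sample_p(row[classes == early], row[classes == lc], test_variant)
            c.p_values[f"{early}_vs_{lc}"] = p
            n_sig_later += p < alpha
        all_sig_ref = True
        for dc in disease:
            p = two_sample_p(row[classes == reference], row[classes == dc], test_variant)
            c.p_values[f"{reference}_vs_{dc}"] = p
            all_sig_ref &= p < alpha
        cands.append(c)
        if n_sig_later >= min_significant_other_stages:
            c.passed_filters.append("early_vs_later")
        if all_sig_ref:
            c.passed_filters.append("reference_vs_disease")
        if n_sig_later >= min_significant_other_stages and all_sig_ref:
            survivors_tests.append(c)

    selected = []
    for c in survivors_tests:
        if trajectory_filter(c.trajectory, class_order, trajectory_rule, onset_class=early):
            c.passed_filters.append("trajectory")
            selected.append(c.ratio)

    funnel = {
        "candidates": len(candidates),
        "after_stage_tests": len(survivors_tests),
        "after_trajectory": len(selected),
    }
    logger.info("staged selection funnel: %s", funnel)
    return BiomarkerPanel(ratios=selected, candidates=cands, funnel=funnel)


def timeseries_selection(
    candidates: list[RatioKey],
    ds: OmicsDataset,
    onset_class: str,
    alpha: float = 0.05,
    test_variant: str = "welch",
) -> BiomarkerPanel:
    """Paired longitudinal funnel.  Requires arm and subject annotations.

    (a) model vs control (unpaired, the arms have different subjects) at
    every time point from onset onward — all significant;
    (b) paired t-test between the last pre-onset time point and every
    disease time point within the model arm — all significant;
    (c) onset-persistent trajectory of the model-arm means.
    """
    if ds.arm_of is None or ds.subject_of is None:
        raise ValueError("time-series selection needs arm and subject annotations")
    order = ds.class_order
    q = order.index(onset_class)
    if q == 0:
        raise ValueError("onset class cannot be the first time point")
    ref_tp = order[q - 1]
    disease_tps = order[q:]

    ratios = compute_ratios(ds)
    classes = ds.classes
    arm = np.array([ds.arm_of[s] for s in ds.sample_ids])
    subj = np.array([ds.subject_of[s] for s in ds.sample_ids])
    model_mask = arm == "model"

    cands: list[CandidateRatio] = []
    sel_a: list[CandidateRatio] = []
    sel_b: list[CandidateRatio] = []
    selected: list[RatioKey] = []
    for key in candidates:
        row = ratios.loc[key.label()].to_numpy(dtype=float)
        c = CandidateRatio(ratio=key)
        c.trajectory = _class_trajectory(row[model_mask], classes[model_mask], order)
        ok_a = True
        for tp in disease_tps:
            m = row[model_mask & (classes == tp)]
            ctl = row[~model_mask & (classes == tp)]
            p = two_sample_p(m, ctl, test_variant)
            c.p_values[f"model_vs_control@{tp}"] = p
            ok_a &= p < alpha
        ok_b = True
        for tp in disease_tps:
            x, y = _paired_vectors(row, classes, subj, model_mask, ref_tp, tp)
            p = paired_p(x, y)
            c.p_values[f"paired_{ref_tp}_vs_{tp}"] = p
            ok_b &= p < alpha
        cands.append(c)
        if ok_a:
            c.passed_filters.append("model_vs_control")
            sel_a.append(c)
        if ok_b:
            c.passed_filters.append("paired_onset")
            if ok_a:
                sel_b.append(c)
        if ok_a and ok_b and trajectory_filter(c.trajectory, order, "onset_persistent", onset_class):
            c.passed_filters.append("trajectory")
            selected.append(key)

    funnel = {
        "candidates": len(candidates),
        "after_model_vs_control": len(sel_a),
        "after_paired_tests": len(sel_b),
        "after_trajectory": len(selected),
    }
    logger.info("time-series selection funnel: %s", funnel)
    return BiomarkerPanel(ratios=selected, candidates=cands, funnel=funnel)


def _paired_vectors(row, classes, subj, model_mask, tp_a, tp_b):
    """Model-arm values at two time points aligned by subject; subjects
    lacking either time point are dropped (logged)."""
    a = {s: v for s, v, m, c in zip(subj, row, model_mask, classes) if m and c == tp_a}
    b = {s: v for s, v, m, c in zip(subj, row, model_mask, classes) if m and c == tp_b}
    common = [s for s in a if s in b]
    dropped = (set(a) | set(b)) - set(common)
    if dropped:
        logger.info("paired %s vs %s: dropped subjects without both time points: %s", tp_a, tp_b, sorted(dropped))
    if len(common) < 3:
        raise ValueError(f"fewer than 3 complete pairs for {tp_a} vs {tp_b}")
    return np.array([a[s] for s in common]), np.array([b[s] for s in common])


# ----------------------------------------------------------------------
# scikit-learn estimator surface
# ----------------------------------------------------------------------
class _BaseRatioSelector(TransformerMixin, BaseEstimator):
    """Shared transform: expand samples x features into ratios, keep panel columns."""

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        ii, jj = np.triu_indices(self.n_features_in_, k=1)
        R = X[:, ii] / X[:, jj]
        return R[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "support_")
        return np.array(self.panel_.labels())

    def _finalize(self, feature_names: list[str], panel: BiomarkerPanel) -> None:
        keys = ratio_pairs(list(feature_names))
        chosen = set(panel.ratios)
        self.support_ = np.array([k in chosen for k in keys], dtype=bool)
        self.panel_ = panel
        self.funnel_ = dict(panel.funnel)


class StagedBiomarkerSelector(_BaseRatioSelector):
    """End-to-end staged pipeline as a scikit-learn selector.

    fit(X, y): X is samples x features (strictly positive), y the per-sample
    ordered stage labels.  Builds the dynamic networks, extracts the
    early-stage hub subnetwork and runs the staged statistical funnel;
    transform(X) returns the selected panel's ratio values.

    Parameters mirror the pipeline configuration: ``class_order`` is
    (reference, early, later...); ``top_k`` hubs feed the candidate set.
    """

    def __init__(
        self,
        class_order=None,
        epsilon: float = 0.6,
        top_k: int = 5,
        alpha: float = 0.05,
        min_significant_other_stages: int = 2,
        test_variant: str = "welch",
        trajectory_rule: str = "strict_monotone",
        mk_form: str = "as_printed",
    ):
        self.class_order = class_order
        self.epsilon = epsilon
        self.top_k = top_k
        self.alpha = alpha
        self.min_significant_other_stages = min_significant_other_stages
        self.test_variant = test_variant
        self.trajectory_rule = trajectory_rule
        self.mk_form = mk_form

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        feature_names = list(feature_names)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.array(feature_names, dtype=object)
        order = list(self.class_order) if self.class_order is not None else list(dict.fromkeys(y))

        builder = DynamicNetworkBuilder(self.epsilon, self.mk_form, order)
        builder.fit(X, y, feature_names=feature_names)
        self.networks_ = builder.networks_
        self.centroid_table_ = builder.centroid_table_

        focus = order[1]
        self.subnetwork_ = extract_subnetwork(self.networks_, focus, self.top_k, feature_names)
        ii, jj = np.triu_indices(X.shape[1], k=1)
        ratios = pd.DataFrame(
            (X[:, ii] / X[:, jj]).T,
            index=[f"{feature_names[i]}/{feature_names[j]}" for i, j in zip(ii, jj)],
        )
        panel = staged_selection(
            self.subnetwork_.candidate_ratios,
            ratios,
            y,
            order,
            alpha=self.alpha,
            min_significant_other_stages=self.min_significant_other_stages,
            test_variant=self.test_variant,
            trajectory_rule=self.trajectory_rule,
        )
        self._finalize(feature_names, panel)
        return self


class TimeSeriesBiomarkerSelector(_BaseRatioSelector):
    """End-to-end longitudinal pipeline as a scikit-learn selector.

    fit(X, y, subject=..., arm=...): y holds time-point labels.  Networks
    are built on the model arm only (time points are the classes); the
    funnel uses both arms.  ``onset_class`` marks disease onset.
    """

    def __init__(
        self,
        onset_class: str,
        class_order=None,
        epsilon: float = 2.3,
        top_k: int = 1,
        alpha: float = 0.05,
        test_variant: str = "welch",
        mk_form: str = "as_printed",
    ):
        self.onset_class = onset_class
        self.class_order = class_order
        self.epsilon = epsilon
        self.top_k = top_k
        self.alpha = alpha
        self.test_variant = test_variant
        self.mk_form = mk_form

    def fit(self, X, y, subject=None, arm=None, feature_names=None):
        if subject is None or arm is None:
            raise ValueError("fit requires subject= and arm= per-sample arrays")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        subject = np.asarray(subject)
        arm = np.asarray(arm)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        feature_names = list(feature_names)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.array(feature_names, dtype=object)
        order = list(self.class_order) if self.class_order is not None else list(dict.fromkeys(y))

        model = arm == "model"
        builder = DynamicNetworkBuilder(self.epsilon, self.mk_form, order)
        builder.fit(X[model], y[model], feature_names=feature_names)
        self.networks_ = builder.networks_
        self.centroid_table_ = builder.centroid_table_
        self.subnetwork_ = extract_subnetwork(self.networks_, self.onset_class, self.top_k, feature_names)

        sample_ids = [f"s{i}" for i in range(X.shape[0])]
        ds = OmicsDataset(
            feature_ids=feature_names,
            sample_ids=sample_ids,
            values=X.T,
            class_of=dict(zip(sample_ids, y)),
            class_order=order,
            subject_of=dict(zip(sample_ids, subject)),
            arm_of=dict(zip(sample_ids, arm)),
        )
        panel = timeseries_selection(
            self.subnetwork_.candidate_ratios,
            ds,
            self.onset_class,
            alpha=self.alpha,
            test_variant=self.test_variant,
        )
        self._finalize(feature_names, panel)
        return self
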