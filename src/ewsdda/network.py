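"""Shrunken-centroid statistic on pairwise molecular ratios and the
per-stage signed dynamic networks built from it.

For features f_i, f_j the molecular ratio r_ij = f_i / f_j is treated as the
readout of an assumed pathway reaction.  For every ratio and every ordered
class (stage / time point) c_k the statistic

    d_ijk = (mu_ijk - mu_ij) / (m_k * (s_ij + s_0))

compares the class centroid mu_ijk of the ratio with its overall centroid
mu_ij, standardised by the pooled within-class standard deviation s_ij plus
a stabiliser s_0 (the median of s_ij over all ratios, which damps ratios
whose raw scale is small), and by the class-size factor m_k.  m_k defaults
to sqrt(1/n + 1/n_k); the classical nearest-shrunken-centroid factor
sqrt(1/n_k - 1/n) is available as ``mk_form="classical"``.

A stage network G_k links f_i and f_j with an "up" (red) edge when
d_ijk >= epsilon and a "down" (green) edge when d_ijk <= -epsilon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import OmicsDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RatioKey",
    "CentroidTable",
    "ratio_pairs",
    "compute_ratios",
    "shrunken_centroid",
    "build_networks",
    "networks_from_dataset",
    "PairwiseRatios",
    "DynamicNetworkBuilder",
]


@dataclass(frozen=True, order=True)
class RatioKey:
    """Canonical unordered feature pair, oriented numerator index < denominator index."""

    numerator: str
    denominator: str

    def label(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    def as_edge(self) -> tuple[str, str]:
        return (self.numerator, self.denominator)


def ratio_pairs(feature_ids: list[str]) -> list[RatioKey]:
    """All m(m-1)/2 canonical pairs in feature-list order."""
    m = len(feature_ids)
    return [
        RatioKey(feature_ids[i], feature_ids[j]) for i in range(m) for j in range(i + 1, m)
    ]


def _pair_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(m, k=1)
    return iu[0], iu[1]


def compute_ratios(ds: OmicsDataset) -> pd.DataFrame:
    """Ratio matrix r_ij = f_i / f_j for every canonical pair i < j.

    Returns a DataFrame with one row per ratio (index "fi/fj") and one
    column per sample.  Requires a strictly positive, preprocessed matrix.
    """
    if not np.all(np.isfinite(ds.values)):
        raise ValueError("ratio computation requires a finite (preprocessed) matrix")
    if np.any(ds.values <= 0):
        fi, si = np.argwhere(ds.values <= 0)[0]
        raise ValueError(
            "non-positive denominator candidate: feature "
            f"{ds.feature_ids[fi]!r}, sample {ds.sample_ids[si]!r}; "
            "run preprocessing first"
        )
    ii, jj = _pair_indices(ds.n_features)
    ratios = ds.values[ii, :] / ds.values[jj, :]
    index = [f"{ds.feature_ids[i]}/{ds.feature_ids[j]}" for i, j in zip(ii, jj)]
    return pd.DataFrame(ratios, index=index, columns=ds.sample_ids)


@dataclass
class CentroidTable:
    """All intermediates of the shrunken-centroid computation.

    Arrays are aligned: ``mu_class`` and ``d`` are (n_ratios, n_classes),
    ``mu_overall`` and ``s_pooled`` are (n_ratios,).
    """

    ratio_keys: list[RatioKey]
    classes: list[str]
    class_sizes: np.ndarray
    mu_class: np.ndarray
    mu_overall: np.ndarray
    s_pooled: np.ndarray
    s0: float
    m_class: np.ndarray
    d: np.ndarray
    mk_form: str = "as_printed"
    meta: dict = field(default_factory=dict)

    @property
    def n_ratios(self) -> int:
        return len(self.ratio_keys)

    def ratio_labels(self) -> list[str]:
        return [k.label() for k in self.ratio_keys]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (ratio, class, d, mu_class, mu_overall, s_pooled)."""
        recs = []
        for r, key in enumerate(self.ratio_keys):
            for k, c in enumerate(self.classes):
                recs.append(
                    {
                        "ratio": key.label(),
                        "numerator": key.numerator,
                        "denominator": key.denominator,
                        "class": c,
                        "d": self.d[r, k],
                        "mu_class": self.mu_class[r, k],
                        "mu_overall": self.mu_overall[r],
                        "s_pooled": self.s_pooled[r],
                    }
                )
        df = pd.DataFrame.from_records(recs)
        df.attrs["s0"] = self.s0
        return df


def _mk(n: int, n_k: np.ndarray, form: str) -> np.ndarray:
    if form == "as_printed":
        return np.sqrt(1.0 / n + 1.0 / n_k)
    if form == "classical":
        return np.sqrt(1.0 / n_k - 1.0 / n)
    raise ValueError(f"unknown mk_form {form!r} (expected 'as_printed' or 'classical')")


def shrunken_centroid(
    ratios: pd.DataFrame | np.ndarray,
    classes: np.ndarray,
    class_order: list[str],
    mk_form: str = "as_printed",
    ratio_keys: list[RatioKey] | None = None,
) -> CentroidTable:
    """Compute d_ijk for every ratio and class.

    Parameters
    ----------
    ratios : (n_ratios, n_samples) matrix
        One row per canonical ratio (e.g. from :func:`compute_ratios`).
    classes : array of per-sample class labels.
    class_order : ordered class labels; every class needs >= 2 samples.
    mk_form : {"as_printed", "classical"}
        Class-size factor sqrt(1/n + 1/n_k) vs sqrt(1/n_k - 1/n).
    """
    if isinstance(ratios, pd.DataFrame):
        if ratio_keys is None:
            ratio_keys = [
                RatioKey(*lbl.split("/", 1)) for lbl in ratios.index
            ]
        values = ratios.to_numpy(dtype=float)
    else:
        values = np.asarray(ratios, dtype=float)
        if ratio_keys is None:
            ratio_keys = [RatioKey(f"r{r}", f"_{r}") for r in range(values.shape[0])]
    classes = np.asarray(classes)
    n_ratios, n = values.shape
    if n_ratios < 2:
        raise ValueError("need at least 2 ratios: s0 is a median over ratios")
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    masks = [classes == c for c in class_order]
    n_k = np.array([int(m.sum()) for m in masks])
    if np.any(n_k < 2):
        bad = [c for c, nk in zip(class_order, n_k) if nk < 2]
        raise ValueError(f"classes with fewer than 2 samples: {bad}")
    if int(n_k.sum()) != n:
        raise ValueError("class labels do not cover all samples exactly once")

    mu_class = np.column_stack([values[:, m].mean(axis=1) for m in masks])
    mu_overall = values.mean(axis=1)
    # pooled within-class variance with the unbiased n - z denominator
    z = len(class_order)
    ss = np.zeros(n_ratios)
    for k, m in enumerate(masks):
        dev = values[:, m] - mu_class[:, [k]]
        ss += np.sum(dev * dev, axis=1)
    s_pooled = np.sqrt(ss / (n - z))
    s0 = float(np.median(s_pooled))
    m_class = _mk(n, n_k, mk_form)

    denom = m_class[None, :] * (s_pooled[:, None] + s0)
    num = mu_class - mu_overall[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(denom <= 0):
        logger.warning(
            "s_ij + s0 = 0 for %d ratios; their d set to 0 (globally constant ratios)",
            int(np.sum(denom[:, 0] <= 0)),
        )
    return CentroidTable(
        ratio_keys=list(ratio_keys),
        classes=list(class_order),
        class_sizes=n_k,
        mu_class=mu_class,
        mu_overall=mu_overall,
        s_pooled=s_pooled,
        s0=s0,
        m_class=m_class,
        d=d,
        mk_form=mk_form,
    )


def build_networks(
    table: CentroidTable,
    epsilon: float,
    feature_ids: list[str] | None = None,
) -> dict[str, nx.Graph]:
    """One undirected signed graph per class.

    An edge (f_i, f_j) exists in G_k iff |d_ijk| >= epsilon (inclusive);
    its ``sign`` attribute is "up" for d >= epsilon (red) and "down" for
    d <= -epsilon (green), and it carries the d value and ratio label.
    All features appear as nodes even when isolated.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if feature_ids is None:
        seen: dict[str, None] = {}
        for key in table.ratio_keys:
            seen.setdefault(key.numerator)
            seen.setdefault(key.denominator)
        feature_ids = list(seen)
    nets: dict[str, nx.Graph] = {}
    for k, c in enumerate(table.classes):
        g = nx.Graph(name=str(c))
        g.add_nodes_from(feature_ids)
        dk = table.d[:, k]
        for r in np.flatnonzero(np.abs(dk) >= epsilon):
            key = table.ratio_keys[r]
            g.add_edge(
                key.numerator,
                key.denominator,
                sign="up" if dk[r] >= epsilon else "down",
                d=float(dk[r]),
                ratio=key.label(),
            )
        nets[c] = g
        logger.info("network %s: %d nodes, %d edges (epsilon=%g)", c, g.number_of_nodes(), g.number_of_edges(), epsilon)
    return nets


def networks_from_dataset(
    ds: OmicsDataset,
    epsilon: float,
    mk_form: str = "as_printed",
) -> tuple[dict[str, nx.Graph], CentroidTable]:
    """Ratios -> statistic -> per-class networks, in one call."""
    ratios = compute_ratios(ds)
    keys = ratio_pairs(ds.feature_ids)
    table = shrunken_centroid(ratios, ds.classes, ds.class_order, mk_form, ratio_keys=keys)
    nets = build_networks(table, epsilon, feature_ids=ds.feature_ids)
    return nets, table


# ----------------------------------------------------------------------
# scikit-learn estimator surface
# ----------------------------------------------------------------------
class PairwiseRatios(TransformerMixin, BaseEstimator):
    """Expand a samples x features matrix into all pairwise feature ratios.

    Follows the scikit-learn convention (samples are rows).  Output columns
    are the canonical pairs i < j in input column order, named
    ``feature_names_in_[i] + "/" + feature_names_in_[j]`` when names are
    available.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        ii, jj = _pair_indices(X.shape[1])
        return X[:, ii] / X[:, jj]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        if input_features is None:
            input_features = [f"x{i}" for i in range(self.n_features_in_)]
        ii, jj = _pair_indices(self.n_features_in_)
        return np.array([f"{input_features[i]}/{input_features[j]}" for i, j in zip(ii, jj)])

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if not np.all(np.isfinite(X)) or np.any(X <= 0):
            raise ValueError("pairwise ratios require strictly positive, finite values")
        return X


class DynamicNetworkBuilder(BaseEstimator):
    """Fit the ratio shrunken-centroid statistic and build stage networks.

    Parameters
    ----------
    epsilon : float, default 0.6
        Edge threshold on |d_ijk| (0.6 is the staged/genomics default;
        time-series analyses conventionally use 2.3).
    mk_form : {"as_printed", "classical"}
    class_order : list of labels or None
        Required at fit; the semantic stage ordering.

    Attributes
    ----------
    centroid_table_ : CentroidTable
    networks_ : dict class -> networkx.Graph
    """

    def __init__(self, epsilon: float = 0.6, mk_form: str = "as_printed", class_order=None):
        self.epsilon = epsilon
        self.mk_form = mk_form
        self.class_order = class_order

    def fit(self, X, y, feature_names=None):
        """X: samples x features (strictly positive); y: per-sample class labels."""
        X = PairwiseRatios._validate(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y length must match number of samples")
        order = list(self.class_order) if self.class_order is not None else list(dict.fromkeys(y))
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        feature_names = list(feature_names)
        self.feature_names_in_ = np.array(feature_names, dtype=object)
        self.n_features_in_ = X.shape[1]
        ii, jj = _pair_indices(X.shape[1])
        keys = [RatioKey(feature_names[i], feature_names[j]) for i, j in zip(ii, jj)]
        ratios = (X[:, ii] / X[:, jj]).T
        self.centroid_table_ = shrunken_centroid(ratios, y, order, self.mk_form, ratio_keys=keys)
        self.networks_ = build_networks(self.centroid_table_, self.epsilon, feature_names)
        return self

    def d_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "centroid_table_")
        return self.centroid_table_.to_frame()
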