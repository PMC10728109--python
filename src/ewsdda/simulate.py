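"""Synthetic staged and longitudinal omics data with planted ratio-level
early-warning signals.

Feature model
-------------
Features are log-normal: ``log f = b_f + e`` with per-feature baselines
``b_f ~ N(BASELINE_LOG_MEAN, BASELINE_LOG_SD^2)`` and independent noise
``e ~ N(0, noise_sd^2)``, which guarantees strict positivity (ratios need
positive denominators) and makes effect sizes interpretable in SD units.

Planted signals
---------------
A planted signal is a hub feature plus partner features whose pairwise
ratios with the hub carry the warning signal.  Each partner is generated
*coupled* to the hub: ``log partner = log hub - delta0 + eta`` with small
coupling noise ``eta ~ N(0, ratio_sd^2)``, so the hub/partner log-ratio is
a tight, low-variance pathway readout (the biological picture behind ratio
networks: a definite reaction relationship).  The signal shifts that
log-ratio by ``g(class) * effect_size * ratio_sd`` — i.e. by ``effect_size``
pooled within-class SDs of the log-ratio — where the stage profile g is

* staged design, ``persistent=False``: 1 at ``signal_class`` only
  (a stage-specific early signal);
* staged design, ``persistent=True``: 1, 2, 3, ... from ``signal_class``
  onward (a stepwise deepening shift across disease stages);
* time-series design, ``persistent=True``: a flat plateau of 1 from the
  onset time point onward (stable high expression after disease onset);

Coupling is what confines the differential signal to hub-partner ratios:
shifting feature *means* instead would leak comparable shifts into every
partner-vs-background ratio (ratio shifts are differences of per-feature
log shifts), and no mean-shift scheme can light up hub-partner pairs while
keeping partner-background pairs dark.  The baseline offset ``delta0``
places the raw scale of planted ratios relative to the cohort's median
ratio scale (which the statistic's s0 stabiliser is the median of), so a
given effect size lands in the statistic's detectable window; see
docs/methods.md for the calibration argument.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .dataset import OmicsDataset
from .network import RatioKey

__all__ = [
    "PlantedSignal",
    "generate_staged",
    "generate_timeseries",
    "inject_missing",
    "zero_out_group",
    "STAGED_CLASS_ORDER",
    "default_staged_class_sizes",
]

# -- design constants ---------------------------------------------------
BASELINE_LOG_MEAN = 3.0
BASELINE_LOG_SD = 0.5
#: coupling noise of a planted hub/partner log-ratio, as a fraction of noise_sd
RATIO_NOISE_FRAC = 1.0 / 60.0
#: raw scale of planted ratios relative to the cohort's (predicted) median
#: ratio SD, i.e. relative to the s0 stabiliser of the shrunken-centroid
#: statistic.  The statistic's grand-mean centring spreads a one-class shift
#: into the other classes at -n_k/(n - n_k) of the signal-class value
#: (-1/4 with five equal classes), so the raw scale of a planted ratio has a
#: window: large enough that the signal-class d clears the conventional
#: staged threshold 0.6, small enough that the spillover stays below it.
#: X = 0.08 places the one-class signal-class d near 16 X/(X+1) ~ 1.2 at
#: effect size 4, the centre of that window.  The time-series plateau (3 of 7 time points shifted)
#: dilutes the onset-class centroid contrast to (1 - 3/7) of the shift, and
#: the conventional time-series threshold is 2.3, hence the larger scale:
#: onset d ~ 5.7 X/(X+1) ~ 3.4 at X = 1.5 (with the pre-onset spillover at
#: -3/4 of that, which is what makes pre-onset edges green rather than
#: absent).  Derivations in docs/methods.md.
STAGED_SIGNAL_SCALE = 0.08
TIMESERIES_SIGNAL_SCALE = 1.5

STAGED_CLASS_ORDER = ["normal", "I", "II", "III", "IV"]


def default_staged_class_sizes() -> dict[str, int]:
    """Study-scale unequal stage sizes (normal cohort plus four tumour stages)."""
    return {"normal": 50, "I": 171, "II": 86, "III": 85, "IV": 5}


class SimulationConfigError(ValueError):
    """Raised when a planted signal or design parameter is inconsistent."""


@dataclass(frozen=True)
class PlantedSignal:
    """A hub-and-partners ratio motif switching on at ``signal_class``.

    effect_size is in units of the pooled within-class SD of the planted
    log-ratio.  ``persistent`` selects the stage profile described in the
    module docstring.
    """

    hub_feature: str
    partner_features: tuple[str, ...]
    signal_class: str
    effect_size: float
    persistent: bool = False

    def __post_init__(self):
        object.__setattr__(self, "partner_features", tuple(self.partner_features))
        if self.hub_feature in self.partner_features:
            raise SimulationConfigError("hub_feature must not be one of its partners")

    def ratio_keys(self, feature_ids: list[str]) -> list[RatioKey]:
        """Planted ratios in the canonical i < j orientation of the feature list."""
        pos = {f: i for i, f in enumerate(feature_ids)}
        keys = []
        for p in self.partner_features:
            a, b = self.hub_feature, p
            if pos[a] > pos[b]:
                a, b = b, a
            keys.append(RatioKey(a, b))
        return keys


def _expected_median_ratio_sd(noise_sd: float) -> float:
    """Median raw-scale SD of a background ratio, up to the cohort's median
    baseline ratio scale (= 1 by symmetry of baseline differences)."""
    s2 = 2.0 * noise_sd**2
    return math.exp(s2 / 2.0) * math.sqrt(math.expm1(s2))


def _predicted_s0(n_features: int, signals, noise_sd: float) -> float:
    """Predicted median ratio SD (the statistic's s0) for a planted design.

    Coupled motif ratios (hub-partner and partner-partner) have SD near the
    coupling noise, far below background ratios; when they hold the median
    rank they set s0 themselves, otherwise they push the background median
    to a lower quantile of the background-scale distribution.  The planted
    raw scale must be expressed relative to this predicted s0 for a given
    effect size to land in the statistic's detectable window.
    """
    from scipy.stats import norm

    ratio_sd = RATIO_NOISE_FRAC * noise_sd
    n_total = n_features * (n_features - 1) // 2
    n_tiny = sum(
        (len(s.partner_features) + 1) * len(s.partner_features) // 2 for s in signals
    )
    if n_tiny >= n_total / 2.0:
        # the coupled partner-partner ratios hold the median
        return math.sqrt(2.0) * ratio_sd
    q = (n_total / 2.0 - n_tiny) / (n_total - n_tiny)
    scale_quantile = math.exp(norm.ppf(q) * math.sqrt(2.0) * BASELINE_LOG_SD)
    return scale_quantile * _expected_median_ratio_sd(noise_sd)


def _feature_names(n_features: int) -> list[str]:
    width = max(3, len(str(n_features)))
    return [f"f{i + 1:0{width}d}" for i in range(n_features)]


def _check_signals(signals, feature_ids, class_order):
    for s in signals:
        if s.signal_class not in class_order:
            raise SimulationConfigError(
                f"signal class {s.signal_class!r} not in class order {class_order}"
            )
        for f in (s.hub_feature, *s.partner_features):
            if f not in feature_ids:
                raise SimulationConfigError(f"signal references unknown feature {f!r}")


def _plant(
    log_values: np.ndarray,
    feature_ids: list[str],
    class_idx: np.ndarray,
    signals,
    noise_sd: float,
    rng: np.random.Generator,
    scale_x: float,
    profile: str,
) -> None:
    """Overwrite partner rows with hub-coupled values (in place, log scale)."""
    pos = {f: i for i, f in enumerate(feature_ids)}
    ratio_sd = RATIO_NOISE_FRAC * noise_sd
    delta0 = math.log(scale_x * _predicted_s0(len(feature_ids), signals, noise_sd) / ratio_sd)
    for sig in signals:
        hub = log_values[pos[sig.hub_feature], :]
        for p in sig.partner_features:
            eta = rng.normal(0.0, ratio_sd, size=log_values.shape[1])
            shift = _stage_profile(class_idx, sig, profile) * sig.effect_size * ratio_sd
            # the statistic runs on raw ratios in canonical (list-order)
            # orientation, and its raw scale matters: place the shift so the
            # *canonical* planted ratio has log-mean delta0 + shift
            if pos[sig.hub_feature] < pos[p]:
                # canonical ratio is hub/partner
                log_values[pos[p], :] = hub - delta0 - shift + eta
            else:
                # canonical ratio is partner/hub
                log_values[pos[p], :] = hub + delta0 + shift + eta


def _stage_profile(class_idx: np.ndarray, sig: PlantedSignal, profile: str) -> np.ndarray:
    q = sig._onset_index
    g = np.zeros(class_idx.shape[0])
    if not sig.persistent:
        g[class_idx == q] = 1.0
    elif profile == "staged":
        after = class_idx >= q
        g[after] = class_idx[after] - q + 1.0
    else:  # plateau
        g[class_idx >= q] = 1.0
    return g


def generate_staged(
    n_features: int = 90,
    class_sizes: dict[str, int] | None = None,
    signals: list[PlantedSignal] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    class_order: list[str] | None = None,
) -> OmicsDataset:
    """Cross-sectional dataset with ordered stages (normal, I-IV by default).

    Deterministic in ``seed``.  ``class_sizes`` defaults to study-scale
    unequal cohorts (see :func:`default_staged_class_sizes`).
    """
    if class_sizes is None:
        class_sizes = default_staged_class_sizes()
    if class_order is None:
        class_order = [c for c in STAGED_CLASS_ORDER if c in class_sizes]
        class_order += [c for c in class_sizes if c not in class_order]
    if any(class_sizes[c] < 3 for c in class_order):
        raise SimulationConfigError("all class sizes must be >= 3")
    signals = list(signals or [])
    feature_ids = _feature_names(n_features)
    _check_signals(signals, feature_ids, class_order)
    for s in signals:
        object.__setattr__(s, "_onset_index", class_order.index(s.signal_class))

    rng = np.random.default_rng(seed)
    labels = np.concatenate([[c] * class_sizes[c] for c in class_order])
    n = labels.shape[0]
    class_idx = np.array([class_order.index(c) for c in labels])

    baselines = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=n_features)
    log_values = baselines[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n))
    _plant(log_values, feature_ids, class_idx, signals, noise_sd, rng, STAGED_SIGNAL_SCALE, "staged")

    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    return OmicsDataset(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=np.exp(log_values),
        class_of=dict(zip(sample_ids, labels)),
        class_order=list(class_order),
        meta={
            "design": "staged",
            "seed": seed,
            "noise_sd": noise_sd,
            "planted": [_signal_dict(s, feature_ids) for s in signals],
        },
    )


def generate_timeseries(
    n_features: int = 90,
    n_model_subjects: int = 7,
    n_control_subjects: int = 10,
    n_timepoints: int = 7,
    onset_timepoint: int = 5,
    signals: list[PlantedSignal] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> OmicsDataset:
    """Paired longitudinal design: model and control arms, one sample per
    subject per time point (defaults mirror 7 model / 10 control subjects
    over 7 time points with disease onset at T5).

    Control-arm ratios are stationary over time; planted model-arm ratios
    shift at ``onset_timepoint`` and stay shifted (plateau).
    """
    if not (1 <= onset_timepoint <= n_timepoints):
        raise SimulationConfigError(
            f"onset_timepoint {onset_timepoint} outside 1..{n_timepoints}"
        )
    class_order = [f"T{t}" for t in range(1, n_timepoints + 1)]
    signals = list(signals or [])
    feature_ids = _feature_names(n_features)
    _check_signals(signals, feature_ids, class_order)
    for s in signals:
        object.__setattr__(s, "_onset_index", class_order.index(s.signal_class))

    rng = np.random.default_rng(seed)
    subjects = [f"M{i + 1:02d}" for i in range(n_model_subjects)] + [
        f"C{i + 1:02d}" for i in range(n_control_subjects)
    ]
    arms = ["model"] * n_model_subjects + ["control"] * n_control_subjects

    sample_ids, class_of, subject_of, arm_of = [], {}, {}, {}
    class_idx_list = []
    for subj, arm in zip(subjects, arms):
        for t in range(n_timepoints):
            sid = f"{subj}_T{t + 1}"
            sample_ids.append(sid)
            class_of[sid] = class_order[t]
            subject_of[sid] = subj
            arm_of[sid] = arm
            class_idx_list.append(t)
    n = len(sample_ids)
    # the stage profile only fires in the model arm
    class_idx = np.array(class_idx_list)
    model_mask = np.array([arm_of[s] == "model" for s in sample_ids])
    effective_idx = np.where(model_mask, class_idx, -1)

    baselines = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=n_features)
    log_values = baselines[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n))
    _plant(
        log_values,
        feature_ids,
        effective_idx,
        signals,
        noise_sd,
        rng,
        TIMESERIES_SIGNAL_SCALE,
        "plateau",
    )

    return OmicsDataset(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=np.exp(log_values),
        class_of=class_of,
        class_order=class_order,
        subject_of=subject_of,
        arm_of=arm_of,
        meta={
            "design": "timeseries",
            "seed": seed,
            "noise_sd": noise_sd,
            "onset_timepoint": onset_timepoint,
            "planted": [_signal_dict(s, feature_ids) for s in signals],
        },
    )


def _signal_dict(sig: PlantedSignal, feature_ids: list[str]) -> dict:
    return {
        "hub": sig.hub_feature,
        "partners": list(sig.partner_features),
        "signal_class": sig.signal_class,
        "effect_size": sig.effect_size,
        "persistent": sig.persistent,
        "ratios": [k.label() for k in sig.ratio_keys(feature_ids)],
    }


# -- explicit corruption for preprocessing tests ------------------------
def inject_missing(ds: OmicsDataset, rate: float, seed: int = 0) -> OmicsDataset:
    """Set a random fraction of entries to NaN (never by default generation)."""
    rng = np.random.default_rng(seed)
    values = ds.values.copy()
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    return ds.with_values(values)


def zero_out_group(ds: OmicsDataset, feature: str, class_label: str) -> OmicsDataset:
    """Zero one feature across every sample of one class (all-zero-group case)."""
    values = ds.values.copy()
    fi = ds.feature_ids.index(feature)
    values[fi, ds.class_mask(class_label)] = 0.0
    return ds.with_values(values)


def ground_truth_json(ds: OmicsDataset) -> str:
    """Planted-signal ground truth as a JSON string (for the simulate CLI)."""
    return json.dumps({"design": ds.meta.get("design"), "planted": ds.meta.get("planted", [])}, indent=2)
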