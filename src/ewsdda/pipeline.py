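"""High-level orchestration of the full analysis on an OmicsDataset:
preprocessing -> ratio networks -> hub subnetwork -> selection funnel,
returning a JSON-serialisable results bundle."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import PipelineConfig
from .dataset import OmicsDataset
from .network import CentroidTable, compute_ratios, networks_from_dataset
from .preprocess import PreprocessReport, preprocess
from .selection import (
    BiomarkerPanel,
    Subnetwork,
    extract_subnetwork,
    staged_selection,
    timeseries_selection,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_staged", "run_timeseries"]


@dataclass
class PipelineResult:
    dataset: OmicsDataset
    preprocess_report: PreprocessReport
    centroid_table: CentroidTable
    networks: dict
    subnetwork: Subnetwork
    panel: BiomarkerPanel
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def summary(self) -> dict:
        return {
            "n_features": self.dataset.n_features,
            "n_samples": self.dataset.n_samples,
            "class_sizes": self.dataset.class_sizes(),
            "epsilon": self.config.epsilon,
            "edges_per_class": {c: g.number_of_edges() for c, g in self.networks.items()},
            "hubs": self.subnetwork.hubs,
            "funnel": self.panel.funnel,
            "panel": self.panel.labels(),
            "preprocess": self.preprocess_report.to_dict(),
        }


def run_staged(ds: OmicsDataset, cfg: PipelineConfig | None = None, focus_class: str | None = None) -> PipelineResult:
    """Full staged analysis.  ``focus_class`` defaults to the second class
    in class_order (the earliest disease stage)."""
    cfg = cfg or PipelineConfig()
    ds, report = preprocess(ds)
    logger.info("staged pipeline on %d features x %d samples", ds.n_features, ds.n_samples)
    nets, table = networks_from_dataset(ds, cfg.epsilon, cfg.mk_form)
    focus = focus_class or ds.class_order[1]
    sub = extract_subnetwork(nets, focus, cfg.top_k_hubs, ds.feature_ids)
    ratios = compute_ratios(ds)
    panel = staged_selection(
        sub.candidate_ratios,
        ratios,
        ds.classes,
        ds.class_order,
        alpha=cfg.alpha,
        min_significant_other_stages=cfg.min_significant_other_stages,
        test_variant=cfg.test_variant,
        trajectory_rule=cfg.trajectory_rule,
    )
    return PipelineResult(ds, report, table, nets, sub, panel, cfg)


def run_timeseries(
    ds: OmicsDataset,
    onset_class: str,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Full longitudinal analysis: networks on the model arm (time points as
    classes), selection funnel using both arms."""
    cfg = cfg or PipelineConfig(epsilon=2.3, top_k_hubs=1, trajectory_rule="onset_persistent")
    ds, report = preprocess(ds)
    model = ds.model_arm()
    logger.info(
        "time-series pipeline: %d model / %d control samples",
        model.n_samples, ds.n_samples - model.n_samples,
    )
    nets, table = networks_from_dataset(model, cfg.epsilon, cfg.mk_form)
    sub = extract_subnetwork(nets, onset_class, cfg.top_k_hubs, ds.feature_ids)
    panel = timeseries_selection(
        sub.candidate_ratios, ds, onset_class, alpha=cfg.alpha, test_variant=cfg.test_variant
    )
    return PipelineResult(ds, report, table, nets, sub, panel, cfg)
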