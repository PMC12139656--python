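"""End-to-end orchestration of the classification workflow.

``run_train`` wires the training path (ΔSv differencing, ROI extraction,
K-means refinement, library building, cluster-count selection, hierarchical
classification, random-forest validation, dominant-frequency assignment,
ellipsoid fitting); ``run_classify`` applies a fitted model to a whole grid;
``run_metrics`` summarizes per-zone, per-period acoustic metrics.  All
randomness flows from explicit seeds carried in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .echogrid import EchogramSet, IntegrationConfig, classify_solar
from .metrics import (
    DVM_FREQUENCIES_KHZ,
    MESO_TOP_M,
    ZoneLabeling,
    depth_category_nasc,
    dvm_strength,
    total_sa,
)
from .multifreq import DeltaSvGrid, compute_delta_sv
from .scoring import (
    ClassifiedGrid,
    EchoClassModel,
    classify_cells,
    fit_ellipsoids,
    per_class_echograms,
    sensitivity_sweep,
)
from .training import (
    ClusterSelectionReport,
    RfValidationReport,
    Roi,
    build_library,
    dominant_frequency,
    extract_roi_cells,
    hierarchical_classify,
    kmeans_refine,
    rf_validate,
    select_k,
)

__all__ = ["PipelineConfig", "TrainResult", "run_train", "run_classify", "run_metrics"]


@dataclass
class PipelineConfig:
    """Workflow parameters; defaults match the standard survey configuration
    (3-ping x 1.5 m ESDU, -100 dB threshold, 15 m exclusion, ellipsoid
    threshold 25)."""

    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    k_candidates: Sequence[int] = tuple(range(2, 9))
    k_roi: int = 3
    seed: int = 0
    threshold: float = 25.0
    sweep_thresholds: Sequence[float] = tuple(range(1, 101))
    roi_file: str | None = None
    zone_file: str | None = None
    scatter_file: str | None = None
    medium: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        integ = IntegrationConfig(**(raw.get("integration") or {}))
        clus = raw.get("clustering") or {}
        esc = raw.get("escore") or {}
        met = raw.get("metrics") or {}
        scat = raw.get("scattering") or {}
        sweep = esc.get("sweep") or {}
        return cls(
            integration=integ,
            k_candidates=tuple(clus.get("k_candidates", range(2, 9))),
            k_roi=int(clus.get("k_roi", 3)),
            seed=int(clus.get("seed", raw.get("seed", 0))),
            threshold=float(esc.get("threshold", 25.0)),
            sweep_thresholds=tuple(
                np.arange(
                    float(sweep.get("lo", 1)),
                    float(sweep.get("hi", 100)) + 1e-9,
                    float(sweep.get("step", 1)),
                )
            ),
            roi_file=raw.get("roi_file"),
            zone_file=met.get("zone_file"),
            scatter_file=scat.get("parameter_file"),
            medium=scat.get("medium") or {},
        )


@dataclass
class TrainResult:
    model: EchoClassModel
    library: object  # labelled EchoTypeLibrary
    selection: ClusterSelectionReport
    rf_report: RfValidationReport
    delta: DeltaSvGrid


def run_train(
    eset: EchogramSet,
    rois: Sequence[Roi],
    config: PipelineConfig | None = None,
) -> TrainResult:
    """Train an echo-class model from an aligned EchogramSet and ROIs.

    The number of echo-classes is selected by the validity-index vote over
    ``config.k_candidates``; each ROI yields one echo-type (K-means with
    ``k_roi`` clusters, seed derived deterministically per ROI).
    """
    config = config or PipelineConfig()
    delta = compute_delta_sv(eset)
    echo_types = []
    for i, roi in enumerate(rois):
        coords, triplets = extract_roi_cells(delta, roi)
        k = min(config.k_roi, len(triplets))
        echo_types.append(
            kmeans_refine(
                coords,
                triplets,
                k_roi=k,
                seed=(config.seed + i) % (2**31 - 1),
                retain=roi.retain,
                echo_type_id=f"et_{roi.id}",
                source_roi=roi.id,
            )
        )
    library = build_library(echo_types)
    selection = select_k(library, list(config.k_candidates), seed=config.seed)
    labelled = hierarchical_classify(library, selection.winning_k)
    rf_report = rf_validate(labelled, seed=config.seed)
    dom = dominant_frequency(labelled, eset)
    model = fit_ellipsoids(labelled, threshold=config.threshold, dominant_khz=dom)
    return TrainResult(
        model=model,
        library=labelled,
        selection=selection,
        rf_report=rf_report,
        delta=delta,
    )


def run_classify(
    eset: EchogramSet,
    model: EchoClassModel,
    truth: np.ndarray | None = None,
    config: PipelineConfig | None = None,
):
    """Classify every cell; optionally sweep thresholds against truth labels.

    Returns ``(classified, per_class, sweep_table)`` where ``per_class`` maps
    class id to the masked 38 kHz echogram over 15-250 m and ``sweep_table``
    is None without truth labels.
    """
    config = config or PipelineConfig()
    delta = compute_delta_sv(eset)
    classified = classify_cells(delta, model)
    freq = 38.0 if 38.0 in eset.sv else sorted(eset.sv)[0]
    per_class = per_class_echograms(classified, eset, freq)
    sweep = None
    if truth is not None:
        sweep = sensitivity_sweep(
            delta, truth, model, thresholds=config.sweep_thresholds
        )
    return classified, per_class, sweep


def run_metrics(
    eset: EchogramSet,
    zones: ZoneLabeling | np.ndarray,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-frequency zone x period metrics: total sA, DVM strength, and
    depth-category NASC (DVM only for the 18/38/70 kHz channels)."""
    if isinstance(zones, ZoneLabeling):
        zone_per_ping = zones.zone_of(eset.ping_times)
    else:
        zone_per_ping = np.asarray(zones, dtype=object)
    periods = classify_solar(
        eset.ping_times, eset.positions[:, 0], eset.positions[:, 1]
    )
    totals, categories, dvm_rows = [], [], []
    for f in sorted(eset.sv):
        e = eset.echogram(f)
        totals.append(total_sa(e, periods, zone_per_ping))
        categories.append(depth_category_nasc(e, periods, zone_per_ping))
        if f in DVM_FREQUENCIES_KHZ:
            from .echogrid import sv_to_nasc

            meso = sv_to_nasc(e, MESO_TOP_M, e.depth_edges[-1])
            p = np.array([getattr(x, "value", str(x)) for x in periods])
            for zone in sorted({str(z) for z in zone_per_ping if z is not None}):
                day = meso[(zone_per_ping == zone) & (p == "day")]
                night = meso[(zone_per_ping == zone) & (p == "night")]
                if len(day) and len(night):
                    dvm_rows.append(
                        {
                            "frequency_khz": f,
                            "zone": zone,
                            "dvm_strength": dvm_strength(
                                float(day.mean()), float(night.mean())
                            ),
                        }
                    )
    return {
        "total_sa": pd.concat(totals, ignore_index=True),
        "depth_category_nasc": pd.concat(categories, ignore_index=True),
        "dvm": pd.DataFrame(
            dvm_rows, columns=["frequency_khz", "zone", "dvm_strength"]
        ),
    }
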