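"""End-to-end orchestration: load/simulate → convert → screen → detect →
categorize → (optionally) classify, with a JSON-serializable run report
and the four standard trace visualizations (raw, phasic, peaks + mean,
combined overlay)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import io as trace_io
from .categorize import CategorizeConfig, categorize_trace, summarize_cohort
from .device_model import ConductanceTrace, DeviceParams, RawTrace, convert_trace
from .preprocess import ValidityConfig, phasic_component, validity_flags
from .scr_events import DetectionConfig, detect_events
from .stress_ml import (
    MLConfig,
    evaluate,
    extract_features,
    features_frame,
    kmeans_stress_clusters,
    train_classifier,
)
from .synthetic_data import CohortSpec, simulate_cohort

logger = logging.getLogger("edastress")

__all__ = ["RunConfig", "run_pipeline", "load_run_config", "plot_trace_panels"]


@dataclass
class RunConfig:
    """One reproducible run: either a list of input CSVs or a simulation
    spec, plus the per-stage configurations."""

    input_paths: Optional[List[str]] = None
    simulation: Optional[CohortSpec] = None
    device: DeviceParams = field(default_factory=DeviceParams)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    categorization: CategorizeConfig = field(default_factory=CategorizeConfig)
    ml: Optional[MLConfig] = None
    half_window: float = 4.0
    baseline_method: str = "mean"
    outdir: Optional[str] = None
    seed: int = 0
    make_plots: bool = False
    plot_limit: int = 4

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_paths or simulation")


def load_run_config(source) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a dict of
    flat config keys (CLI flags use the same names)."""
    if not isinstance(source, dict):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    d = dict(source)
    device = DeviceParams(
        supply_voltage=d.get("supply_voltage", 5.0),
        adc_levels=d.get("adc_levels", 1024),
        series_resistance=d.get("series_resistance_kohm", 500.0),
    )
    lo, hi = d.get("valid_range_us", [1.0, 20.0])
    validity = ValidityConfig(
        min_valid=lo,
        max_valid=hi,
        invalid_fraction_threshold=d.get("invalid_fraction_threshold", 0.5),
    )
    detection = DetectionConfig(
        onset_amplitude_criterion=d.get("onset_amplitude_criterion", 0.05),
        er_latency_window=tuple(d.get("er_latency_window", (1.0, 5.0))),
    )
    categorization = CategorizeConfig(
        magnitude_margin=d.get("magnitude_margin", 0.1),
        onset_amplitude_criterion=d.get("onset_amplitude_criterion", 0.05),
    )
    ml = None
    if d.get("ml", False) or "kernel" in d:
        ml = MLConfig(
            kernel=d.get("kernel", "rbf"),
            gamma=d.get("gamma", 2.0),
            nu=d.get("nu"),
            n_folds=d.get("n_folds", 5),
            seed=d.get("seed", 0),
        )
    sim = None
    if "simulation" in d:
        sim = CohortSpec(**d["simulation"])
    return RunConfig(
        input_paths=d.get("inputs"),
        simulation=sim,
        device=device,
        validity=validity,
        detection=detection,
        categorization=categorization,
        ml=ml,
        half_window=d.get("half_window_s", 4.0),
        baseline_method=d.get("baseline_method", "mean"),
        outdir=d.get("outdir"),
        seed=d.get("seed", 0),
        make_plots=d.get("make_plots", False),
    )


def plot_trace_panels(trace, phasic, events, path) -> None:
    """Four-panel figure: raw signal; phasic signal; raw with peak
    markers and the mean line; raw and phasic overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, y = trace.times, trace.conductance
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    (a, b), (c, d) = axes
    a.plot(t, y, color="tab:blue")
    a.set_title("Raw GSR signal")
    b.plot(phasic.times, phasic.phasic, color="tab:orange")
    b.set_title("Phasic GSR signal")
    c.plot(t, y, color="tab:blue")
    mean = float(np.nanmean(y))
    c.axhline(mean, color="tab:green", ls="--", label=f"mean {mean:.2f} µS")
    if events:
        c.plot(
            [e.peak_time for e in events],
            [e.peak_value for e in events],
            "rx",
            ms=10,
            label="peaks",
        )
    c.legend(loc="best", fontsize=8)
    c.set_title("Peaks and mean value")
    d.plot(t, y, color="tab:blue", label="raw")
    d.plot(phasic.times, phasic.phasic, color="tab:orange", label="phasic")
    d.legend(loc="best", fontsize=8)
    d.set_title("Combined")
    for ax in axes.flat:
        ax.set_xlabel("time (s)")
        ax.set_ylabel("conductance (µS)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _event_dict(ev) -> dict:
    d = dataclasses.asdict(ev)
    return {k: v for k, v in d.items() if k not in ("onset_index", "peak_index")}


def _load_inputs(cfg: RunConfig):
    """Yield (trace_id, trace-or-None, truth_label, error) tuples."""
    entries = []
    if cfg.simulation is not None:
        for i, sim in enumerate(simulate_cohort(cfg.simulation)):
            entries.append((f"sim_{i:03d}", sim.trace, sim.label, None))
        return entries
    for path in cfg.input_paths:
        try:
            obj = trace_io.read_trace_csv(path, cfg.device)
        except Exception as exc:  # unreadable input: record, keep going
            logger.error("skipping %s: %s", path, exc)
            entries.append((str(path), None, None, str(exc)))
            continue
        entries.append((Path(path).stem, obj, None, None))
    return entries


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the report dict (also written to
    ``<outdir>/report.json`` when an output directory is set)."""
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    entries = _load_inputs(cfg)
    traces_report, categories, feats, truth_labels = [], [], [], []
    n_plotted = 0
    for trace_id, obj, truth, error in entries:
        if obj is None:
            traces_report.append({"id": trace_id, "error": error})
            continue
        if isinstance(obj, RawTrace):
            trace = convert_trace(obj)
        else:
            trace = obj
        n_flagged = int(trace.flagged.sum())
        validity = validity_flags(trace, cfg.validity)
        phasic = phasic_component(trace, cfg.half_window, cfg.baseline_method)
        events = detect_events(trace, phasic, cfg.detection)
        category = categorize_trace(trace, events, validity, cfg.categorization)
        fv = extract_features(trace, phasic, events)
        categories.append(category)
        feats.append(fv)
        truth_labels.append(truth)
        logger.info(
            "%s: %d samples, %d events, %s", trace_id, len(trace), len(events), category.label
        )
        traces_report.append(
            {
                "id": trace_id,
                "source": trace.source,
                "n_samples": len(trace),
                "n_flagged_samples": n_flagged,
                "validity": {
                    "invalid_fraction": validity.invalid_fraction,
                    "trace_invalid": validity.trace_invalid,
                },
                "n_events": len(events),
                "events": [_event_dict(e) for e in events],
                "category": dataclasses.asdict(category),
                "features": dataclasses.asdict(fv),
                **({"truth_label": truth} if truth is not None else {}),
            }
        )
        if cfg.make_plots and outdir and n_plotted < cfg.plot_limit:
            plot_trace_panels(trace, phasic, events, outdir / f"{trace_id}.png")
            n_plotted += 1

    if not categories:
        raise RuntimeError("empty cohort: no readable traces")
    cohort = summarize_cohort(categories)
    report = {
        "n_inputs": len(entries),
        "traces": traces_report,
        "cohort": dataclasses.asdict(cohort),
    }

    if cfg.ml is not None:
        report["ml"] = _ml_stage(cfg, categories, feats, truth_labels)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def _ml_stage(cfg: RunConfig, categories, feats, truth_labels) -> dict:
    """K-means pseudo-labeling then SVM on the valid traces; scored
    against ground-truth labels when the cohort is simulated."""
    valid_idx = [i for i, c in enumerate(categories) if c.label != "invalid"]
    if len(valid_idx) < 4:
        return {"skipped": "fewer than 4 valid traces"}
    df = features_frame([feats[i] for i in valid_idx])
    X_cluster = df[["peak_amplitude_norm", "phasic_max_norm"]].to_numpy()
    try:
        pseudo, centroids = kmeans_stress_clusters(X_cluster, seed=cfg.ml.seed)
    except ValueError as exc:
        return {"skipped": f"clustering degenerate: {exc}"}
    out = {
        "kmeans": {
            "n_stressed": int(pseudo.sum()),
            "n_relaxed": int((1 - pseudo).sum()),
            "centroids": centroids.tolist(),
        }
    }
    if np.unique(pseudo).size < 2:
        out["skipped"] = "pseudo-labels collapsed to a single class"
        return out
    X_svm = df[["mean_gsr_norm", "amp_minus_mean_norm"]].to_numpy()
    model = train_classifier(X_svm, pseudo, cfg.ml)
    pred = model.predict(X_svm)
    svm_info = {"kernel": cfg.ml.kernel, "nu": cfg.ml.nu}
    if hasattr(model, "best_params_"):
        svm_info["best_params"] = model.best_params_
        svm_info["cv_accuracy"] = float(model.best_score_)
    out["svm"] = svm_info
    truth = [truth_labels[i] for i in valid_idx]
    if all(t is not None for t in truth):
        y_true = np.array([1 if t == "stressed" else 0 for t in truth])
        out["metrics_vs_truth"] = dataclasses.asdict(evaluate(pred, y_true))
    out["metrics_vs_pseudo"] = dataclasses.asdict(evaluate(pred, pseudo))
    return out
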