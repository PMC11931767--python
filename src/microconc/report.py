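"""End-to-end pipeline: assign, concentrate, fit, permute, render.

``run_pipeline`` composes the full analysis on any events/network pair and
writes a report bundle: a study summary, the annual concentration series,
a model table (RR, 95% CI, conventional and Monte Carlo p-values), figures
(annual counts, annual concentration, repeat/non-repeat map) and a single
machine-readable JSON holding every number the rendered outputs show.
Figures and JSON are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection

from .assignment import DEFAULT_SNAP_THRESHOLD, build_case_series
from .cases import CaseSeries
from .concentration import annual_concentration, compute_repeat_indicators, summary_table
from .network import Kind, MicroplaceNetwork
from .permutation import monte_carlo_null
from .trend import RepeatTrendModel

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]


@dataclass
class RunConfig:
    events_path: str
    network_path: str
    out_dir: str
    snap_threshold: float = DEFAULT_SNAP_THRESHOLD
    year_coding: str = "integer"
    span_years: float | None = None  # default: elapsed study years from data
    n_trials: int = 10_000
    seed: int = 0
    null_mode: str = "permute"
    make_figures: bool = True


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _load_network(path: str) -> MicroplaceNetwork:
    if str(path).endswith((".geojson", ".json")):
        return MicroplaceNetwork.from_geojson(path)
    return MicroplaceNetwork.from_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results dict it also writes."""
    for p in (config.events_path, config.network_path):
        if not Path(p).exists():
            raise PipelineStageError("input", f"path does not exist: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    network = _load_network(config.network_path)
    events = pd.read_csv(
        config.events_path, dtype={"event_id": str, "microplace_id": str}
    )

    try:
        series, exclusions = build_case_series(events, network, config.snap_threshold)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineStageError("assignment", str(e)) from e

    try:
        if len(series) == 0:
            raise ValueError("no assignable events; nothing to analyse")
        series = compute_repeat_indicators(series)
        annual = annual_concentration(series)
        summary = summary_table(series, network)
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("concentration", str(e)) from e

    try:
        fit = RepeatTrendModel.from_case_series(series, config.year_coding).fit()
        first, last = series.study_years
        elapsed = (
            (series.data["date"].max() - series.data["date"].min()).days / 365.25
        )
        span = config.span_years if config.span_years is not None else last - first
        baseline = annual.loc[annual["year"] == first, "concentration"].iloc[0]
        mean_annual = len(series) / max(elapsed, 1e-9)
        derived = fit.derive_quantities(span, baseline, mean_annual)
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("trend", str(e)) from e

    try:
        perm = monte_carlo_null(
            series,
            n_trials=config.n_trials,
            seed=config.seed,
            year_coding=config.year_coding,
            null_mode=config.null_mode,
            network=network,
            observed=fit,
        )
    except Exception as e:
        raise PipelineStageError("permutation", str(e)) from e

    results = {
        "config": asdict(config),
        "summary": summary,
        "n_excluded": int(len(exclusions)),
        "annual": annual.to_dict(orient="list"),
        "trend": fit.to_dict(),
        "derived": asdict(derived),
        "permutation": perm.to_dict(),
    }

    # -- write the bundle ------------------------------------------------
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    pd.DataFrame([summary]).to_csv(out / "summary.csv", index=False)
    annual.to_csv(out / "annual.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    with open(out / "model.json", "w") as fh:
        json.dump(
            {"trend": fit.to_dict(), "derived": asdict(derived), "permutation": perm.to_dict()},
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(out / "run.log", "w") as fh:
        fh.write("microconc pipeline run\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config: {json.dumps(asdict(config), sort_keys=True)}\n")
        fh.write(f"events: {len(series)} assigned, {len(exclusions)} excluded\n")
        fh.write(fit.summary() + "\n")

    if config.make_figures:
        _render_figures(out, series, annual, network, config)
    return results


def _render_figures(out, series, annual, network, config):
    plt.rcParams["svg.hashsalt"] = str(config.seed)
    meta = {"Date": None}

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(annual["year"], annual["n_events"], color="#444444")
    ax.set_xlabel("Year")
    ax.set_ylabel("Events")
    ax.set_title("Annual event counts")
    fig.tight_layout()
    fig.savefig(out / "annual_counts.svg", metadata=meta)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(annual["year"], 100 * annual["concentration"], "o-", color="#1f77b4")
    ax.set_xlabel("Year")
    ax.set_ylabel("Spatial concentration (%)")
    ax.set_ylim(0, 100)
    ax.set_title("Share of events at repeat locations, by year")
    fig.tight_layout()
    fig.savefig(out / "annual_concentration.svg", metadata=meta)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 6))
    seg_lines = [
        np.asarray(m.geometry.coords)
        for m in network.microplaces
        if m.kind is Kind.SEGMENT
    ]
    if seg_lines:
        ax.add_collection(
            LineCollection(seg_lines, colors="#cccccc", linewidths=0.4, zorder=1)
        )
    df = series.data
    counts = df["microplace_id"].value_counts()
    for repeat_flag, color, label in ((0, "#1f77b4", "non-repeat"), (1, "#d62728", "repeat")):
        place_ids = sorted(
            counts[(counts >= 2) == bool(repeat_flag)].index.tolist()
        )
        pts = [network[p].geometry.centroid for p in place_ids if p in network]
        if pts:
            ax.scatter(
                [p.x for p in pts],
                [p.y for p in pts],
                s=8,
                c=color,
                label=label,
                zorder=2,
            )
    ax.autoscale()
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("Repeat and non-repeat event locations")
    fig.tight_layout()
    fig.savefig(out / "map.svg", metadata=meta)
    plt.close(fig)
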