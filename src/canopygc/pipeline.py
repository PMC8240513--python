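"""End-to-end diurnal experiment: simulate, estimate, analyse, report.

``run_experiment`` chains the full study: simulate a trial and its 13-event
hourly schedule, render every plot x event sensor bundle, estimate ground
cover by all four methods, fit per-event variance components, and emit the
analysis products — per-event mean +- sd summaries, GC-versus-light pairings,
between-event ICC matrices per method, between-method phenotypic correlation
matrices per event, and the repeatability table. Everything is deterministic
for a fixed master seed, and all outputs are CSV.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import ExperimentConfig
from .correlations import CorrelationMatrix, icc_matrix, phenotypic_corr_matrix
from .errors import StageError
from .estimators import METHODS, build_gc_table
from .reml import GroundCoverVarianceModel, repeatability
from .schedule import SamplingEvent, make_event_schedule, schedule_frame
from .sensors import render_bundle
from .trial import GroundTruth, TrialDesign, simulate_trial

log = logging.getLogger("canopygc")


@dataclass
class ExperimentReport:
    """All analysis products of one experiment run."""

    design: TrialDesign
    truth: GroundTruth | None
    schedule: list[SamplingEvent]
    gc_table: pd.DataFrame
    event_summary: pd.DataFrame
    gc_vs_light_table: pd.DataFrame
    variance_components: pd.DataFrame
    repeatability_table: pd.DataFrame     # events x methods, wide
    blups: pd.DataFrame
    icc: dict[str, CorrelationMatrix]
    phenotypic: dict[int, CorrelationMatrix]
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Write every product as CSV plus a provenance JSON and summary text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.8g"
        self.gc_table.to_csv(out / "gc_table.csv", index=False, float_format=fmt)
        schedule_frame(self.schedule).to_csv(out / "schedule.csv", index=False)
        self.event_summary.to_csv(out / "event_summary.csv", index=False,
                                  float_format=fmt)
        self.gc_vs_light_table.to_csv(out / "gc_vs_light.csv", index=False,
                                      float_format=fmt)
        self.variance_components.to_csv(out / "variance_components.csv",
                                        index=False, float_format=fmt)
        self.repeatability_table.to_csv(out / "repeatability.csv",
                                        float_format=fmt)
        self.blups.to_csv(out / "blups.csv", index=False, float_format=fmt)
        for method, mat in self.icc.items():
            mat.r.to_csv(out / f"icc_{method}_r.csv", float_format=fmt)
            mat.stars.to_csv(out / f"icc_{method}_stars.csv")
        for event_id, mat in self.phenotypic.items():
            mat.r.to_csv(out / f"phenotypic_event{event_id}_r.csv",
                         float_format=fmt)
            mat.stars.to_csv(out / f"phenotypic_event{event_id}_stars.csv")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary())

    def summary(self) -> str:
        lines = [
            "Diurnal ground-cover experiment",
            f"plots: {self.design.n_plots}  genotypes: {self.design.n_genotypes}"
            f"  mean replication: {self.design.nrep:.3f}",
            f"events: {len(self.schedule)}  methods: {', '.join(METHODS)}",
            "",
            "Mean repeatability by method:",
        ]
        for m in METHODS:
            col = self.repeatability_table[m].astype(float)
            lines.append(f"  {m:<12} {np.nanmean(col):.3f}")
        lines.append("")
        lines.append("Mean between-event ICC by method:")
        for m in METHODS:
            lines.append(f"  {m:<12} {self.icc[m].mean_offdiagonal():.3f}")
        return "\n".join(lines) + "\n"


# -- stages ------------------------------------------------------------------

def simulate_bundles(config: ExperimentConfig, master_seed: int):
    """Simulate trial + schedule and render every plot x event bundle."""
    design, truth = simulate_trial(config.trial, master_seed)
    schedule = make_event_schedule(config.schedule)
    bundles = []
    for event in schedule:
        for plot in design.plots["plot"]:
            bundles.append(
                render_bundle(
                    int(plot), event, design, truth, config.sensors,
                    master_seed, schedule,
                )
            )
        log.info("simulate: event %s rendered (%d plots)",
                 event.clock_label, design.n_plots)
    return design, truth, schedule, bundles


def simulate_gc_table(config: ExperimentConfig, master_seed: int):
    """Simulate and estimate in one pass, event by event (memory-friendly).

    Returns (design, truth, schedule, gc_table).
    """
    design, truth = simulate_trial(config.trial, master_seed)
    schedule = make_event_schedule(config.schedule)
    parts = []
    for event in schedule:
        bundles = [
            render_bundle(int(p), event, design, truth, config.sensors,
                          master_seed, schedule)
            for p in design.plots["plot"]
        ]
        parts.append(build_gc_table(bundles, design, config.estimator))
    table = pd.concat(parts, ignore_index=True)
    return design, truth, schedule, table


def summarize_events(table: pd.DataFrame) -> pd.DataFrame:
    """Per (event, method): mean, sample sd, n and missing count over plots."""
    if table.empty:
        raise ValueError("empty GC table")
    g = table.groupby(["event_id", "method"])["value"]
    out = g.agg(
        mean="mean",
        sd=lambda v: v.std(ddof=1),
        n_plots="count",
        n_missing=lambda v: int(v.isna().sum()),
    ).reset_index()
    return out.sort_values(["event_id", "method"]).reset_index(drop=True)


def gc_vs_light(table: pd.DataFrame, schedule: list[SamplingEvent]) -> pd.DataFrame:
    """Join per-event method means to the event's solar radiation."""
    summary = summarize_events(table)
    sched = schedule_frame(schedule)
    missing = set(summary["event_id"]) - set(sched["event_id"])
    if missing:
        raise StageError("gc_vs_light",
                         f"events missing from schedule: {sorted(missing)}")
    out = summary.merge(
        sched[["event_id", "clock_label", "solar_radiation"]],
        on="event_id", how="inner",
    )
    cols = ["event_id", "clock_label", "solar_radiation", "method", "mean", "sd"]
    return out[cols].sort_values(["event_id", "method"]).reset_index(drop=True)


def fit_all_events(table: pd.DataFrame, design: TrialDesign):
    """REML fit per (event, method): variance components, rho, BLUPs.

    Returns (variance_components long frame, repeatability wide frame,
    blups long frame, results dict keyed by (event_id, method)).
    """
    vc_rows, blup_rows, results = [], [], {}
    events = sorted(table["event_id"].unique())
    for ev in events:
        for m in METHODS:
            sub = table[(table["event_id"] == ev) & (table["method"] == m)]
            sub = sub.dropna(subset=["value"])
            if sub.empty or sub["value"].nunique() < 2:
                vc_rows.append({"event_id": ev, "method": m, "sigma2_g": np.nan,
                                "sigma2_row": np.nan, "sigma2_col": np.nan,
                                "sigma2_eps": np.nan, "nrep": design.nrep,
                                "rho": np.nan})
                continue
            model = GroundCoverVarianceModel.from_dataframe(sub, design)
            res = model.fit()
            results[(ev, m)] = res
            vc_rows.append({
                "event_id": ev, "method": m,
                "sigma2_g": res.sigma2_g, "sigma2_row": res.sigma2_row,
                "sigma2_col": res.sigma2_col, "sigma2_eps": res.sigma2_eps,
                "nrep": res.nrep, "rho": repeatability(res),
            })
            for geno, mean in res.genotype_means().items():
                blup_rows.append({"event_id": ev, "method": m,
                                  "genotype": geno, "genotype_mean": mean})
        log.info("stats: event %s fitted", ev)
    vc = pd.DataFrame(vc_rows)
    rho_wide = vc.pivot(index="event_id", columns="method", values="rho")
    rho_wide = rho_wide.reindex(columns=list(METHODS))
    blups = pd.DataFrame(blup_rows,
                         columns=["event_id", "method", "genotype",
                                  "genotype_mean"])
    return vc, rho_wide, blups, results


def run_experiment(
    config: ExperimentConfig | None = None,
    master_seed: int | None = None,
    out_dir=None,
) -> ExperimentReport:
    """Run the full simulate -> estimate -> analyse chain.

    When ``out_dir`` is given, all CSV products are written there; on any
    stage failure partial outputs are removed and a stage-named error raised.
    """
    config = config or ExperimentConfig()
    config.validate()
    if master_seed is None:
        master_seed = config.master_seed
    if master_seed is None:
        raise StageError("setup", "a master seed is required")

    stage = "simulate+estimate"
    try:
        t0 = time.time()
        design, truth, schedule, table = simulate_gc_table(config, master_seed)
        log.info("%s: %d rows in %.1fs", stage, len(table), time.time() - t0)

        stage = "summaries"
        summary = summarize_events(table)
        light = gc_vs_light(table, schedule)

        stage = "stats"
        t0 = time.time()
        vc, rho_wide, blups, results = fit_all_events(table, design)
        log.info("stats: %d fits in %.1fs", len(results), time.time() - t0)

        stage = "correlations"
        icc = {m: icc_matrix(table, m) for m in METHODS}
        phenotypic = {}
        for ev in sorted(table["event_id"].unique()):
            means = {m: results[(ev, m)].genotype_means()
                     for m in METHODS if (ev, m) in results}
            if len(means) >= 2:
                phenotypic[int(ev)] = phenotypic_corr_matrix(means)

        report = ExperimentReport(
            design=design, truth=truth, schedule=schedule, gc_table=table,
            event_summary=summary, gc_vs_light_table=light,
            variance_components=vc, repeatability_table=rho_wide,
            blups=blups, icc=icc, phenotypic=phenotypic,
            provenance={
                "master_seed": int(master_seed),
                "config": config.to_dict(),
                "package_version": _pkg_version,
            },
        )
        if out_dir is not None:
            stage = "write"
            report.write(out_dir)
        return report
    except Exception as exc:
        if out_dir is not None and Path(out_dir).exists():
            shutil.rmtree(out_dir, ignore_errors=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
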