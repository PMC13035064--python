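"""End-to-end orchestration: simulate -> metrics -> score -> enrich.

Each stage is logged; outputs (per-group summaries, compound z-score table,
hit list, enrichment table) are written as TSV together with a manifest
recording the package version, seed, config, and SHA-256 hashes of every
primary output.  Two runs with the same (config, seed) produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .metrics import group_summary, summarize_cohort
from .schedule import build_schedule
from .screen import (
    CompoundResult,
    call_hits,
    control_distribution,
    enrich_targets,
    score_compounds,
)
from .simulate import make_library, simulate_screen_day

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def _group_metric_means(
    tables: dict[str, pd.DataFrame], schedule
) -> pd.DataFrame:
    """Per-group means of every behavioral metric (one row per group/metric)."""
    records = []
    for group, events in tables.items():
        summaries = summarize_cohort(events, schedule)
        stats = group_summary(summaries)
        stats.insert(0, "group", group)
        records.append(stats)
    return pd.concat(records, ignore_index=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the full screen pipeline and write its artifact bundle.

    Returns a dict with the in-memory results: per-group metric table,
    compound z-score table, hit lists per readout, enrichment tables and
    the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = _stage("schedule")(build_schedule, config.assay)

    logger.info("stage simulate: %d days x %d compounds", config.n_days, config.compounds_per_day)
    root = np.random.SeedSequence(config.seed)
    day_seeds = [int(s.generate_state(1)[0]) for s in root.spawn(config.n_days)]

    treated_tables: dict[str, pd.DataFrame] = {}
    control_tables: dict[str, pd.DataFrame] = {}
    doses: dict[str, float] = {}
    n_total = config.n_days * config.compounds_per_day
    all_ids = [f"C{i + 1:04d}" for i in range(n_total)]
    for d in range(config.n_days):
        day_id = f"day{d + 1}"
        ids = all_ids[d * config.compounds_per_day : (d + 1) * config.compounds_per_day]
        treated, controls = _stage("simulate")(
            simulate_screen_day,
            config.compounds_per_day,
            config.group_size,
            config.behavior,
            day_seeds[d],
            schedule=schedule,
            day_id=day_id,
            compound_ids=ids,
            dose_um=config.dose_um,
        )
        for cid, table in treated.items():
            treated_tables[cid] = table
            doses[cid] = config.dose_um
        for j, table in enumerate(controls):
            control_tables[f"{day_id}:ctrl{j + 1}"] = table

    logger.info("stage metrics: summarizing %d treated + %d control groups",
                len(treated_tables), len(control_tables))
    treated_metrics = _stage("metrics")(_group_metric_means, treated_tables, schedule)
    control_metrics = _stage("metrics")(_group_metric_means, control_tables, schedule)

    logger.info("stage score: readouts %s", ", ".join(config.readouts))
    results: list[CompoundResult] = []
    hits_by_readout: dict[str, list[str]] = {}
    for readout in config.readouts:
        ctrl = control_metrics[control_metrics["metric"] == readout]
        control = _stage("score")(
            control_distribution, ctrl["mean"].tolist(), readout
        )
        treated_means = {
            row["group"]: row["mean"]
            for _, row in treated_metrics[treated_metrics["metric"] == readout].iterrows()
            if np.isfinite(row["mean"])
        }
        readout_results = score_compounds(treated_means, control, doses)
        hits = call_hits(readout_results, readout, config.hit_direction, config.alpha)
        hits_by_readout[readout] = [h.compound_id for h in hits]
        results.extend(readout_results)

    logger.info("stage enrich: %d compounds", n_total)
    library = _stage("enrich")(make_library, n_total, config.class_sizes, config.seed)
    enrichment = {
        readout: _stage("enrich")(
            enrich_targets, hits, library, config.enrichment_alpha
        )
        for readout, hits in hits_by_readout.items()
    }

    # ----------------------------------------------------------- artifacts
    ztable = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "readout": [r.readout for r in results],
            "dose_um": [r.dose_um for r in results],
            "treated_mean": [r.treated_mean for r in results],
            "z": [r.z for r in results],
        }
    )
    hit_rows = [
        {"readout": readout, "compound_id": cid}
        for readout, cids in hits_by_readout.items()
        for cid in cids
    ]
    hit_table = pd.DataFrame(hit_rows, columns=["readout", "compound_id"])
    enrich_rows = [
        {
            "readout": readout,
            "target_class": r.target_class,
            "hits_in_class": r.hits_in_class,
            "hits_out": r.hits_out,
            "nonhits_in_class": r.nonhits_in_class,
            "nonhits_out": r.nonhits_out,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for readout, rs in enrichment.items()
        for r in rs
    ]
    enrich_table = pd.DataFrame(
        enrich_rows,
        columns=[
            "readout",
            "target_class",
            "hits_in_class",
            "hits_out",
            "nonhits_in_class",
            "nonhits_out",
            "p_value",
            "significant",
        ],
    )

    paths = {
        "treated_metrics": outdir / "treated_metrics.tsv",
        "control_metrics": outdir / "control_metrics.tsv",
        "zscores": outdir / "zscores.tsv",
        "hits": outdir / "hits.tsv",
        "enrichment": outdir / "enrichment.tsv",
        "library": outdir / "library.tsv",
    }
    treated_metrics.to_csv(paths["treated_metrics"], sep="\t", index=False)
    control_metrics.to_csv(paths["control_metrics"], sep="\t", index=False)
    ztable.to_csv(paths["zscores"], sep="\t", index=False)
    hit_table.to_csv(paths["hits"], sep="\t", index=False)
    enrich_table.to_csv(paths["enrichment"], sep="\t", index=False)
    library.to_csv(paths["library"], sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {name: _sha256(p) for name, p in paths.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "schedule": schedule,
        "treated_metrics": treated_metrics,
        "control_metrics": control_metrics,
        "zscores": ztable,
        "hits": hits_by_readout,
        "enrichment": enrichment,
        "library": library,
        "manifest": manifest,
    }
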