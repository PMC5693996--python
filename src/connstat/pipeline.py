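"""End-to-end orchestration: cohort -> networks -> NBS -> hubs -> metrics
-> associations -> report, behind a single seeded configuration.

The global seed is expanded into per-stage substreams by stable hashing
of the stage name, so adding a stage never shifts the random stream of an
earlier one.  Reports are JSON plus flat TSV tables and round-trip
through :func:`read_report`; re-running an identical config reproduces
identical output up to the provenance timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import associate_edges, associate_metrics, write_association_tsv
from .cohort import CohortDataset, read_manifest
from .nbs import NBSResults, nbs_test
from .network import build_network, read_adjacency_tsv, read_timeseries_tsv
from .simulate import CohortSpec, PlantedEffect, fronto_thalamic_subnetwork
from .simulate import generate_clinical_scores, generate_edge_cohort
from .simulate import generate_timeseries_cohort, write_cohort
from .topology import compute_all, write_metrics_tsv

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_CONTRASTS = (("SI", "noSI"), ("MDD_all", "HC"))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    simulation: CohortSpec | None = None
    sim_mode: str = "edges"                   # or "timeseries"
    manifest: str | None = None               # ingestion mode
    data_dir: str | None = None
    data_format: str = "adjacency"            # or "timeseries"
    contrasts: tuple = DEFAULT_CONTRASTS
    threshold: float = 4.20
    n_perm: int = 10_000
    alpha: float = 0.05
    tail: str = "greater"
    fdr_q: float = 0.05
    seed: int = 0
    output_dir: str = "connstat_out"
    write_subject_data: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.simulation is None and self.manifest is None:
            raise ValueError("config needs either a simulation spec or a "
                             "manifest path")
        self.contrasts = tuple(tuple(c) for c in self.contrasts)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        spec = None
        if sim is not None:
            planted = sim.pop("planted", None)
            if planted == "fronto_thalamic":
                sim["planted"] = fronto_thalamic_subnetwork()
            elif planted:
                sim["planted"] = tuple(
                    PlantedEffect(tuple(p["edge"]), p["mean_group_a"],
                                  p["mean_group_b"], p.get("mean_controls"))
                    for p in planted
                )
            spec = CohortSpec(**sim)
        return cls(simulation=spec, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["planted"] = [
                {"edge": list(e.edge), "mean_group_a": e.mean_group_a,
                 "mean_group_b": e.mean_group_b,
                 "mean_controls": e.mean_controls}
                for e in self.simulation.planted
            ]
            out["simulation"] = sim
        out["contrasts"] = [list(c) for c in self.contrasts]
        return out


def load_cohort(manifest_path: str | Path, data_dir: str | Path | None = None,
                data_format: str = "adjacency") -> CohortDataset:
    """Read a cohort from a manifest CSV plus per-subject TSV files
    (``<subject_id>.tsv`` under ``data_dir``, default ``subjects/`` next
    to the manifest)."""
    manifest = read_manifest(manifest_path)
    data_dir = Path(data_dir or Path(manifest_path).parent / "subjects")
    if data_format == "adjacency":
        nets = [read_adjacency_tsv(data_dir / f"{sid}.tsv", subject_id=sid)
                for sid in manifest.index]
        return CohortDataset(manifest, networks=nets)
    if data_format != "timeseries":
        raise ValueError(f"unknown data format {data_format!r}")
    series = [read_timeseries_tsv(data_dir / f"{sid}.tsv", subject_id=sid)
              for sid in manifest.index]
    return CohortDataset(manifest, timeseries=series)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs under the
    configured output directory.  Returns the report dictionary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "config": config.to_dict(),
            "seed": config.seed,
            "software": f"connstat {__version__}",
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "contrasts": [],
        "associations": {},
    }
    stage = "setup"
    try:
        # -- cohort ---------------------------------------------------------
        stage = "simulate" if config.simulation is not None else "ingest"
        t0 = time.perf_counter()
        if config.simulation is not None:
            spec = dataclasses.replace(
                config.simulation, seed=stage_seed(config.seed, "simulate"))
            if config.sim_mode == "edges":
                cohort = generate_edge_cohort(spec)
            else:
                cohort = generate_timeseries_cohort(spec)
        else:
            spec = None
            cohort = load_cohort(config.manifest, config.data_dir,
                                 config.data_format)
        logger.info("stage %s: %d subjects (%.2fs)", stage,
                    cohort.n_subjects, time.perf_counter() - t0)

        # -- networks -------------------------------------------------------
        stage = "networks"
        t0 = time.perf_counter()
        if cohort.networks is None:
            cohort = cohort.with_networks(
                [build_network(ts) for ts in cohort.timeseries])
        if spec is not None:
            cohort = generate_clinical_scores(cohort, spec)
            if config.write_subject_data:
                write_cohort(cohort, outdir / "cohort", spec=spec)
        logger.info("stage networks: %d regions (%.2fs)",
                    cohort.n_regions, time.perf_counter() - t0)

        # -- NBS contrasts --------------------------------------------------
        results: list[NBSResults] = []
        for group_a, group_b in config.contrasts:
            stage = f"nbs:{group_a}_vs_{group_b}"
            t0 = time.perf_counter()
            res = nbs_test(
                cohort, group_a, group_b, threshold=config.threshold,
                n_perm=config.n_perm, alpha=config.alpha,
                seed=stage_seed(config.seed, stage), tail=config.tail,
            )
            results.append(res)
            entry = res.to_dict()
            entry["hubs"] = (sorted(res.hubs(0))
                             if res.significant_components else [])
            report["contrasts"].append(entry)
            res.edge_table().to_csv(
                outdir / f"subnetwork_{group_a}_vs_{group_b}.tsv",
                sep="\t", index=False, float_format="%.6g")
            logger.info("stage %s: %d components, %d significant (%.2fs)",
                        stage, len(res.components),
                        len(res.significant_components),
                        time.perf_counter() - t0)

        # -- hub metrics and associations (patient contrast) ----------------
        for (group_a, group_b), res in zip(config.contrasts, results):
            if {group_a, group_b} != {"SI", "noSI"}:
                continue
            if not res.significant_components:
                continue
            comp = res.significant_components[0]
            hubs = res.hubs(0)

            stage = "metrics"
            t0 = time.perf_counter()
            metrics = compute_all(cohort, regions=hubs or None)
            write_metrics_tsv(metrics, outdir / "metrics.tsv")
            logger.info("stage metrics: %d rows (%.2fs)", len(metrics),
                        time.perf_counter() - t0)

            stage = "associations"
            t0 = time.perf_counter()
            edge_assoc = associate_edges(cohort, comp)
            write_association_tsv(edge_assoc,
                                  outdir / "associations_edges.tsv")
            report["associations"]["edges"] = edge_assoc.to_dict("records")
            if hubs:
                metric_assoc = associate_metrics(cohort, hubs, metrics)
                write_association_tsv(metric_assoc,
                                      outdir / "associations_metrics.tsv")
                report["associations"]["hub_metrics"] = (
                    metric_assoc.to_dict("records"))
            logger.info("stage associations done (%.2fs)",
                        time.perf_counter() - t0)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_report(report, outdir)
    return report


def write_report(report: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True,
                               default=float))
    return path


def read_report(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "report.json").read_text())
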