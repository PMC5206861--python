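"""End-to-end orchestration: simulate/load -> normalize -> call -> set ops
-> network -> enrichment -> report.

A :class:`RunConfig` (YAML/JSON-loadable) names the inputs (or a simulate
block), the comparisons, and the thresholds; :func:`run_pipeline` executes
every stage, writes each stage's outputs under the output directory with
stable filenames, and finishes with a machine-readable ``report.json``.
Re-running an identical config and seed reproduces identical analytical
outputs.  Any stage failure aborts with a stage-named error and leaves an
``INCOMPLETE`` marker file.

The two-threshold design mirrors standard qPCR-array practice: a calling
tier (default fold change >= 3) defines the differential sets, and a "top"
tier (default >= 5) selects the strongly modulated miRNAs that seed the
regulatory network.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .enrich import GeneSetCollection, hypergeom_enrich, read_gmt, \
    write_enrichment_tsv
from .network import TargetEdgeTable, annotate_nodes, build_bipartite, \
    consensus_targets, export_network, filter_min_targeting, network_summary
from .qpcr import CtTable, ComparisonProfile, call_differential, \
    common_detected_features, group_fold_change
from .setops import inverse_regulated, venn

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` holds keyword arguments for
    :class:`~mirnet.synthetic.SynthConfig` (seed injected from ``seed``),
    or ``ct_csv``/``groups_csv``/``reference`` point at input files.
    ``comparisons`` maps comparison id -> (numerator group, denominator
    group); the first comparison is treated as the injury profile and the
    second (when present) as the treatment profile for inverse-regulation
    detection and network seeding.
    """

    outdir: str
    seed: int = 0
    simulate: dict[str, Any] | None = None
    ct_csv: str | None = None
    groups_csv: str | None = None
    reference: str | None = None
    edge_tsvs: list[str] = field(default_factory=list)
    gmt: str | None = None
    comparisons: dict[str, list[str]] = field(
        default_factory=lambda: {"Cis_vs_Saline": ["cisplatin", "saline"],
                                 "CisMSC_vs_Cis": ["cisplatin_MSC",
                                                   "cisplatin"]})
    call_fc: float = 3.0
    top_fc: float = 5.0
    min_targeting: int = 2
    min_databases: int | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.call_fc < 1 or self.top_fc < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.simulate is None and not (self.ct_csv and self.groups_csv
                                          and self.reference):
            raise ValueError(
                "either a simulate block or ct_csv/groups_csv/reference "
                "inputs are required")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (or JSON, a YAML subset)."""
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


def _stage(name: str, outdir: Path):
    """Context manager: logs timing; on failure writes the marker file."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "INCOMPLETE").write_text(
                    f"pipeline aborted in stage {name!r}: {exc}\n")
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name,
                        time.perf_counter() - self.t0)
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run report (also written
    as ``report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    if marker.exists():
        marker.unlink()

    report: dict[str, Any] = {
        "tool": "mirnet",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    truth = None
    annotation: GeneSetCollection | None = None
    edge_tables: list[TargetEdgeTable] = []

    with _stage("input", outdir):
        if config.simulate is not None:
            from .synthetic import PlantedEffect, SynthConfig, \
                generate_annotation, generate_ct_table, \
                generate_prediction_tables
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            effects = sim_kwargs.get("planted_effects", ())
            sim_kwargs["planted_effects"] = tuple(
                e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
                for e in effects)
            if "groups" in sim_kwargs:
                sim_kwargs["groups"] = tuple(
                    (g, int(n)) for g, n in sim_kwargs["groups"])
            if "comparisons" not in sim_kwargs:
                sim_kwargs["comparisons"] = {
                    cid: (num, den)
                    for cid, (num, den) in config.comparisons.items()}
            synth = SynthConfig(**sim_kwargs)
            ct, truth = generate_ct_table(synth)
            edge_tables = generate_prediction_tables(synth, truth)
            annotation = generate_annotation(synth, truth)
            ct.write_csv(outdir / "ct_table.csv", outdir / "groups.csv")
            for db, table in zip([t.records["db"].iloc[0] if len(t.records)
                                  else "empty" for t in edge_tables],
                                 edge_tables):
                table.write_tsv(outdir / f"targets_{db}.tsv")
            annotation.write_gmt(outdir / "annotation.gmt")
        else:
            ct = CtTable.read_csv(config.ct_csv, config.groups_csv,
                                  reference=config.reference)
            edge_tables = [TargetEdgeTable.read_tsv(p)
                           for p in config.edge_tsvs]
            if config.gmt:
                annotation = read_gmt(config.gmt)
        report["n_panel_features"] = len(ct.features)
        report["n_common_detected"] = len(common_detected_features(ct))

    profiles: dict[str, ComparisonProfile] = {}
    top_profiles: dict[str, ComparisonProfile] = {}
    with _stage("call", outdir):
        report["comparisons"] = {}
        for cid, (num, den) in config.comparisons.items():
            fc = group_fold_change(ct, num, den)
            prof = call_differential(fc, config.call_fc, comparison_id=cid,
                                     numerator=num, denominator=den)
            top = call_differential(fc, config.top_fc,
                                    comparison_id=f"{cid}_top",
                                    numerator=num, denominator=den)
            profiles[cid] = prof
            top_profiles[cid] = top
            prof.write_tsv(outdir / f"profile_{cid}.tsv")
            (outdir / f"profile_{cid}.json").write_text(
                json.dumps(prof.to_dict(), indent=2) + "\n")
            report["comparisons"][cid] = prof.to_dict()
            report["comparisons"][cid]["top"] = top.to_dict()

    with _stage("setops", outdir):
        called_sets = {cid: set(p.called) for cid, p in profiles.items()}
        if len(called_sets) >= 2:
            venn_result = venn(called_sets)
            (outdir / "venn.json").write_text(
                json.dumps(venn_result.to_dict(), indent=2) + "\n")
            report["venn"] = venn_result.to_dict()["counts"]
            cids = list(profiles)
            inv = inverse_regulated(profiles[cids[0]], profiles[cids[1]])
            (outdir / "inverse.json").write_text(
                json.dumps(inv.to_dict(), indent=2) + "\n")
            report["inverse"] = inv.to_dict()
        else:
            report["venn"] = None
            report["inverse"] = None

    with _stage("network", outdir):
        # network seeded by the top tier of the treatment comparison when
        # present, else of the single comparison
        seed_cid = list(profiles)[1] if len(profiles) > 1 else \
            list(profiles)[0]
        directions = top_profiles[seed_cid].directions()
        if directions and edge_tables:
            net = build_bipartite(edge_tables, directions)
            net = filter_min_targeting(net, config.min_targeting)
            if annotation is not None:
                flag_map = {name: name for name in annotation.sets}
                net = annotate_nodes(net, annotation.sets, flag_map)
            export_network(net, outdir / "network.sif")
            export_network(net, outdir / "network.graphml")
            report["network"] = network_summary(net)
            report["network"]["seed_comparison"] = seed_cid
            consensus = {
                m: sorted(consensus_targets(edge_tables, m,
                                            config.min_databases))
                for m in sorted(directions)
            }
            (outdir / "consensus_targets.json").write_text(
                json.dumps(consensus, indent=2) + "\n")
            report["consensus_targets"] = consensus
        else:
            report["network"] = None
            report["consensus_targets"] = {}

    with _stage("enrichment", outdir):
        if annotation is not None and report.get("network"):
            universe = set(
                TargetEdgeTable.concat(edge_tables).records["gene"])
            query = set().union(
                *(set(v) for v in report["consensus_targets"].values()),
            ) if report["consensus_targets"] else set()
            result = hypergeom_enrich(query, annotation, universe=universe)
            write_enrichment_tsv(result, outdir / "enrichment.tsv")
            report["enrichment"] = {
                "path": "enrichment.tsv",
                "n_sets": int(len(result)),
                "n_significant": int((result["q"] <= config.alpha).sum()),
                "alpha": config.alpha,
            }
        else:
            report["enrichment"] = None

    with _stage("report", outdir):
        if truth is not None:
            report["planted_truth"] = {
                cid: {"up": sorted(r["up"]), "down": sorted(r["down"])}
                for cid, r in truth.regulation.items()}
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
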