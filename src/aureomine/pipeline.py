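"""End-to-end orchestration: simulate -> mine -> network/cluster ->
properties/statistics -> tree -> BGC -> report.

A run is driven by one validated configuration (YAML, versioned schema,
unknown keys rejected) and a single RNG seed; identical configuration
plus seed yields byte-identical outputs.  Every intermediate table is
serialized into the output directory, and the report records
per-stage counts plus a provenance block (config hash, seed, version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .bgc import classify_gene_role, find_bgcs, tabulate_bgcs, write_synteny_svg
from .cluster_network import (
    build_ssn,
    greedy_cluster,
    identity_matrix,
    write_clusters,
    write_edge_list,
    write_node_attributes,
)
from .hmm import iterative_search, write_hits_tsv
from .phylo import distances_from_identity, neighbor_joining, root_at_outgroup
from .props import properties_table, property_group_test
from .seqio import (
    read_alignment_fasta,
    read_fasta,
    read_features,
    read_taxonomy,
    write_fasta,
    write_newick,
)
from .synthetic import SimConfig, generate_dataset, write_dataset

logger = logging.getLogger("aureomine.pipeline")

SCHEMA = "aureomine-pipeline/1"

_THRESHOLD_BOUNDS = {
    "e_value": (0.0, 1.0),
    "max_len": (1, 100000),
    "ssn_edge": (0.0, 100.0),
    "cluster_id": (0.0, 1.0),
    "window": (0, 10_000_000),
}

_TOP_KEYS = {
    "schema",
    "rng_seed",
    "outdir",
    "synthetic",
    "inputs",
    "thresholds",
    "calibration_n",
    "outgroup_id",
}
_SYNTH_KEYS = {
    "n_families",
    "family_distances",
    "members_per_family",
    "n_decoys",
    "decoy_length_range",
    "operon_layouts",
}
_INPUT_KEYS = {"seed_msa", "db", "features", "taxonomy", "contigs"}


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    rng_seed: int = 0
    outdir: str = "aureomine_out"
    synthetic: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    e_value: float = 1e-5
    max_len: int = 100
    ssn_edge: float = 64.29
    cluster_id: float = 0.90
    window: int = 5000
    calibration_n: int = 1000
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            self.synthetic = {}
        for name in _THRESHOLD_BOUNDS:
            lo, hi = _THRESHOLD_BOUNDS[name]
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise PipelineError(f"threshold {name}={val} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if raw.get("schema", SCHEMA) != SCHEMA:
            raise PipelineError(f"unsupported config schema {raw.get('schema')!r}")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        synth = raw.get("synthetic")
        if synth is not None:
            bad = set(synth) - _SYNTH_KEYS
            if bad:
                raise PipelineError(f"unknown synthetic keys: {sorted(bad)}")
        inputs = raw.get("inputs")
        if inputs is not None:
            bad = set(inputs) - _INPUT_KEYS
            if bad:
                raise PipelineError(f"unknown input keys: {sorted(bad)}")
        thresholds = raw.get("thresholds") or {}
        bad = set(thresholds) - set(_THRESHOLD_BOUNDS)
        if bad:
            raise PipelineError(f"unknown threshold keys: {sorted(bad)}")
        return cls(
            rng_seed=int(raw.get("rng_seed", 0)),
            outdir=str(raw.get("outdir", "aureomine_out")),
            synthetic=synth,
            inputs=inputs,
            e_value=float(thresholds.get("e_value", 1e-5)),
            max_len=int(thresholds.get("max_len", 100)),
            ssn_edge=float(thresholds.get("ssn_edge", 64.29)),
            cluster_id=float(thresholds.get("cluster_id", 0.90)),
            window=int(thresholds.get("window", 5000)),
            calibration_n=int(raw.get("calibration_n", 1000)),
            outgroup_id=raw.get("outgroup_id"),
        )

    def canonical(self) -> dict[str, Any]:
        return {
            "schema": SCHEMA,
            "rng_seed": self.rng_seed,
            "synthetic": self.synthetic,
            "inputs": self.inputs,
            "thresholds": {
                "e_value": self.e_value,
                "max_len": self.max_len,
                "ssn_edge": self.ssn_edge,
                "cluster_id": self.cluster_id,
                "window": self.window,
            },
            "calibration_n": self.calibration_n,
            "outgroup_id": self.outgroup_id,
        }

    def digest(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    counts: dict[str, int]
    files: dict[str, str]
    notes: list[str]
    provenance: dict[str, Any]

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "files": self.files,
            "notes": self.notes,
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order; see the module docstring.

    Stage failures raise :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    counts: dict[str, int] = {}
    files: dict[str, str] = {}
    notes: list[str] = []
    t0 = time.monotonic()
    try:
        # -- stage: inputs ------------------------------------------------
        stage = "inputs"
        if config.inputs is not None:
            seed_msa = read_alignment_fasta(config.inputs["seed_msa"])
            db = read_fasta(config.inputs["db"])
            features = (
                read_features(config.inputs["features"])
                if "features" in config.inputs
                else []
            )
            taxonomy = (
                {
                    row.sequence_or_assembly_id: row
                    for row in read_taxonomy(config.inputs["taxonomy"])
                }
                if "taxonomy" in config.inputs
                else {}
            )
            contig_lengths: dict[str, int] = {}
            if "contigs" in config.inputs:
                with open(config.inputs["contigs"]) as fh:
                    next(fh)
                    for line in fh:
                        cols = line.rstrip("\n").split("\t")
                        contig_lengths[cols[0]] = int(cols[1])
        else:
            stage = "simulate"
            sim = SimConfig(rng_seed=config.rng_seed, **(config.synthetic or {}))
            dataset = generate_dataset(sim)
            paths = write_dataset(dataset, outdir / "synthetic")
            files.update({f"synthetic_{k}": str(v) for k, v in paths.items()})
            seed_msa = dataset.seed_msa
            db = dataset.records
            features = [f for c in dataset.contigs for f in c.features]
            contig_lengths = {c.contig_id: c.length for c in dataset.contigs}
            taxonomy = dict(dataset.truth.taxonomy)
            counts["planted"] = len(dataset.truth.planted)
            counts["decoys"] = len(dataset.truth.decoy_ids)
        counts["db_records"] = len(db)
        logger.info("stage %s done (%d db records)", stage, len(db))

        # -- stage: mine --------------------------------------------------
        stage = "mine"
        hits = iterative_search(
            seed_msa,
            db,
            e_threshold=config.e_value,
            max_len=config.max_len,
            calibration_n=config.calibration_n,
            rng=np.random.default_rng(config.rng_seed),
        )
        counts["hits"] = len(hits)
        write_hits_tsv(hits, outdir / "hits.tsv")
        files["hits"] = str(outdir / "hits.tsv")
        by_id = {rec.id: rec for rec in db}
        hit_records = [by_id[h.sequence_id] for h in hits]
        write_fasta(hit_records, outdir / "hit_peptides.fasta")
        files["hit_peptides"] = str(outdir / "hit_peptides.fasta")
        logger.info("stage mine done (%d hits)", len(hits))

        # -- stage: properties --------------------------------------------
        stage = "props"
        props = properties_table(hit_records)
        props.to_csv(outdir / "properties.tsv", sep="\t", index=False,
                     float_format="%.6g")
        files["properties"] = str(outdir / "properties.tsv")
        counts["profiled_peptides"] = len(props)
        phylum_by_id = {k: v.phylum for k, v in taxonomy.items()}
        if len(props) >= 3 and len(
            {phylum_by_id.get(i, "") for i in props["id"]} - {""}
        ) >= 2:
            group_test = property_group_test(props, phylum_by_id)
            group_test.to_csv(outdir / "rank_tests.tsv", sep="\t", index=False,
                              float_format="%.6g")
            files["rank_tests"] = str(outdir / "rank_tests.tsv")
        else:
            notes.append("rank test skipped: fewer than two phyla among hits")

        # -- stage: network / clustering ----------------------------------
        stage = "network"
        if hit_records:
            matrix = identity_matrix(hit_records)
            ssn = build_ssn(matrix, config.ssn_edge, phylum_by_id)
            write_edge_list(ssn, outdir / "ssn_edges.tsv")
            write_node_attributes(ssn, outdir / "ssn_nodes.tsv")
            files["ssn_edges"] = str(outdir / "ssn_edges.tsv")
            files["ssn_nodes"] = str(outdir / "ssn_nodes.tsv")
            counts["ssn_components"] = ssn.n_components
            counts["ssn_components_excluding_singletons"] = (
                ssn.n_components_excluding_singletons
            )
            counts["ssn_singletons"] = len(ssn.singletons)
            clusters = greedy_cluster(hit_records, config.cluster_id)
            write_clusters(clusters, outdir / "clusters.tsv")
            files["clusters"] = str(outdir / "clusters.tsv")
            counts["clusters"] = len(clusters.clusters)
            representatives = [by_id[r] for r in clusters.representative_ids()]
        else:
            notes.append("network skipped: no hits")
            representatives = []

        # -- stage: tree ---------------------------------------------------
        stage = "tree"
        if len(representatives) >= 3:
            matrix = identity_matrix(representatives)
            tree = neighbor_joining(distances_from_identity(matrix))
            if config.outgroup_id is not None:
                tree = root_at_outgroup(tree, config.outgroup_id)
            write_newick(tree, outdir / "tree.nwk")
            files["tree"] = str(outdir / "tree.nwk")
            counts["tree_leaves"] = len(representatives)
        else:
            notes.append("tree skipped: fewer than 3 cluster representatives")

        # -- stage: bgc ----------------------------------------------------
        stage = "bgc"
        core_gene_ids = [
            f.gene_id for f in features if classify_gene_role(f.product) == "core"
        ]
        if core_gene_ids:
            bgcs = find_bgcs(
                features, core_gene_ids, config.window, contig_lengths
            )
            counts["bgcs"] = len(bgcs)
            counts["bgc_core_genes"] = sum(b.n_core for b in bgcs)
            counts["bgcs_single"] = sum(1 for b in bgcs if b.category == "single")
            counts["bgcs_multi"] = sum(1 for b in bgcs if b.category == "multi")
            summary = tabulate_bgcs(bgcs, taxonomy)
            summary.to_csv(outdir / "bgc_summary.tsv", sep="\t", index=False)
            files["bgc_summary"] = str(outdir / "bgc_summary.tsv")
            for i, bgc in enumerate(bgcs):
                write_synteny_svg(bgc, outdir / f"bgc_{i}.svg")
        else:
            notes.append("bgc skipped: no core genes among features")

        # -- referential integrity ----------------------------------------
        hit_ids = {h.sequence_id for h in hits}
        assert all(r.id in hit_ids for r in hit_records)
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.info("total wall time %.2f s", time.monotonic() - t0)
        logger.removeHandler(handler)
        handler.close()

    report = RunReport(
        counts=counts,
        files={k: str(Path(v).relative_to(outdir)) for k, v in files.items()},
        notes=notes,
        provenance={
            "config_sha256": config.digest(),
            "rng_seed": config.rng_seed,
            "version": __version__,
        },
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
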