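"""End-to-end pipeline: parse -> merge -> network -> stats -> subnets -> coding.

Every stage reads and writes plain files, never hidden state, so any
stage can be rerun independently — in particular the recode-and-re-run
loop of qualitative analysis.  A run produces a manifest recording the
inputs, a hash of the configuration, per-stage counts, and the paths of
every artifact written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import coding, ego, medline, network, stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    queries: dict[str, str]  # query label -> MEDLINE file path
    outdir: str = "meshnet_out"
    qualifier_mode: str = "composite"
    major_mode: str = "distinct"
    min_edge_weight: int = 1
    subnet_seeds: list[str] = field(default_factory=list)
    codebook: str | None = None
    coding_fields: tuple[str, ...] = ("title", "abstract")
    flow_columns: list[str] = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["coding_fields"] = tuple(doc.get("coding_fields", ("title", "abstract")))
        return cls(**doc)

    def to_yaml(self) -> str:
        d = self.__dict__.copy()
        d["coding_fields"] = list(self.coding_fields)
        return yaml.safe_dump(d, sort_keys=True)

    def build_config(self) -> network.NetworkBuildConfig:
        return network.NetworkBuildConfig(
            qualifier_mode=self.qualifier_mode,
            major_mode=self.major_mode,
            min_edge_weight=self.min_edge_weight,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and return the run manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "inputs": dict(config.queries),
        "stages": {},
        "outputs": {},
        "skipped": [],
    }

    # stage: parse + merge
    record_lists = []
    for label, path in config.queries.items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"stage parse: query file missing: {path}")
        record_lists.append((label, medline.parse_medline(p.read_text(), label)))
    corpus = medline.merge_and_dedupe(record_lists)
    if not corpus.records:
        raise ValueError("stage merge: empty corpus after merge")
    corpus_path = outdir / "corpus.medline"
    corpus_path.write_text(medline.write_medline(corpus.records))
    prov_path = Path(str(corpus_path) + ".provenance.json")
    prov_path.write_text(
        json.dumps(
            {
                "provenance": corpus.provenance,
                "n_duplicates_removed": corpus.n_duplicates_removed,
                "source_query": {r.pmid: r.source_query for r in corpus.records},
            },
            indent=2,
        )
    )
    manifest["stages"]["merge"] = medline.corpus_summary(corpus)
    manifest["outputs"]["corpus"] = str(corpus_path)

    # stage: network build
    net = network.build_cooccurrence_network(corpus, config.build_config())
    net_path = outdir / "network.sif"
    network.save_network(net, net_path, "sif")
    manifest["stages"]["network"] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges}
    manifest["outputs"]["network"] = str(net_path)

    # stage: statistics
    report = stats.full_report(net)
    stats_path = outdir / "network_stats.json"
    stats_path.write_text(json.dumps(report.to_dict(), indent=2))
    manifest["stages"]["stats"] = {
        k: v for k, v in report.to_dict().items() if k != "degree_table"
    }
    manifest["outputs"]["stats"] = str(stats_path)

    # stage: ego subnetworks
    if config.subnet_seeds:
        subs = []
        for seed in config.subnet_seeds:
            sub = ego.ego_subnetwork(net, seed)
            slug = "".join(c if c.isalnum() else "_" for c in seed.lower())
            sub_path = outdir / f"subnet_{slug}.sif"
            network.save_network(sub.graph, sub_path, "sif")
            (outdir / f"subnet_{slug}.json").write_text(
                json.dumps(sub.stats.to_dict(), indent=2)
            )
            manifest["stages"].setdefault("subnets", {})[seed] = {
                "n_nodes": sub.stats.n_nodes,
                "n_edges": sub.stats.n_edges,
            }
            manifest["outputs"][f"subnet:{seed}"] = str(sub_path)
            subs.append(sub)
        if len(subs) >= 2:
            cmp_path = outdir / "subnet_comparison.csv"
            ego.compare_subnets(subs).to_csv(cmp_path, index=False)
            manifest["outputs"]["subnet_comparison"] = str(cmp_path)
    else:
        manifest["skipped"].append("subnets")

    # stage: content coding + flows
    if config.codebook:
        cb = coding.load_codebook(Path(config.codebook))
        result = coding.apply_codebook(corpus, cb, config.coding_fields)
        result_path = outdir / "coding_result.json"
        result_path.write_text(result.to_json())
        freq_path = outdir / "code_frequencies.csv"
        coding.code_frequencies(result, cb).to_csv(freq_path, index=False)
        manifest["stages"]["coding"] = {
            "n_documents": len(result.assignments),
            "n_codes": len(result.codebook_codes),
        }
        manifest["outputs"]["coding_result"] = str(result_path)
        manifest["outputs"]["code_frequencies"] = str(freq_path)
        columns = config.flow_columns or [c.name for c in cb.columns]
        if len(columns) >= 2:
            table = coding.category_flows(result, columns)
            flows_path = outdir / "flows.csv"
            flows_path.write_text(table.to_long_csv())
            manifest["stages"]["flows"] = {
                "n_flows": sum(len(v) for v in table.flows.values())
            }
            manifest["outputs"]["flows"] = str(flows_path)
    else:
        manifest["skipped"].append("coding")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
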