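#!/usr/bin/env python
"""Re-analyse a previously deposited co-occurrence network file.

Loads a network (SIF or GraphML — e.g. the edge table exported from a
Cytoscape session), recomputes the global connectivity statistics, and
extracts first-neighbor subnetworks around the given seed terms.

Usage:
    python scripts/reanalyze_deposited.py data/deposited/network.sif \
        --seed "Government Regulation" --seed "Social Control, Formal"
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from meshnet import ego_subnetwork, full_report, read_network


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("network", type=Path)
    parser.add_argument("--format", default=None, choices=["sif", "graphml"])
    parser.add_argument("--seed", action="append", default=[],
                        help="Seed term for ego-subnetwork extraction (repeatable).")
    args = parser.parse_args()

    fmt = args.format or ("graphml" if args.network.suffix == ".graphml" else "sif")
    net = read_network(args.network, fmt)
    report = full_report(net).to_dict()
    degree_table = report.pop("degree_table")
    out = {"global": report, "top_degrees": degree_table[:10], "subnets": {}}
    for seed in args.seed:
        sub = ego_subnetwork(net, seed)
        sub_report = sub.stats.to_dict()
        sub_report.pop("degree_table")
        out["subnets"][seed] = sub_report
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
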