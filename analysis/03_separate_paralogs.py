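#!/usr/bin/env python
"""Separate paralogous subgroups with an SSN threshold sweep.

Collapses near-identical sequences (>= 70% identity) into meta-nodes,
raises the alignment-score cutoff in 5-unit steps until clusters are
annotation-homogeneous, and reads each final cluster's gene-neighborhood
signature — the planted partner family should dominate its subgroup's
cluster, mirroring how conserved gene context distinguishes
non-isofunctional paralogs.
"""

import json
import sys
from pathlib import Path

from ecaudit.io import read_labels
from ecaudit.ssn import (
    collapse_nodes,
    export_edge_list,
    export_graphml,
    neighborhood_signature,
    read_blast_tab,
    read_neighborhood_table,
    sweep_threshold,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    inputs = SCRATCH / "inputs"
    if not (inputs / "similarity.tsv").exists():
        print("run analysis/01_simulate_inputs.py first", file=sys.stderr)
        return 1
    out = ROOT / "ssn"
    out.mkdir(parents=True, exist_ok=True)

    edges = read_blast_tab(inputs / "similarity.tsv")
    labels = read_labels(inputs / "truth.tsv")
    partition = collapse_nodes(edges, labels.keys(), identity_cutoff=0.7)
    print(f"{len(labels)} sequences collapse to {len(partition)} meta-nodes at 70% identity")

    report = sweep_threshold(partition, edges, labels, as_start=10.0, step=5.0,
                             purity_target=0.9, frac_clusters=0.9, min_cluster_size=5)
    print(f"sweep stopped at AS={report.chosen_threshold:g} "
          f"(converged={report.converged}); clusters:")
    for i, (size, purity) in enumerate(zip(report.sizes, report.purities)):
        print(f"  cluster {i}: {size} sequences, purity {purity:.2f}")

    ctx = read_neighborhood_table(inputs / "neighborhoods.tsv")
    sigs = neighborhood_signature(report, ctx, window=5)
    for ci, sig in sigs.items():
        dom = ", ".join(sorted(sig["dominant"])) or "none"
        print(f"  cluster {ci} dominant neighborhood signature: {dom}")

    export_edge_list(report.ssn, out / "ssn_edges.tsv")
    cluster_ids = {m: i for i, c in enumerate(report.clusters) for m in c}
    export_graphml(report.ssn, out / "ssn.graphml", labels=labels, cluster_ids=cluster_ids)
    payload = {
        "chosen_threshold": report.chosen_threshold,
        "converged": report.converged,
        "sizes": report.sizes,
        "purities": report.purities,
        "history": report.history,
        "neighborhood_signatures": {
            str(k): {**v, "dominant": sorted(v["dominant"])} for k, v in sigs.items()
        },
    }
    (out / "ssn_sweep.json").write_text(json.dumps(payload, indent=2))
    print(f"outputs in {out}")


if __name__ == "__main__":
    sys.exit(main())
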