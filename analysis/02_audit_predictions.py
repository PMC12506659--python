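#!/usr/bin/env python
"""Audit the EC predictions in the evidence table.

Runs the repetition pre-pass and the category rubric over the evidence
fixture from step 01, tallies the categories, and checks the partition
arithmetic. Reproduces the headline result: roughly a third of
predictions are correct but mostly not novel, and over half are
inconsistent with existing evidence.
"""

import json
import sys
from pathlib import Path

from ecaudit.io import read_evidence, write_audit_calls
from ecaudit.rubric import audit, tally

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    evidence = SCRATCH / "inputs" / "evidence.tsv"
    if not evidence.exists():
        print("run analysis/01_simulate_inputs.py first", file=sys.stderr)
        return 1
    out = ROOT / "audit"
    out.mkdir(parents=True, exist_ok=True)
    records = read_evidence(evidence)
    calls = audit(records, min_count=3)
    write_audit_calls(calls, out / "audit.tsv")
    summary = tally(calls)
    d = summary.as_dict()
    (out / "summary.json").write_text(json.dumps(d, indent=2))

    print("category  count")
    for cat, n in d["counts"].items():
        print(f"{cat:>8}  {n}")
    print(f"total {d['n_total']}: {d['n_correct']} correct ({d['pct_correct']}%), "
          f"{d['n_inconsistent']} inconsistent ({d['pct_inconsistent_int']}%)")
    cnn, lsp = d["counts"]["CNN"], d["counts"]["LSP"]
    print(f"partition arithmetic: {d['n_total']} - {cnn} = {d['n_total'] - cnn}; "
          f"{d['n_total'] - cnn} - {lsp} = {d['n_total'] - cnn - lsp}; "
          f"{d['rationale_counts']['identical_ec']} exact matches + "
          f"{cnn - d['rationale_counts']['identical_ec']} same-function = {cnn}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    sys.exit(main())
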