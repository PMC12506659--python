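"""File formats, run configuration, and the end-to-end pipeline.

Tabular interchange is TSV throughout: evidence tables (one row per
locus, boolean flags as true/false, empty field = no reference EC),
audit calls, importance maps (long format, 1-based positions), and
gene-neighborhood context. Pairwise similarity is BLAST tabular
(outfmt 6). All outputs are sorted by locus/sequence id and floats are
serialized at 6 significant digits, so repeated runs diff cleanly; every
run directory carries the serialized config and its hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from ecaudit import __version__
from ecaudit.ec import ECNumber, parse_ec
from ecaudit.explain import BatchExplanation, CategoryProfile, explain_batch, stratify
from ecaudit.rubric import AuditCall, AuditSummary, Category, EvidenceRecord, audit, tally
from ecaudit.ssn import (
    ClusterReport,
    collapse_nodes,
    export_edge_list,
    export_graphml,
    neighborhood_signature,
    read_blast_tab,
    read_neighborhood_table,
    sweep_threshold,
)

__all__ = [
    "EVIDENCE_COLUMNS",
    "read_evidence",
    "write_evidence",
    "write_audit_calls",
    "read_audit_calls",
    "write_importance",
    "write_profiles",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("ecaudit")

_BOOL_FLAGS = [
    "same_function_without_ec",
    "in_training_set",
    "family_supports_predicted_ec",
    "activity_assigned_to_other_gene",
    "other_gene_same_family",
    "pathway_absent_in_organism",
    "literature_refutes",
    "literature_supports_uncaptured",
    "family_has_nonisofunctional_paralogs",
]

EVIDENCE_COLUMNS = [
    "locus_tag",
    "predicted_ec",
    "predicted_prob",
    "reference_ecs",
    "reference_function",
    "family_id",
] + _BOOL_FLAGS


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def read_evidence(path) -> list[EvidenceRecord]:
    """Read an evidence TSV into records; schema errors name the column."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        refs = tuple(
            parse_ec(t) for t in str(row.reference_ecs).split(";") if t.strip()
        )
        prob = row.predicted_prob.strip()
        records.append(
            EvidenceRecord(
                locus_tag=row.locus_tag,
                predicted_ec=parse_ec(row.predicted_ec),
                predicted_prob=float(prob) if prob else None,
                reference_ecs=refs,
                reference_function=row.reference_function,
                family_id=row.family_id or None,
                **{f: _parse_bool(row[f]) for f in _BOOL_FLAGS},
            )
        )
    return records


def write_evidence(records: Sequence[EvidenceRecord], path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: r.locus_tag):
        row = {
            "locus_tag": r.locus_tag,
            "predicted_ec": r.predicted_ec.text,
            "predicted_prob": "" if r.predicted_prob is None else f"{r.predicted_prob:.6g}",
            "reference_ecs": ";".join(e.text for e in r.reference_ecs),
            "reference_function": r.reference_function,
            "family_id": r.family_id or "",
        }
        row.update({f: str(getattr(r, f)).lower() for f in _BOOL_FLAGS})
        rows.append(row)
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_audit_calls(calls: Sequence[AuditCall], path) -> None:
    rows = [
        {
            "locus_tag": c.locus_tag,
            "category": c.category.value,
            "cs": c.cs,
            "rationale_code": c.rationale_code,
        }
        for c in sorted(calls, key=lambda c: c.locus_tag)
    ]
    pd.DataFrame(rows, columns=["locus_tag", "category", "cs", "rationale_code"]).to_csv(
        path, sep="\t", index=False
    )


def read_audit_calls(path) -> list[AuditCall]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str})
    return [
        AuditCall(r.locus_tag, Category(r.category), int(r.cs), r.rationale_code)
        for r in df.itertuples()
    ]


def write_importance(batch: BatchExplanation, path) -> None:
    """Long-format importance TSV: locus, label, 1-based position, value, status."""
    rows = []
    for m in sorted(batch.all_maps, key=lambda m: m.locus_tag):
        status = "explained" if m.explained else "estimated"
        for pos, v in enumerate(m.importances, start=1):
            rows.append((m.locus_tag, m.label, pos, f"{v:.6g}", status))
    pd.DataFrame(
        rows, columns=["locus_tag", "label", "position", "importance", "status"]
    ).to_csv(path, sep="\t", index=False)


def write_profiles(profiles: Sequence[CategoryProfile], path) -> None:
    rows = []
    for p in profiles:
        for b, (m, s) in enumerate(zip(p.mean, p.sd)):
            rows.append((p.category.value, b, f"{m:.6g}", f"{s:.6g}"))
    pd.DataFrame(rows, columns=["category", "bin", "mean", "sd"]).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (all stages optional but audit)."""

    evidence_path: str
    outdir: str
    similarity_path: Optional[str] = None
    labels_path: Optional[str] = None  # TSV: seq_id, true_ec (SSN cluster labels)
    neighborhood_path: Optional[str] = None
    fasta_path: Optional[str] = None
    rng_seed: int = 0
    # rubric
    min_count: int = 3
    # SSN sweep
    identity_cutoff: float = 0.7
    as_start: float = 0.0
    step: float = 5.0
    purity_target: float = 0.9
    frac_clusters: float = 0.9
    min_cluster_size: int = 5
    window: int = 5
    # explainer
    n_samples: int = 1000
    mask_rate: float = 0.3
    kernel_width: float = 0.25
    ridge_penalty: float = 1e-3
    max_explained: int = 500
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.identity_cutoff <= 1:
            raise ValueError("identity_cutoff must lie in (0, 1]")
        if not 0 < self.mask_rate < 1:
            raise ValueError("mask_rate must lie in (0, 1)")
        if self.min_count < 2:
            raise ValueError("min_count must be >= 2")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "seq_id" not in df.columns or "true_ec" not in df.columns:
        raise ValueError("labels table needs columns seq_id, true_ec")
    return dict(zip(df.seq_id, df.true_ec))


def run_pipeline(config: RunConfig, classifier=None) -> dict:
    """Run audit -> SSN sweep -> explanation -> report under one config.

    The explainer stage runs only when a classifier implementing the
    scoring contract is supplied (a plugin callable; the pipeline core
    carries no model runtime) together with a FASTA of sequences. The
    SSN stage runs when similarity and label inputs are present. Returns
    a manifest of written outputs; every JSON output embeds the config
    hash and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "outputs": {},
    }
    try:
        logger.info("run start: seed=%d hash=%s version=%s",
                    config.rng_seed, manifest["config_hash"], __version__)
        (outdir / "config.json").write_text(json.dumps(manifest["config"], indent=2, sort_keys=True))

        records = read_evidence(config.evidence_path)
        logger.info("audit: %d evidence records", len(records))
        calls = audit(records, min_count=config.min_count)
        summary = tally(calls)
        write_audit_calls(calls, outdir / "audit.tsv")
        summary_payload = {"config_hash": manifest["config_hash"], **summary.as_dict()}
        (outdir / "summary.json").write_text(json.dumps(summary_payload, indent=2))
        manifest["outputs"]["audit"] = "audit.tsv"
        manifest["outputs"]["summary"] = "summary.json"

        report: Optional[ClusterReport] = None
        if config.similarity_path and config.labels_path:
            edges = read_blast_tab(config.similarity_path)
            labels = read_labels(config.labels_path)
            partition = collapse_nodes(edges, labels.keys(), config.identity_cutoff)
            logger.info("ssn: %d edges, %d meta-nodes", len(edges), len(partition))
            report = sweep_threshold(
                partition,
                edges,
                labels,
                as_start=config.as_start,
                step=config.step,
                purity_target=config.purity_target,
                frac_clusters=config.frac_clusters,
                min_cluster_size=config.min_cluster_size,
            )
            logger.info(
                "ssn sweep: threshold=%.1f converged=%s clusters=%d",
                report.chosen_threshold, report.converged, len(report.clusters),
            )
            export_edge_list(report.ssn, outdir / "ssn_edges.tsv")
            cluster_ids = {m: i for i, c in enumerate(report.clusters) for m in c}
            export_graphml(report.ssn, outdir / "ssn.graphml", labels=labels, cluster_ids=cluster_ids)
            cluster_rows = [
                {
                    "cluster": i,
                    "n_sequences": report.sizes[i],
                    "purity": f"{report.purities[i]:.6g}",
                    "meta_nodes": ";".join(sorted(c)),
                }
                for i, c in enumerate(report.clusters)
            ]
            pd.DataFrame(cluster_rows).to_csv(outdir / "ssn_clusters.tsv", sep="\t", index=False)
            sweep_payload = {
                "config_hash": manifest["config_hash"],
                "chosen_threshold": report.chosen_threshold,
                "converged": report.converged,
                "history": report.history,
            }
            if config.neighborhood_path:
                ctx = read_neighborhood_table(config.neighborhood_path)
                sigs = neighborhood_signature(report, ctx, window=config.window)
                sweep_payload["neighborhood_signatures"] = {
                    str(k): {**v, "dominant": sorted(v["dominant"])} for k, v in sigs.items()
                }
            (outdir / "ssn_sweep.json").write_text(json.dumps(sweep_payload, indent=2))
            manifest["outputs"]["ssn"] = "ssn_sweep.json"

        if classifier is not None and config.fasta_path:
            seqs = read_fasta(config.fasta_path)
            call_loci_all = {c.locus_tag for c in calls}
            if calls and not (set(seqs) & call_loci_all):
                offenders = sorted(set(seqs) - call_loci_all)[:5]
                raise ValueError(
                    "sequence ids share no locus tags with the evidence table; "
                    f"first offenders: {offenders}"
                )
            logger.info("explain: %d sequences, max_explained=%d", len(seqs), config.max_explained)
            batch = explain_batch(
                classifier,
                seqs,
                max_explained=config.max_explained,
                rng_seed=config.rng_seed,
                n_samples=config.n_samples,
                mask_rate=config.mask_rate,
                kernel_width=config.kernel_width,
                ridge_penalty=config.ridge_penalty,
                n_bins=config.n_bins,
            )
            write_importance(batch, outdir / "importance.tsv")
            manifest["outputs"]["importance"] = "importance.tsv"
            call_loci = {c.locus_tag for c in calls}
            strat_maps = [m for m in batch.maps if m.locus_tag in call_loci]
            if strat_maps:
                profiles = stratify(strat_maps, calls, n_bins=config.n_bins)
                write_profiles(profiles, outdir / "profiles.csv")
                manifest["outputs"]["profiles"] = "profiles.csv"

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("run complete: %s", sorted(manifest["outputs"]))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
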