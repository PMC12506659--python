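"""Synthetic data with the statistical structure the audit assumes.

Generators for every pipeline input, so each stage is testable without
downloads: (i) paralogous superfamilies — subgroups diverged from a
common ancestor to controlled within/between identity targets, each
subgroup carrying a planted signature of subgroup-specific residues
(the sequence basis of non-isofunctional paralogy); (ii) gene
neighborhoods with a planted partner family colocalized with each
subgroup (the contextual evidence a curator would use); (iii) toy
multilabel EC classifiers in two regimes — a motif-driven model that
reads the planted signature residues and a frequency-driven model whose
predictions merely echo training-set label frequencies, plus a hybrid;
(iv) audit evidence fixtures whose flag patterns force each record into
an intended rubric category, including replicated-EC groups.

Mutations are substitution-only (no indels), so sequences stay
equal-length and ungapped column identity is well-defined; substitutions
are uniform over the 19 alternative residues. Subgroup "true" ECs are
drawn from a fictitious series (9.9.9.k) that cannot collide with real
EC numbers.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ecaudit.ec import parse_ec
from ecaudit.rubric import AuditCall, Category, EvidenceRecord

__all__ = [
    "AMINO_ACIDS",
    "SuperfamilyConfig",
    "Truth",
    "SuperfamilyData",
    "gen_superfamily",
    "realized_identities",
    "gen_neighborhoods",
    "ToyClassifier",
    "make_toy_classifier",
    "gen_audit_fixture",
    "gen_paper_scale_fixture",
    "PAPER_CATEGORY_COUNTS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class SuperfamilyConfig:
    """Parameters of one synthetic paralogous superfamily.

    Identity targets are mean pairwise fractions of matching columns:
    ``within_identity`` among members of one subgroup, and
    ``between_identity`` across subgroups (must be lower).
    ``signature_positions`` residues per subgroup are fixed,
    subgroup-specific, and disjoint across subgroups.
    """

    n_subgroups: int = 2
    seqs_per_subgroup: Union[int, tuple[int, ...]] = 20
    seq_length: int = 120
    within_identity: float = 0.8
    between_identity: float = 0.45
    signature_positions: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.between_identity < self.within_identity <= 1.0:
            raise ValueError(
                f"need 0 < between_identity ({self.between_identity}) < "
                f"within_identity ({self.within_identity}) <= 1"
            )
        if self.n_subgroups * self.signature_positions > self.seq_length:
            raise ValueError("signature positions exceed sequence length")

    @property
    def subgroup_sizes(self) -> tuple[int, ...]:
        if isinstance(self.seqs_per_subgroup, int):
            return (self.seqs_per_subgroup,) * self.n_subgroups
        if len(self.seqs_per_subgroup) != self.n_subgroups:
            raise ValueError("seqs_per_subgroup length must equal n_subgroups")
        return tuple(self.seqs_per_subgroup)

    def subgroup_ec(self, k: int) -> str:
        """Fictitious true EC for subgroup k (0-based): 9.9.9.{k+1}."""
        return f"9.9.9.{k + 1}"


@dataclass
class Truth:
    """Generator bookkeeping: per-sequence ground truth and planted features."""

    table: pd.DataFrame  # seq_id, subgroup, true_ec, genome_id
    signatures: dict[str, list[tuple[int, str]]]  # true_ec -> [(0-based position, residue)]
    config: SuperfamilyConfig

    def labels(self) -> dict[str, str]:
        return dict(zip(self.table.seq_id, self.table.true_ec))

    def subgroup_of(self) -> dict[str, int]:
        return dict(zip(self.table.seq_id, self.table.subgroup))


@dataclass
class SuperfamilyData:
    sequences: dict[str, str]
    truth: Truth

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sequences):
                fh.write(f">{sid}\n{self.sequences[sid]}\n")


def _solve_mutation_rates(within: float, between: float) -> tuple[float, float]:
    """Per-position substitution rates hitting the identity targets.

    With uniform substitution over 19 alternatives, two sequences mutated
    independently from a shared ancestor at rate r match per position
    with probability (1-r)^2 + r^2/19. For between-subgroup pairs the
    lineage composition (subgroup rate q then member rate r) leaves a
    root-match probability s, and pairs match with s^2 + (1-s)^2/19.
    Both equations are solved numerically.
    """
    def within_gap(r: float) -> float:
        return (1 - r) ** 2 + r**2 / _N_AA_MINUS1_F - within

    r = brentq(within_gap, 0.0, 0.97)

    def between_gap(q: float) -> float:
        s1 = 1 - q
        s = s1 * (1 - r) + (1 - s1) * (r / _N_AA_MINUS1_F)
        return s**2 + (1 - s) ** 2 / _N_AA_MINUS1_F - between

    q = brentq(between_gap, 0.0, 0.985)
    return q, r


_N_AA_MINUS1_F = float(_N_AA - 1)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly round(rate * L) random positions, never to itself.

    A fixed substitution count (rather than per-position Bernoulli draws)
    keeps the expected pairwise identity of the Bernoulli model while
    shrinking its variance, so small families land on their identity
    targets instead of scattering around them.
    """
    out = arr.copy()
    k = int(round(rate * arr.shape[0]))
    if k:
        hit = rng.choice(arr.shape[0], size=k, replace=False)
        alt = rng.integers(0, _N_AA - 1, size=k)
        out[hit] = alt + (alt >= arr[hit])  # skip the current residue
    return out


def gen_superfamily(cfg: SuperfamilyConfig) -> SuperfamilyData:
    """Generate a paralogous superfamily with planted subgroup signatures.

    One random ancestor; subgroup ancestors diverge from it to the
    between-identity target; members diverge from their subgroup
    ancestor to the within-identity target; each subgroup's signature
    residues are then fixed at its (disjoint) signature positions.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    L = cfg.seq_length
    # Signature columns perturb pairwise identity: within a subgroup its own
    # sigma positions always match; between subgroups the 2*sigma overwritten
    # columns match a random residue (~1/20). Adjust the targets the evolved
    # columns must hit so the realized full-length identities land on cfg's.
    sigma = cfg.signature_positions
    w_adj = (cfg.within_identity * L - sigma) / (L - sigma)
    b_adj = (cfg.between_identity * L - 2 * sigma / _N_AA) / (L - 2 * sigma)
    if not 0.0 < b_adj < w_adj < 1.0:
        raise ValueError("identity targets infeasible once signature columns are accounted for")
    q, r = _solve_mutation_rates(w_adj, b_adj)
    ancestor = rng.integers(0, _N_AA, size=L)

    n_sig_total = cfg.n_subgroups * cfg.signature_positions
    sig_pos = rng.choice(L, size=n_sig_total, replace=False)
    signatures: dict[str, list[tuple[int, str]]] = {}
    sig_by_subgroup: list[list[tuple[int, int]]] = []
    for k in range(cfg.n_subgroups):
        block = sig_pos[k * cfg.signature_positions : (k + 1) * cfg.signature_positions]
        residues = rng.integers(0, _N_AA, size=block.size)
        sig_by_subgroup.append([(int(p), int(c)) for p, c in zip(block, residues)])
        signatures[cfg.subgroup_ec(k)] = [
            (int(p), AMINO_ACIDS[int(c)]) for p, c in zip(block, residues)
        ]

    sequences: dict[str, str] = {}
    rows = []
    idx = 0
    for k, size in enumerate(cfg.subgroup_sizes):
        sub_anc = _mutate(ancestor, q, rng)
        for _ in range(size):
            member = _mutate(sub_anc, r, rng)
            for p, c in sig_by_subgroup[k]:
                member[p] = c
            sid = f"sub{k:02d}_seq{idx:04d}"
            sequences[sid] = "".join(AMINO_ACIDS[c] for c in member)
            rows.append(
                {
                    "seq_id": sid,
                    "subgroup": k,
                    "true_ec": cfg.subgroup_ec(k),
                    "genome_id": f"gm{idx:04d}",
                }
            )
            idx += 1
    table = pd.DataFrame(rows, columns=["seq_id", "subgroup", "true_ec", "genome_id"])
    return SuperfamilyData(sequences=sequences, truth=Truth(table, signatures, cfg))


def realized_identities(data: SuperfamilyData) -> tuple[float, float]:
    """Mean pairwise (within-subgroup, between-subgroup) column identities."""
    ids = sorted(data.sequences)
    sub = data.truth.subgroup_of()
    L = len(next(iter(data.sequences.values())))
    arr = np.frombuffer(
        "".join(data.sequences[i] for i in ids).encode("ascii"), dtype=np.uint8
    ).reshape(len(ids), L)
    groups = np.array([sub[i] for i in ids])
    within, between = [], []
    for i in range(len(ids)):
        same = groups[i + 1 :] == groups[i]
        ident = (arr[i + 1 :] == arr[i]).mean(axis=1)
        within.extend(ident[same])
        between.extend(ident[~same])
    return float(np.mean(within)), float(np.mean(between)) if between else float("nan")


def gen_neighborhoods(
    truth: Truth,
    colocal_prob: float = 0.9,
    n_decoy_families: int = 30,
    rng_seed: int = 0,
    window: int = 5,
) -> pd.DataFrame:
    """Gene-neighborhood table with planted subgroup-partner colocalization.

    Each subgroup k has a designated partner family ``partner_k`` placed
    adjacent (offset +1) with probability ``colocal_prob``; every other
    slot within +/-window is filled with a uniform decoy family. Long
    format: seq_id, genome_id, neighbor_family, offset.
    """
    if not 0.0 <= colocal_prob <= 1.0:
        raise ValueError("colocal_prob must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    rows = []
    offsets = [o for o in range(-window, window + 1) if o != 0]
    for _, rec in truth.table.iterrows():
        partner = f"partner_{rec.subgroup}"
        place_partner = rng.random() < colocal_prob
        for o in offsets:
            if o == 1 and place_partner:
                fam = partner
            else:
                fam = f"decoy_{rng.integers(0, n_decoy_families)}"
            rows.append(
                {
                    "seq_id": rec.seq_id,
                    "genome_id": rec.genome_id,
                    "neighbor_family": fam,
                    "offset": o,
                }
            )
    return pd.DataFrame(rows, columns=["seq_id", "genome_id", "neighbor_family", "offset"])


def _content_uniform(seq: str, seed: int) -> float:
    """Deterministic pseudo-uniform in [0, 1) from sequence content + seed."""
    return zlib.crc32(f"{seed}:{seq}".encode("ascii")) / 2**32


class ToyClassifier:
    """Deterministic multilabel toy EC classifier.

    ``motif`` mode scores each label by how completely the sequence
    carries that label's planted signature residues — a model that reads
    localized sequence features. ``frequency`` mode carries no
    biological signal: per-label base scores are a fixed monotone
    transform of the training-label frequencies, and the top label is
    drawn per sequence by inverse-CDF sampling of those frequencies from
    a content hash, so prediction counts mirror the training
    distribution regardless of the planted signatures. ``hybrid`` mixes
    the two score vectors with a convex weight (0 = pure frequency).
    """

    def __init__(
        self,
        mode: str,
        labels: Sequence[str],
        signatures: Mapping[str, list[tuple[int, str]]],
        training_freq: Optional[Mapping[str, float]] = None,
        sharpness: float = 2.0,
        rng_seed: int = 0,
        hybrid_weight: float = 0.5,
    ) -> None:
        if mode not in ("motif", "frequency", "hybrid"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode in ("frequency", "hybrid"):
            if training_freq is None:
                raise ValueError(f"{mode} mode requires training_freq")
            total = sum(training_freq.values())
            if not 0.98 <= total <= 1.02:
                raise ValueError(f"training_freq must sum to ~1, got {total:.4f}")
        self.mode = mode
        self.labels = list(labels)
        self.sharpness = float(sharpness)
        self.rng_seed = int(rng_seed)
        self.hybrid_weight = float(hybrid_weight)
        self._signatures = {lab: list(signatures.get(lab, [])) for lab in self.labels}
        freqs = np.array([float((training_freq or {}).get(lab, 0.0)) for lab in self.labels])
        self._freqs = freqs
        if freqs.sum() > 0:
            self._cdf = np.cumsum(freqs / freqs.sum())
            self._base = 0.05 + 0.5 * freqs / freqs.max()
        else:
            self._cdf = None
            self._base = np.zeros(len(self.labels))
        self._n_sig = max((len(s) for s in self._signatures.values()), default=0)

    def _motif_scores(self, seq: str) -> np.ndarray:
        thr = self._n_sig - 0.5
        out = np.empty(len(self.labels))
        for i, lab in enumerate(self.labels):
            matches = sum(
                1 for p, res in self._signatures[lab] if p < len(seq) and seq[p] == res
            )
            out[i] = expit(self.sharpness * (matches - thr))
        return out

    def _frequency_scores(self, seq: str) -> np.ndarray:
        u = _content_uniform(seq, self.rng_seed)
        sampled = int(np.searchsorted(self._cdf, u, side="right"))
        sampled = min(sampled, len(self.labels) - 1)
        out = self._base.copy()
        out[sampled] = 0.95
        return out

    def score(self, sequence: str) -> np.ndarray:
        if self.mode == "motif":
            return self._motif_scores(sequence)
        if self.mode == "frequency":
            return self._frequency_scores(sequence)
        w = self.hybrid_weight
        return w * self._motif_scores(sequence) + (1 - w) * self._frequency_scores(sequence)

    def score_batch(self, sequences: Sequence[str]) -> np.ndarray:
        return np.array([self.score(s) for s in sequences])


def make_toy_classifier(
    mode: str,
    truth: Truth,
    training_freq: Optional[Mapping[str, float]] = None,
    sharpness: float = 2.0,
    rng_seed: int = 0,
    hybrid_weight: float = 0.5,
) -> ToyClassifier:
    """Build a toy classifier over the superfamily's subgroup EC labels.

    Labels are the subgroup ECs in subgroup order, followed by any extra
    labels that appear only in ``training_freq``.
    """
    labels = [truth.config.subgroup_ec(k) for k in range(truth.config.n_subgroups)]
    if training_freq:
        labels += [lab for lab in training_freq if lab not in labels]
    return ToyClassifier(
        mode=mode,
        labels=labels,
        signatures=truth.signatures,
        training_freq=training_freq,
        sharpness=sharpness,
        rng_seed=rng_seed,
        hybrid_weight=hybrid_weight,
    )


# ---------------------------------------------------------------------------
# audit evidence fixtures

#: the audited study's category counts (453 predictions)
PAPER_CATEGORY_COUNTS: dict[str, int] = {
    "COR": 3, "CNN": 136, "LSP": 27, "UNC": 42, "PLI": 42, "NPI": 77, "REP": 126,
}


def _unique_ec_stream(reserved: set[str]) -> Iterable[str]:
    for a, b, c, d in itertools.product(range(1, 7), range(1, 40), range(1, 40), range(1, 60)):
        ec = f"{a}.{b}.{c}.{d}"
        if ec not in reserved:
            yield ec


def gen_audit_fixture(
    category_counts: Mapping[str, int],
    rng_seed: int = 0,
    min_count: int = 3,
    cnn_same_function: int = 0,
    cnn_ec_overrides: Optional[Sequence[tuple[str, int]]] = None,
    rep_ec_plan: Optional[Sequence[tuple[str, int]]] = None,
) -> tuple[list[EvidenceRecord], list[AuditCall]]:
    """Evidence records whose flags force each intended rubric category.

    CNN via an identical EC (with ``cnn_same_function`` of them instead
    using the same-function-without/partial-EC routes, alternating); LSP
    via a prediction generalizing the reference; COR via literature the
    reference missed; NPI via an absent pathway; PLI via a same-family
    gene already holding the activity; REP via replicated ECs with
    refuting literature and no family support; UNC via no flags.
    Records are shuffled deterministically.

    ``rep_ec_plan`` assigns specific (EC, count) replication groups; the
    remainder is chunked into shared synthetic ECs, each group >=
    ``min_count`` (a REP total of 1..min_count-1 is infeasible under the
    rubric and raises). ``cnn_ec_overrides`` forces some CNN-identical
    records onto given predicted ECs with family support, emulating
    family-supported members of an otherwise replicated EC.

    Returns ``(records, intended_calls)`` in matching shuffled order.
    """
    counts = {Category(k) if isinstance(k, str) else k: int(v) for k, v in category_counts.items()}
    for cat, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {cat.value}")
    counts = {c: counts.get(c, 0) for c in Category}
    if cnn_same_function > counts[Category.CNN]:
        raise ValueError("cnn_same_function exceeds the CNN count")

    n_rep = counts[Category.REP]
    if 0 < n_rep < min_count:
        raise ValueError(f"a REP count of {n_rep} cannot reach min_count={min_count}")
    rep_plan: list[tuple[str, int]] = list(rep_ec_plan or [])
    planned = sum(c for _, c in rep_plan)
    if planned > n_rep:
        raise ValueError("rep_ec_plan exceeds the REP count")
    remainder = n_rep - planned
    chunk_idx = 0
    while remainder > 0:
        size = min(20, remainder)
        if 0 < remainder - size < min_count:
            size = remainder  # avoid a trailing group too small to flag
        rep_plan.append((f"8.8.8.{chunk_idx + 1}", size))
        remainder -= size
        chunk_idx += 1
    for ec, c in rep_plan:
        if c < min_count:
            raise ValueError(f"replication group {ec} of size {c} is below min_count={min_count}")

    reserved = {ec for ec, _ in rep_plan} | {ec for ec, _ in (cnn_ec_overrides or [])}
    ec_stream = iter(_unique_ec_stream(reserved))
    records: list[EvidenceRecord] = []
    intended: list[AuditCall] = []
    tag = itertools.count(1)

    def add(rec: EvidenceRecord, cat: Category, code: str) -> None:
        records.append(rec)
        from ecaudit.rubric import CONFIDENCE_SCORE

        intended.append(AuditCall(rec.locus_tag, cat, CONFIDENCE_SCORE[cat], code))

    # CNN: identical ECs, some via the same-function routes, some on override ECs
    override = [(ec, c) for ec, c in (cnn_ec_overrides or [])]
    n_override = sum(c for _, c in override)
    n_identical = counts[Category.CNN] - cnn_same_function
    if n_override > n_identical:
        raise ValueError("cnn_ec_overrides exceed the identical-EC CNN count")
    override_ecs = [ec for ec, c in override for _ in range(c)]
    for i in range(n_identical):
        if i < len(override_ecs):
            ec, fam_support = override_ecs[i], True
        else:
            ec, fam_support = next(ec_stream), False
        pred = parse_ec(ec)
        add(
            EvidenceRecord(
                locus_tag=f"b{next(tag):04d}",
                predicted_ec=pred,
                reference_ecs=(pred,),
                in_training_set=True,
                family_supports_predicted_ec=fam_support,
            ),
            Category.CNN,
            "identical_ec",
        )
    for i in range(cnn_same_function):
        pred = parse_ec(next(ec_stream))
        if i % 2 == 0:
            rec = EvidenceRecord(
                locus_tag=f"b{next(tag):04d}",
                predicted_ec=pred,
                reference_ecs=(),
                same_function_without_ec=True,
            )
            code = "same_function_no_ec"
        else:
            partial = parse_ec(".".join(str(c) for c in pred.specified()[:3]) + ".-")
            rec = EvidenceRecord(
                locus_tag=f"b{next(tag):04d}",
                predicted_ec=pred,
                reference_ecs=(partial,),
                same_function_without_ec=True,
            )
            code = "same_function_partial_ec"
        add(rec, Category.CNN, code)

    # LSP: partial prediction generalizing a full reference EC
    for _ in range(counts[Category.LSP]):
        full = parse_ec(next(ec_stream))
        pred = parse_ec(".".join(str(c) for c in full.specified()[:3]) + ".-")
        add(
            EvidenceRecord(
                locus_tag=f"b{next(tag):04d}", predicted_ec=pred, reference_ecs=(full,)
            ),
            Category.LSP,
            "less_precise",
        )

    # COR: validated by literature the reference database missed
    for _ in range(counts[Category.COR]):
        add(
            EvidenceRecord(
                locus_tag=f"b{next(tag):04d}",
                predicted_ec=parse_ec(next(ec_stream)),
                literature_supports_uncaptured=True,
            ),
            Category.COR,
            "literature_uncaptured",
        )

    # UNC: no evidence either way
    for _ in range(counts[Category.UNC]):
        add(
            EvidenceRecord(locus_tag=f"b{next(tag):04d}", predicted_ec=parse_ec(next(ec_stream))),
            Category.UNC,
            "uncertain",
        )

    # PLI: the activity belongs to a paralog in the same family
    for _ in range(counts[Category.PLI]):
        add(
            EvidenceRecord(
                locus_tag=f"b{next(tag):04d}",
                predicted_ec=parse_ec(next(ec_stream)),
                family_id="famP",
                activity_assigned_to_other_gene=True,
                other_gene_same_family=True,
            ),
            Category.PLI,
            "paralog_conflict",
        )

    # NPI: refuted — the predicted pathway is absent from the organism
    for _ in range(counts[Category.NPI]):
        add(
            EvidenceRecord(
                locus_tag=f"b{next(tag):04d}",
                predicted_ec=parse_ec(next(ec_stream)),
                pathway_absent_in_organism=True,
            ),
            Category.NPI,
            "pathway_absent",
        )

    # REP: replicated ECs, literature-refuted, no family support
    for ec, c in rep_plan:
        pred = parse_ec(ec)
        for _ in range(c):
            add(
                EvidenceRecord(
                    locus_tag=f"b{next(tag):04d}",
                    predicted_ec=pred,
                    literature_refutes=True,
                    family_supports_predicted_ec=False,
                ),
                Category.REP,
                "replicated_ec",
            )

    order = np.random.default_rng(rng_seed).permutation(len(records))
    return [records[i] for i in order], [intended[i] for i in order]


def gen_paper_scale_fixture(rng_seed: int = 0, min_count: int = 3):
    """Fixture mirroring the audited study's structure at full scale.

    453 records: the published category counts, a 121/15 split of CNN
    into identical-EC vs same-function cases, 12 replicated histidine
    kinase predictions (EC 2.7.13.3), and 15 predictions of the PTS
    transporter EC 2.7.1.69 of which 4 carry family support (leaving 11
    flagged as replications).
    """
    return gen_audit_fixture(
        PAPER_CATEGORY_COUNTS,
        rng_seed=rng_seed,
        min_count=min_count,
        cnn_same_function=15,
        cnn_ec_overrides=[("2.7.1.69", 4)],
        rep_ec_plan=[("2.7.13.3", 12), ("2.7.1.69", 11)],
    )
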