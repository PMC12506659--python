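"""Error-taxonomy rubric for audited EC-number predictions.

Each prediction for a protein of unknown function is compared against the
curated evidence for that protein — the reference annotation, family
membership, pathway presence in the organism, and published literature —
and assigned one of seven categories with a confidence score (CS):

==========  ====================================  ==
category    meaning                               CS
==========  ====================================  ==
CNN         correct but not novel (matches the     2
            existing reference annotation)
LSP         less precise (more generic than the    2
            reference annotation)
COR         correct and novel (validated by        2
            literature the reference missed)
UNC         uncertain (neither validated nor       1
            refuted)
PLI         paralog-incorrect (activity belongs    0
            to a paralog in the same family)
NPI         nonparalog-incorrect (refuted on       0
            other grounds)
REP         repetition (an EC replicated across    0
            many unrelated proteins, with no
            family support)
==========  ====================================  ==

The module also provides the audit tallies, a per-class macro-F1 for
benchmarking predictors, and a rank-correlation statistic that detects
frequency-dependent prediction behaviour (a model echoing its training
label frequencies instead of reading the sequence).
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from ecaudit.ec import ECNumber, Relation, RelationKind, relation_to_set

__all__ = [
    "Category",
    "EvidenceRecord",
    "AuditCall",
    "AuditSummary",
    "classify_prediction",
    "detect_repetitions",
    "audit",
    "tally",
    "macro_f1",
    "frequency_dependence",
]


class Category(enum.Enum):
    CNN = "CNN"
    LSP = "LSP"
    COR = "COR"
    UNC = "UNC"
    PLI = "PLI"
    NPI = "NPI"
    REP = "REP"


#: confidence score is a pure function of the category
CONFIDENCE_SCORE: dict[Category, int] = {
    Category.CNN: 2,
    Category.LSP: 2,
    Category.COR: 2,
    Category.UNC: 1,
    Category.PLI: 0,
    Category.NPI: 0,
    Category.REP: 0,
}

CORRECT_CATEGORIES = frozenset({Category.CNN, Category.LSP, Category.COR})
INCONSISTENT_CATEGORIES = frozenset({Category.PLI, Category.NPI, Category.REP})


@dataclass(frozen=True)
class EvidenceRecord:
    """One protein's prediction plus the curated evidence used to judge it.

    Boolean evidence flags encode curation judgements (they are inputs,
    not computed from text): whether the reference entry describes the
    same function without/with a partial EC, whether the protein was in
    the predictor's training set, whether its sequence family supports
    the predicted activity, whether the activity is already assigned to
    another gene (possibly a paralog in the same family), whether the
    predicted pathway is absent from the organism, and whether published
    literature refutes the prediction or supports it where the reference
    database lagged behind.
    """

    locus_tag: str
    predicted_ec: ECNumber
    predicted_prob: Optional[float] = None
    reference_ecs: tuple[ECNumber, ...] = ()
    reference_function: str = ""
    same_function_without_ec: bool = False
    in_training_set: bool = False
    family_id: Optional[str] = None
    family_supports_predicted_ec: bool = False
    activity_assigned_to_other_gene: bool = False
    other_gene_same_family: bool = False
    pathway_absent_in_organism: bool = False
    literature_refutes: bool = False
    literature_supports_uncaptured: bool = False
    family_has_nonisofunctional_paralogs: bool = False

    def __post_init__(self) -> None:
        if self.other_gene_same_family and not self.activity_assigned_to_other_gene:
            raise ValueError(
                f"{self.locus_tag}: other_gene_same_family requires activity_assigned_to_other_gene"
            )
        if self.literature_refutes and self.literature_supports_uncaptured:
            raise ValueError(
                f"{self.locus_tag}: literature cannot both refute and support the prediction"
            )
        if self.predicted_prob is not None and not 0.0 <= self.predicted_prob <= 1.0:
            raise ValueError(f"{self.locus_tag}: predicted_prob must lie in [0, 1]")

    @property
    def has_refuting_evidence(self) -> bool:
        return (
            self.pathway_absent_in_organism
            or self.activity_assigned_to_other_gene
            or self.literature_refutes
        )

    def reference_relation(self) -> Relation:
        return relation_to_set(self.predicted_ec, self.reference_ecs)


@dataclass(frozen=True)
class AuditCall:
    """Category and confidence score assigned to one prediction."""

    locus_tag: str
    category: Category
    cs: int
    rationale_code: str

    def __post_init__(self) -> None:
        if self.cs != CONFIDENCE_SCORE[self.category]:
            raise ValueError(f"cs {self.cs} inconsistent with category {self.category.value}")


def _positive_category(rec: EvidenceRecord) -> Optional[tuple[Category, str]]:
    """Rules (1)-(3): the supported categories CNN / LSP / COR, or None.

    Evaluated before any refutation logic; repetition flagging also uses
    this to exempt supported predictions from the replication count.
    """
    rel = rec.reference_relation()
    if rel.kind is RelationKind.IDENTICAL:
        return Category.CNN, "identical_ec"
    if rec.same_function_without_ec:
        if rel.kind is RelationKind.PRED_SPECIALIZES_REF:
            # reference holds the same function under a partial EC
            return Category.CNN, "same_function_partial_ec"
        return Category.CNN, "same_function_no_ec"
    if rel.kind is RelationKind.PRED_GENERALIZES_REF:
        return Category.LSP, "less_precise"
    if rec.literature_supports_uncaptured:
        return Category.COR, "literature_uncaptured"
    return None


def classify_prediction(rec: EvidenceRecord, is_repetition: bool = False) -> AuditCall:
    """Assign the audit category for one prediction.

    Deterministic decision tree, in order: (1) agreement with the
    reference annotation (identical EC, or same function with no/partial
    EC) -> CNN; (2) a more generic prediction than the reference -> LSP;
    (3) validation by literature the reference missed -> COR; (4) any
    refuting evidence -> REP when the EC is a flagged replication, PLI
    when the activity belongs to a paralog in the same family (or the
    family is known non-isofunctional and only the serial digit
    diverges), otherwise NPI; (5) everything else -> UNC. Exactly one
    category results; the CS follows from it.
    """
    pos = _positive_category(rec)
    if pos is not None:
        cat, code = pos
        return AuditCall(rec.locus_tag, cat, CONFIDENCE_SCORE[cat], code)

    if rec.has_refuting_evidence:
        if is_repetition:
            return AuditCall(rec.locus_tag, Category.REP, 0, "replicated_ec")
        rel = rec.reference_relation()
        paralog_serial_divergence = (
            rec.family_has_nonisofunctional_paralogs
            and rel.kind is RelationKind.DIVERGENT
            and rel.k == 4
        )
        if rec.other_gene_same_family or paralog_serial_divergence:
            return AuditCall(rec.locus_tag, Category.PLI, 0, "paralog_conflict")
        if rec.pathway_absent_in_organism:
            code = "pathway_absent"
        elif rec.activity_assigned_to_other_gene:
            code = "activity_elsewhere"
        else:
            code = "literature_refuted"
        return AuditCall(rec.locus_tag, Category.NPI, 0, code)

    return AuditCall(rec.locus_tag, Category.UNC, 1, "uncertain")


def detect_repetitions(records: Sequence[EvidenceRecord], min_count: int = 3) -> set[str]:
    """Locus tags whose predicted EC is a suspect replication.

    A locus is flagged iff its full predicted EC occurs at least
    ``min_count`` times among all records, its own family does not
    support the predicted activity, and the record is not already
    supported (CNN/LSP/COR-eligible). Family-supported or supported
    records still count toward the occurrence tally — replication is a
    property of the EC, exemption a property of the record.
    """
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    counts = Counter(rec.predicted_ec.text for rec in records)
    flagged: set[str] = set()
    for rec in records:
        if counts[rec.predicted_ec.text] < min_count:
            continue
        if rec.family_supports_predicted_ec:
            continue
        if _positive_category(rec) is not None:
            continue
        flagged.add(rec.locus_tag)
    return flagged


def audit(records: Sequence[EvidenceRecord], min_count: int = 3) -> list[AuditCall]:
    """Full rubric pass: repetition pre-pass, then per-record classification."""
    reps = detect_repetitions(records, min_count=min_count)
    return [classify_prediction(rec, is_repetition=rec.locus_tag in reps) for rec in records]


@dataclass
class AuditSummary:
    """Category tallies for a set of audit calls."""

    counts: dict[Category, int]
    rationale_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_correct(self) -> int:
        return sum(self.counts[c] for c in CORRECT_CATEGORIES)

    @property
    def n_inconsistent(self) -> int:
        return sum(self.counts[c] for c in INCONSISTENT_CATEGORIES)

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_total if self.n_total else 0.0

    @property
    def pct_inconsistent(self) -> float:
        return 100.0 * self.n_inconsistent / self.n_total if self.n_total else 0.0

    def as_dict(self) -> dict:
        """JSON-ready summary; percentages at one decimal and nearest integer."""
        return {
            "counts": {c.value: self.counts[c] for c in Category},
            "rationale_counts": dict(sorted(self.rationale_counts.items())),
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "n_inconsistent": self.n_inconsistent,
            "pct_correct": round(self.pct_correct, 1),
            "pct_correct_int": int(round(self.pct_correct)),
            "pct_inconsistent": round(self.pct_inconsistent, 1),
            "pct_inconsistent_int": int(round(self.pct_inconsistent)),
        }


def tally(calls: Iterable[AuditCall]) -> AuditSummary:
    """Count calls per category; empty input yields zeros with a warning."""
    counts = {c: 0 for c in Category}
    rationale: Counter[str] = Counter()
    n = 0
    for call in calls:
        counts[call.category] += 1
        rationale[call.rationale_code] += 1
        n += 1
    if n == 0:
        warnings.warn("tally of an empty call list: percentages reported as 0", stacklevel=2)
    return AuditSummary(counts=counts, rationale_counts=dict(rationale))


def _as_text(ec) -> str:
    return ec.text if isinstance(ec, ECNumber) else str(ec)


def macro_f1(
    predicted: Mapping[str, object], truth: Mapping[str, object]
) -> tuple[float, dict[str, float]]:
    """Macro-averaged F1 over full-EC classes.

    F1 is computed per EC class (harmonic mean of precision and recall,
    0 where undefined) and averaged, unweighted, over the union of
    classes present in the truth or the predictions. Both mappings must
    cover the same locus set. Returns ``(macro_f1, per_class_f1)``.
    """
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth must cover the same locus set")
    loci = sorted(predicted)
    if not loci:
        return 0.0, {}
    y_pred = [_as_text(predicted[l]) for l in loci]
    y_true = [_as_text(truth[l]) for l in loci]
    labels = sorted(set(y_pred) | set(y_true))
    _, _, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )
    per_class = {lab: float(v) for lab, v in zip(labels, f1)}
    return float(np.mean(f1)), per_class


def frequency_dependence(
    predicted: Mapping[str, object], training_freq: Mapping[str, float]
) -> Optional[float]:
    """Spearman correlation of per-EC prediction counts vs training frequency.

    A predictor that echoes its training label frequencies rather than
    reading the sequence yields a strong positive rank correlation;
    sequence-driven predictions on a frequency-unrelated label mix yield
    a correlation near zero. The union of ECs from either argument is
    used, with absent entries counted as 0. Returns None when fewer than
    3 distinct ECs are available (the statistic is undefined).
    """
    total = sum(training_freq.values())
    if not 0.98 <= total <= 1.02:
        raise ValueError(f"training_freq must sum to ~1, got {total:.4f}")
    counts = Counter(_as_text(ec) for ec in predicted.values())
    ecs = sorted(set(counts) | {_as_text(e) for e in training_freq})
    if len(ecs) < 3:
        return None
    x = np.array([counts.get(e, 0) for e in ecs], dtype=float)
    y = np.array([dict((_as_text(k), v) for k, v in training_freq.items()).get(e, 0.0) for e in ecs])
    rho = stats.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)
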