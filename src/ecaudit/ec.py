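"""Hierarchical Enzyme Commission (EC) numbers.

An EC number is a four-level hierarchical code (class, subclass,
sub-subclass, serial) describing an enzymatic activity, e.g. ``2.7.7.87``
for L-threonylcarbamoyladenylate synthase. Trailing levels may be left
unspecified, written ``-`` (``2.1.1.-``): such partial codes name an
activity class rather than a substrate-level activity. Partial codes are
prefixes only — an unspecified level is never followed by a specified one.

Comparison between a predicted and a reference EC is hierarchical: two
codes may be identical, one may specialize (extend) the other, or they may
diverge at some level k — the distinction between an annotation that is
merely less precise and one that names a different activity altogether.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "ECNumber",
    "ECParseError",
    "RelationKind",
    "Relation",
    "parse_ec",
    "relation",
    "relation_to_set",
]


class ECParseError(ValueError):
    """Raised for text that is not a valid (possibly partial) EC number."""


@dataclass(frozen=True, order=True)
class ECNumber:
    """A full or partial EC number.

    ``levels`` holds up to four components; ``None`` marks an unspecified
    level and may appear only as a contiguous suffix. Construct via
    :func:`parse_ec` or directly from integers.
    """

    levels: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        lv = tuple(self.levels)
        if not 1 <= len(lv) <= 4:
            raise ECParseError(f"EC number must have 1-4 levels, got {len(lv)}")
        if lv[0] is None:
            raise ECParseError("first EC level must be specified")
        seen_unspecified = False
        for i, c in enumerate(lv, start=1):
            if c is None:
                seen_unspecified = True
            else:
                if seen_unspecified:
                    raise ECParseError(
                        f"specified level {c!r} at position {i} follows an unspecified level"
                    )
                if not isinstance(c, int) or isinstance(c, bool) or c < 1:
                    raise ECParseError(f"EC level at position {i} must be a positive integer, got {c!r}")
        # normalize to length 4 so "2.7.1" and "2.7.1.-" compare equal
        object.__setattr__(self, "levels", lv + (None,) * (4 - len(lv)))

    @property
    def specified_depth(self) -> int:
        """Number of specified leading levels (1-4)."""
        return sum(1 for c in self.levels if c is not None)

    @property
    def is_full(self) -> bool:
        """True when all four levels are specified (substrate-level code)."""
        return self.specified_depth == 4

    @property
    def text(self) -> str:
        """Canonical dotted serialization, ``-`` for unspecified levels."""
        return ".".join("-" if c is None else str(c) for c in self.levels)

    def specified(self) -> tuple[int, ...]:
        return tuple(c for c in self.levels if c is not None)

    def __str__(self) -> str:
        return self.text

    def __repr__(self) -> str:
        return f"ECNumber({self.text!r})"


def parse_ec(text: str) -> ECNumber:
    """Parse a dotted EC string such as ``"2.7.13.3"`` or ``"2.1.1.-"``.

    Trailing ``-`` components become unspecified levels. Raises
    :class:`ECParseError` naming the offending component on malformed
    input (non-numeric specified level, more than four levels, or a
    specified level after an unspecified one).
    """
    if not isinstance(text, str) or not text.strip():
        raise ECParseError("empty EC string")
    parts = text.strip().split(".")
    if len(parts) > 4:
        raise ECParseError(f"{text!r}: more than 4 levels")
    levels: list[Optional[int]] = []
    for i, p in enumerate(parts, start=1):
        p = p.strip()
        if p in ("-", ""):
            levels.append(None)
            continue
        # "n" classes such as 1.14.14.n1 are preliminary serials; not accepted here
        try:
            v = int(p)  # normalizes leading zeros
        except ValueError:
            raise ECParseError(f"{text!r}: component {p!r} at level {i} is not a number") from None
        if v < 1:
            raise ECParseError(f"{text!r}: component {p!r} at level {i} must be >= 1")
        levels.append(v)
    return ECNumber(tuple(levels))


class RelationKind(enum.Enum):
    """Hierarchical relation of a predicted EC to a reference EC."""

    IDENTICAL = "identical"
    PRED_SPECIALIZES_REF = "pred_specializes_ref"
    PRED_GENERALIZES_REF = "pred_generalizes_ref"
    DIVERGENT = "divergent_at_k"
    NO_REFERENCE = "no_reference"


@dataclass(frozen=True)
class Relation:
    """Result of comparing predicted vs reference EC.

    ``k`` is the first level (1-based) at which both codes are specified
    and differ; it is set only for :attr:`RelationKind.DIVERGENT`.
    """

    kind: RelationKind
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.kind is RelationKind.DIVERGENT) != (self.k is not None):
            raise ValueError("k is set exactly for divergent relations")


def relation(pred: ECNumber, ref: Optional[ECNumber]) -> Relation:
    """Hierarchically relate a predicted EC to a reference EC.

    identical: same specified depth, all specified levels equal.
    pred_specializes_ref: the reference's specified levels are a proper
    prefix of the prediction's (the prediction is more precise).
    pred_generalizes_ref: the converse (the prediction is less precise).
    divergent_at_k: both specify level k and disagree there, agreeing on
    everything shallower. no_reference: ``ref`` is absent.
    """
    if ref is None:
        return Relation(RelationKind.NO_REFERENCE)
    a, b = pred.specified(), ref.specified()
    for k, (x, y) in enumerate(zip(a, b), start=1):
        if x != y:
            return Relation(RelationKind.DIVERGENT, k=k)
    if len(a) == len(b):
        return Relation(RelationKind.IDENTICAL)
    if len(a) > len(b):
        return Relation(RelationKind.PRED_SPECIALIZES_REF)
    return Relation(RelationKind.PRED_GENERALIZES_REF)


# precedence for picking the "best" verdict against a multi-EC reference entry
_PRECEDENCE = {
    RelationKind.IDENTICAL: 0,
    RelationKind.PRED_SPECIALIZES_REF: 1,
    RelationKind.PRED_GENERALIZES_REF: 2,
    RelationKind.DIVERGENT: 3,
}


def relation_to_set(pred: ECNumber, refs: Iterable[ECNumber]) -> Relation:
    """Best relation of ``pred`` against a set of reference ECs.

    Reference database entries can carry several EC numbers; the rubric
    needs a single verdict. Precedence: identical > specializes >
    generalizes > divergent; among divergent relations the deepest
    divergence level (largest shared prefix) wins. An empty set is
    ``no_reference``.
    """
    best: Optional[Relation] = None
    for ref in refs:
        r = relation(pred, ref)
        if best is None:
            best = r
            continue
        pa, pb = _PRECEDENCE[r.kind], _PRECEDENCE[best.kind]
        if pa < pb or (pa == pb and r.kind is RelationKind.DIVERGENT and r.k > best.k):  # type: ignore[operator]
            best = r
    return best if best is not None else Relation(RelationKind.NO_REFERENCE)


def enumerate_ecs(max_level: int = 2, depths: Sequence[int] = (1, 2, 3, 4)) -> list[ECNumber]:
    """Small exhaustive enumeration of EC numbers for property tests."""
    out: list[ECNumber] = []
    for d in depths:
        for combo in itertools.product(range(1, max_level + 1), repeat=d):
            out.append(ECNumber(combo))
    return out
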