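"""Domain types for SRS microdata and the generalization lattice.

A quasi-identifier (QID) value is a tuple with one entry per schema
attribute: a closed numeric interval ``(lo, hi)`` for numeric attributes,
or a taxonomy node label for categorical ones.  ``covers`` is the partial
order "equal to or more generalized than"; ``lub`` is the least value
covering a collection (interval hull / lowest common ancestor).

Information loss of a QID group g follows the standard clustering-based
measure:

    IL(g) = |g| * [ sum_num (max(N_i,g)-min(N_i,g)) / (max(N_i)-min(N_i))
                  + sum_cat h(C_j,g) / h(C_j) ]

where the numeric spans are normalized by the global attribute range and
h(C_j,g) is the height (from the leaf level) of the group's generalized
taxonomy node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .taxonomy import TaxonomyTree

Interval = tuple[float, float]
QIDValue = tuple  # per-attribute: Interval for numeric, str label for categorical


class SchemaError(ValueError):
    """QID values defined on mismatched or invalid attribute schemas."""


@dataclass(frozen=True)
class AttributeSchema:
    """One QID attribute: numeric with a global range, or categorical with
    a taxonomy tree rooted at ``ANY``."""

    name: str
    kind: str  # "numeric" | "categorical"
    global_min: Optional[float] = None
    global_max: Optional[float] = None
    taxonomy: Optional[TaxonomyTree] = None

    def __post_init__(self) -> None:
        if self.kind == "numeric":
            if self.global_min is None or self.global_max is None:
                raise SchemaError(f"{self.name}: numeric attribute needs a global range")
            if not self.global_min < self.global_max:
                raise SchemaError(f"{self.name}: zero-width global numeric range")
        elif self.kind == "categorical":
            if self.taxonomy is None:
                raise SchemaError(f"{self.name}: categorical attribute needs a taxonomy")
            if self.taxonomy.height < 1:
                raise SchemaError(f"{self.name}: taxonomy height must be positive")
        else:
            raise SchemaError(f"{self.name}: unknown attribute kind {self.kind!r}")

    @property
    def global_range(self) -> float:
        return float(self.global_max) - float(self.global_min)


Schema = tuple[AttributeSchema, ...]


def _check_value(schema: Schema, q: QIDValue) -> None:
    if len(q) != len(schema):
        raise SchemaError(f"QID value arity {len(q)} != schema arity {len(schema)}")


def make_qid(schema: Schema, raw: Sequence) -> QIDValue:
    """Normalize raw per-attribute values into a QID tuple.

    Numeric scalars become degenerate intervals ``(x, x)``; intervals and
    labels are validated against the schema.
    """
    out = []
    for attr, v in zip(schema, raw, strict=True):
        if attr.kind == "numeric":
            if isinstance(v, (tuple, list)):
                lo, hi = float(v[0]), float(v[1])
            else:
                lo = hi = float(v)
            if lo > hi:
                raise SchemaError(f"{attr.name}: interval lo > hi ({lo}, {hi})")
            out.append((lo, hi))
        else:
            if v not in attr.taxonomy.nodes:
                raise SchemaError(f"{attr.name}: unknown taxonomy node {v!r}")
            out.append(v)
    return tuple(out)


def is_leaf_qid(schema: Schema, q: QIDValue) -> bool:
    """True iff every attribute is at its most specific level."""
    for attr, v in zip(schema, q, strict=True):
        if attr.kind == "numeric":
            if v[0] != v[1]:
                return False
        elif not attr.taxonomy.is_leaf(v):
            return False
    return True


def covers(schema: Schema, q1: QIDValue, q2: QIDValue) -> bool:
    """``q1`` is equal to or more generalized than ``q2`` on every attribute.

    Numeric: the interval of q1 contains that of q2 (closed, inclusive).
    Categorical: q1's node equals q2's node or is an ancestor of it.
    """
    _check_value(schema, q1)
    _check_value(schema, q2)
    for attr, a, b in zip(schema, q1, q2):
        if attr.kind == "numeric":
            if not (a[0] <= b[0] and b[1] <= a[1]):
                return False
        else:
            if not attr.taxonomy.is_ancestor_or_self(a, b):
                return False
    return True


def lub(schema: Schema, values: Sequence[QIDValue]) -> QIDValue:
    """Least value covering every input: interval hull for numeric
    attributes, lowest common ancestor for categorical ones."""
    values = list(values)
    if not values:
        raise ValueError("lub of empty collection")
    for q in values:
        _check_value(schema, q)
    out = []
    for i, attr in enumerate(schema):
        col = [q[i] for q in values]
        if attr.kind == "numeric":
            out.append((min(v[0] for v in col), max(v[1] for v in col)))
        else:
            out.append(attr.taxonomy.lca(col))
    return tuple(out)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SRSRecord:
    """One adverse-event report.

    ``case_id`` is the follow-up key: all records sharing it, in the same
    or different quarters, refer to the same event/person.  ``qid`` is at
    the leaf level in raw data and generalized in a published release.
    """

    case_id: int
    quarter: int
    qid: QIDValue
    drugs: frozenset[str] = frozenset()
    sensitive: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.quarter < 1:
            raise ValueError("quarter must be >= 1")


@dataclass(frozen=True)
class SuperRecord:
    """Merger of all same-CaseID records within one quarter.

    The merged QID is the least-common generalization of the member QIDs;
    the sensitive set is the union.  Super records keep follow-up rows of
    one event together so a group never splits an event.
    """

    case_id: int
    quarter: int
    qid: QIDValue
    members: tuple[SRSRecord, ...]
    sensitive: frozenset[str]
    drugs: frozenset[str]


@dataclass
class QIDGroup:
    """A cluster of (super) records published under one generalized QID.

    ``nc_count`` is the number of members whose CaseID is new in this
    period; ``sigma`` maps each sensitive term s to sigma_s(g), the number
    of cases in g containing s.
    """

    generalized_qid: QIDValue
    members: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def sigma(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            for s in m.sensitive:
                counts[s] = counts.get(s, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Information loss
# ---------------------------------------------------------------------------


def qid_il_per_record(schema: Schema, q: QIDValue) -> float:
    """Per-record information loss of one generalized QID value
    (the bracketed sum in IL; in [0, |QID|])."""
    total = 0.0
    for attr, v in zip(schema, q, strict=True):
        if attr.kind == "numeric":
            total += (v[1] - v[0]) / attr.global_range
        else:
            total += attr.taxonomy.node_height(v) / attr.taxonomy.height
    return total


def group_il(schema: Schema, g: QIDGroup) -> float:
    """IL(g) = |g| * per-record loss of the group's generalized QID.

    Ranges over [0, |g| * |QID|]: 0 for an ungeneralized leaf group,
    the maximum when every attribute is generalized to its root/global
    range.
    """
    return g.size * qid_il_per_record(schema, g.generalized_qid)


def il_of(schema: Schema, qids: Sequence[QIDValue]) -> float:
    """IL of the group that the given member QIDs would form."""
    return len(qids) * qid_il_per_record(schema, lub(schema, qids))


def delta_il(schema: Schema, g: QIDGroup, r) -> float:
    """Increase in information loss caused by adding record ``r`` to group
    ``g``: the widening of the group's generalization, charged to all
    |g| + 1 members,

        delta_IL(g, r) = (|g| + 1) * (L(g ∪ {r}) - L(g))

    with L the per-record loss of the generalized QID.  Nonnegative, and
    exactly zero when the group's QID already covers r's (an addition that
    widens nothing is free, whatever the group's current width — the
    property the new-cases-first grouping refinement relies on)."""
    merged = lub(schema, [g.generalized_qid, r.qid])
    widened = qid_il_per_record(schema, merged) - qid_il_per_record(schema, g.generalized_qid)
    return (g.size + 1) * widened
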