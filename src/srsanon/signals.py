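"""ADR-signal utility: PRR disproportionality on raw vs anonymized data.

A demographic-conditioned ADR rule ("drug, condition -> reaction") is
evaluated on the subpopulation of reports whose QID value *entails* the
condition: a generalized value counts only when every leaf consistent with
it satisfies the condition, so generalization can only remove reports from
the 2x2 table (the "missing count" effect).  Within that subpopulation:

    a = drug & reaction      b = drug & ~reaction
    c = ~drug & reaction     d = neither

    PRR = (a / (a + b)) / (c / (c + d))

The minimum signal criterion is a >= 3 and PRR > 2; PRR is forced to 0 when
a < 3, so that a rare rule losing even one count to generalization is
invalidated outright.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import QIDValue, Schema

_OPS = (">", ">=", "<", "<=", "==")


@dataclass(frozen=True)
class ADRRule:
    """drug, condition-on-one-QID-attribute -> reaction."""

    drug: str
    reaction: str
    attribute: str
    op: str
    value: object  # number for numeric attributes, label for categorical

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")


@dataclass(frozen=True)
class SignalResult:
    a: int
    b: int
    c: int
    d: int
    prr: float

    @property
    def valid(self) -> bool:
        return self.a >= 3 and self.prr > 2.0


def condition_entails(schema: Schema, qid: QIDValue, rule: ADRRule) -> bool:
    """True iff every leaf consistent with the (possibly generalized) QID
    value satisfies the rule's condition — entailment, not overlap."""
    names = [a.name for a in schema]
    if rule.attribute not in names:
        raise ValueError(f"unknown attribute {rule.attribute!r}")
    ai = names.index(rule.attribute)
    attr, v = schema[ai], qid[ai]
    if attr.kind == "numeric":
        lo, hi = v
        t = float(rule.value)
        if rule.op == ">":
            return lo > t
        if rule.op == ">=":
            return lo >= t
        if rule.op == "<":
            return hi < t
        if rule.op == "<=":
            return hi <= t
        return lo == hi == t  # ==
    # categorical: only equality conditions are meaningful; entailed iff
    # every leaf under the node lies under the condition's node
    if rule.op != "==":
        raise ValueError(f"operator {rule.op!r} invalid for categorical attribute")
    return attr.taxonomy.is_ancestor_or_self(str(rule.value), v)


def prr(a: int, b: int, c: int, d: int) -> float:
    """Proportional reporting ratio; forced to 0 when a < 3."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative contingency cell")
    if a < 3:
        return 0.0
    if a + b == 0 or c + d == 0:
        raise ValueError("PRR undefined: empty margin in the 2x2 table")
    rate_drug = a / (a + b)
    rate_rest = c / (c + d)
    if rate_rest == 0:
        raise ValueError("PRR undefined: zero reaction rate among other drugs")
    return rate_drug / rate_rest


def _case_level(rows):
    """Collapse same-CaseID rows within the dataset to one case each
    (union of drugs/reactions; any member QID entailing the condition is
    resolved at the merged level by requiring all rows to share the QID —
    published rows of one case in one quarter always do)."""
    by_case: dict[int, list] = {}
    for r in rows:
        by_case.setdefault(r.case_id, []).append(r)
    out = []
    for cid in sorted(by_case):
        grp = by_case[cid]
        out.append((cid, grp[0].qid,
                    frozenset().union(*(g.drugs for g in grp)),
                    frozenset().union(*(g.sensitive for g in grp))))
    return out


def evaluate_rule(schema: Schema, rows, rule: ADRRule) -> SignalResult:
    """Tabulate the rule's 2x2 table over the condition-entailing cases of a
    dataset (raw or anonymized rows carrying qid, drugs, sensitive)."""
    drug = rule.drug.casefold()
    reaction = rule.reaction.casefold()
    a = b = c = d = 0
    for _, qid, drugs, reactions in _case_level(rows):
        if not condition_entails(schema, qid, rule):
            continue
        has_drug = drug in {x.casefold() for x in drugs}
        has_react = reaction in {x.casefold() for x in reactions}
        if has_drug and has_react:
            a += 1
        elif has_drug:
            b += 1
        elif has_react:
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise ValueError("empty condition-entailing subpopulation")
    return SignalResult(a=a, b=b, c=c, d=d, prr=prr(a, b, c, d))


def signal_bias(schema: Schema, raw_rows, anon_rows, rule: ADRRule
                ) -> tuple[int, float]:
    """(count delta, PRR delta) of the anonymized data against the raw data
    for one rule: anonymized minus raw."""
    raw = evaluate_rule(schema, raw_rows, rule)
    anon = evaluate_rule(schema, anon_rows, rule)
    return anon.a - raw.a, anon.prr - raw.prr
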