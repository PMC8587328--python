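"""Cross-release linkage attacks on follow-up CaseIDs (BFL-attacks).

The attacker knows a target's true leaf QID value q^v and the release R_i
holding the target's record, links into the target's QID group to obtain
the candidate CaseID set CI, and then prunes CI using the other releases:

* Backward-attack (B): a candidate whose record in some *previous* release
  carries a published QID that does not cover q^v cannot be the target.
* Forward-attack (F): likewise using *subsequent* releases.
* Latest-attack (L): when the attacker also knows the target's event first
  appears in R_i, every candidate CaseID already seen in a previous release
  can be excluded.

The auditor plays the strongest such attacker against every record of every
release and reports the effective anonymity |CI - (B ∪ F ∪ L)| and the
post-exclusion confidences per sensitive term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import QIDValue, covers
from .series import PublishedRecord, ReleaseSeries


@dataclass
class AttackFinding:
    """Result of auditing one target in one release."""

    release_index: int                 # 0-based index of R_i
    case_id: int                       # the target's own CaseID
    group_qid: QIDValue
    ci: frozenset[int]
    b_set: frozenset[int]
    f_set: frozenset[int]
    l_set: frozenset[int]
    confidences: dict[str, float] = field(default_factory=dict)

    @property
    def excluded(self) -> frozenset[int]:
        return self.b_set | self.f_set | self.l_set

    @property
    def effective_ci(self) -> frozenset[int]:
        return self.ci - self.excluded

    @property
    def effective_anonymity(self) -> int:
        return len(self.effective_ci)

    def max_confidence(self) -> tuple[Optional[str], float]:
        if not self.confidences:
            return None, 0.0
        term = max(sorted(self.confidences), key=lambda s: self.confidences[s])
        return term, self.confidences[term]


class AuditError(ValueError):
    pass


def _candidate_group(series: ReleaseSeries, i: int, qv: QIDValue,
                     case_id: Optional[int] = None) -> tuple[QIDValue, list[PublishedRecord]]:
    """The QID group in R_i the attacker links the target into.

    With ``case_id`` given (audit mode) it is the group of that case's
    records; otherwise the unique group whose published QID covers q^v.
    """
    groups = series[i].groups()
    if case_id is not None:
        for gq, members in groups.items():
            if any(r.case_id == case_id for r in members):
                return gq, members
        raise AuditError(f"case {case_id} not found in release {i + 1}")
    matching = [(gq, m) for gq, m in groups.items() if covers(series.schema, gq, qv)]
    if not matching:
        raise AuditError(f"no QID group in release {i + 1} covers the target value")
    if len(matching) > 1:
        raise AuditError("ambiguous target: several groups cover the QID value; "
                         "pass the target's case_id to disambiguate")
    return matching[0]


def b_attack(series: ReleaseSeries, i: int, qv: QIDValue,
             ci, *, occurrences=None) -> frozenset[int]:
    """CaseIDs in CI excludable via previous releases R_1..R_{i-1}: some
    record of theirs was published with a QID not covering q^v."""
    if occurrences is None:
        occurrences = series.case_occurrences()
    out = set()
    for c in ci:
        for j, rec in occurrences.get(c, ()):
            if j < i and not covers(series.schema, rec.qid, qv):
                out.add(c)
                break
    return frozenset(out)


def f_attack(series: ReleaseSeries, i: int, qv: QIDValue,
             ci, *, occurrences=None) -> frozenset[int]:
    """Mirror of the B-attack over subsequent releases R_{i+1}..R_n."""
    if occurrences is None:
        occurrences = series.case_occurrences()
    out = set()
    for c in ci:
        for j, rec in occurrences.get(c, ()):
            if j > i and not covers(series.schema, rec.qid, qv):
                out.add(c)
                break
    return frozenset(out)


def l_attack(series: ReleaseSeries, i: int, ci, *,
             target_first_seen_here: bool = True, occurrences=None) -> frozenset[int]:
    """CaseIDs in CI already present in a previous release; applicable only
    when the attacker knows the target's event first appears in R_i."""
    if not target_first_seen_here:
        return frozenset()
    if occurrences is None:
        occurrences = series.case_occurrences()
    return frozenset(c for c in ci
                     if any(j < i for j, _ in occurrences.get(c, ())))


def attack_target(series: ReleaseSeries, i: int, qv: QIDValue, *,
                  case_id: Optional[int] = None,
                  first_seen_here: bool = False,
                  occurrences=None) -> AttackFinding:
    """Run the full BFL exclusion for a single target and compute the
    post-exclusion confidence of every sensitive term over the surviving
    candidate cases."""
    if occurrences is None:
        occurrences = series.case_occurrences()
    gq, members = _candidate_group(series, i, qv, case_id)
    ci = frozenset(r.case_id for r in members)
    b = b_attack(series, i, qv, ci, occurrences=occurrences)
    f = f_attack(series, i, qv, ci, occurrences=occurrences)
    l = l_attack(series, i, ci, target_first_seen_here=first_seen_here,
                 occurrences=occurrences)
    finding = AttackFinding(
        release_index=i,
        case_id=case_id if case_id is not None else -1,
        group_qid=gq, ci=ci, b_set=b, f_set=f, l_set=l,
    )
    remaining = finding.effective_ci
    if remaining:
        terms: dict[str, set[int]] = {}
        for r in members:
            if r.case_id in remaining:
                for s in r.sensitive:
                    terms.setdefault(s, set()).add(r.case_id)
        finding.confidences = {s: len(cs) / len(remaining) for s, cs in terms.items()}
    return finding


def audit_series(series: ReleaseSeries) -> list[AttackFinding]:
    """Audit every record of every release as a target.

    B/F-attacks use the record's true leaf QID (which every record in an
    auditable series must carry); the L-attack is evaluated only for
    targets whose CaseID is genuinely new in their release.
    """
    occurrences = series.case_occurrences()
    first_seen = series.first_release_of_case()
    findings: list[AttackFinding] = []
    for i, rel in enumerate(series.releases):
        seen_cases: set[int] = set()
        for rec in rel.records:
            if rec.case_id in seen_cases:
                continue  # one finding per case per release
            seen_cases.add(rec.case_id)
            if rec.leaf_qid is None:
                raise AuditError(
                    f"record {rec.case_id} in release {i + 1} carries no leaf QID")
            findings.append(attack_target(
                series, i, rec.leaf_qid,
                case_id=rec.case_id,
                first_seen_here=first_seen[rec.case_id] == i,
                occurrences=occurrences,
            ))
    return findings
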