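"""Anonymization-quality metrics evaluated after the BFL audit.

* NIL — normalized information loss: the total group information loss of a
  release divided by |QID| times the number of records, in [0, 1].
* DIR — dangerous identity ratio: fraction of QID groups containing at
  least one audited target whose effective anonymity (candidate set after
  removing B ∪ F ∪ L) falls below k.
* DSR — dangerous sensitivity ratio: fraction of QID groups containing at
  least one audited target whose post-exclusion confidence for some
  sensitive term exceeds that term's threshold.

Groups are recovered from a published release as maximal sets of records
sharing an identical generalized QID value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .attacks import AttackFinding
from .model import QIDGroup, Schema, group_il
from .privacy import ThresholdMap
from .series import Release

_TOL = 1e-12


@dataclass(frozen=True)
class MetricsReport:
    nil: float
    dir: float
    dsr: float
    group_num: int
    dig_num: int
    dsg_num: int


def nil(schema: Schema, release: Release) -> float:
    """Average per-attribute, per-record information loss of a release."""
    if len(release) == 0:
        raise ValueError("NIL of an empty release is undefined")
    total = 0.0
    for gq, members in release.groups().items():
        total += group_il(schema, QIDGroup(generalized_qid=gq, members=members))
    return total / (len(schema) * len(release))


def _findings_by_group(release_index: int, findings: list[AttackFinding]):
    by_group: dict = {}
    for f in findings:
        if f.release_index == release_index:
            by_group.setdefault(f.group_qid, []).append(f)
    return by_group


def dir_ratio(release: Release, release_index: int,
              findings: list[AttackFinding], k: int) -> float:
    """Fraction of groups with some target at effective anonymity < k."""
    groups = release.groups()
    if not groups:
        return 0.0
    by_group = _findings_by_group(release_index, findings)
    dangerous = sum(
        1 for gq in groups
        if any(f.effective_anonymity < k for f in by_group.get(gq, ()))
    )
    return dangerous / len(groups)


def dsr_ratio(release: Release, release_index: int,
              findings: list[AttackFinding], thresholds: ThresholdMap) -> float:
    """Fraction of groups with some post-exclusion confidence above its
    term threshold."""
    groups = release.groups()
    if not groups:
        return 0.0
    by_group = _findings_by_group(release_index, findings)
    dangerous = 0
    for gq in groups:
        unsafe = any(
            conf > thresholds[s] + _TOL
            for f in by_group.get(gq, ())
            for s, conf in f.confidences.items()
        )
        dangerous += int(unsafe)
    return dangerous / len(groups)


def metrics_report(schema: Schema, release: Release, release_index: int,
                   findings: list[AttackFinding], k: int,
                   thresholds: ThresholdMap) -> MetricsReport:
    groups = release.groups()
    by_group = _findings_by_group(release_index, findings)
    dig = sum(1 for gq in groups
              if any(f.effective_anonymity < k for f in by_group.get(gq, ())))
    dsg = sum(1 for gq in groups
              if any(conf > thresholds[s] + _TOL
                     for f in by_group.get(gq, ())
                     for s, conf in f.confidences.items()))
    n = len(groups)
    return MetricsReport(
        nil=nil(schema, release),
        dir=dig / n if n else 0.0,
        dsr=dsg / n if n else 0.0,
        group_num=n, dig_num=dig, dsg_num=dsg,
    )
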