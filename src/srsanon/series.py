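"""Published releases and release series.

A release exposes, per record, only the CaseID and the generalized QID
(plus drugs / sensitive terms).  Groups are therefore recovered as maximal
sets of records sharing an identical generalized QID value — that is all a
release reveals.  For auditing, each record may additionally carry its true
leaf QID (oracle knowledge available to the data holder, and assumed known
to the strongest attacker for their own target).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import QIDValue, Schema


@dataclass(frozen=True)
class PublishedRecord:
    case_id: int
    quarter: int
    qid: QIDValue                      # generalized, as published
    drugs: frozenset[str] = frozenset()
    sensitive: frozenset[str] = frozenset()
    leaf_qid: Optional[QIDValue] = None  # true value; audit-time oracle only


@dataclass
class Release:
    """One anonymized quarterly table."""

    quarter: int
    records: list[PublishedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> dict[QIDValue, list[PublishedRecord]]:
        """Recover QID groups: records sharing an identical published QID."""
        out: dict[QIDValue, list[PublishedRecord]] = {}
        for r in self.records:
            out.setdefault(r.qid, []).append(r)
        return out

    def case_ids(self) -> set[int]:
        return {r.case_id for r in self.records}


@dataclass
class ReleaseSeries:
    """Ordered anonymized releases R_1..R_n over a fixed schema."""

    schema: Schema
    releases: list[Release] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.releases)

    def __getitem__(self, i: int) -> Release:
        return self.releases[i]

    def case_occurrences(self) -> dict[int, list[tuple[int, PublishedRecord]]]:
        """case_id -> [(release index, record), ...] in release order."""
        occ: dict[int, list[tuple[int, PublishedRecord]]] = {}
        for i, rel in enumerate(self.releases):
            for r in rel.records:
                occ.setdefault(r.case_id, []).append((i, r))
        return occ

    def first_release_of_case(self) -> dict[int, int]:
        first: dict[int, int] = {}
        for i, rel in enumerate(self.releases):
            for r in rel.records:
                first.setdefault(r.case_id, i)
        return first
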