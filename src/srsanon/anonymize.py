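"""Three-stage anonymization of a quarterly SRS stream.

Each raw quarter D_i is anonymized into a release R_i in three stages:

1.  *Covering* — same-CaseID rows are combined into super records; records
    whose CaseID already appeared in the recent published history (within
    the CaseID life span x) are "old cases" and have their QID generalized
    to cover a designated prior published occurrence, so the record can
    never be excluded from that earlier release by a Forward-attack:

    * ``ppms``   covers the *most recent* prior occurrence (by covering
      transitivity the whole chain back is then covered);
    * ``ppms+`` / ``ppms++`` cover only the *earliest* occurrence — the one
      release in which the case was new and hence actually at risk —
      avoiding accumulated generalization;
    * ``ms`` (single-release baseline) performs no covering.

2.  *Grouping* — greedy clustering builds QID groups, growing each from a
    seed record by repeatedly adding the record with minimal
    delta-IL'(g, r) until the group holds at least k new-CaseID members
    (NC-bounding; the ``ms`` baseline requires total size >= k instead) and
    every sensitive term is within its occurrence bound.  ``ppms++`` groups
    only new cases, deferring old cases entirely to stage 3.

3.  *Generalization* — leftover records (and, for ``ppms++``, the old
    cases) are assigned to the feasible group with minimal delta-IL';
    records with no feasible placement are suppressed.  Super records are
    split back into their original rows and every member's QID is replaced
    by the group's least-common generalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Schema, SRSRecord, SuperRecord, lub, qid_il_per_record
from .privacy import PrivacyParams
from .series import PublishedRecord, Release, ReleaseSeries

VARIANTS = ("ms", "ppms", "ppms+", "ppms++")

_EPS = 1e-9  # guards floor(theta * nc) against float fuzz


@dataclass(frozen=True)
class AnonymizerConfig:
    variant: str
    params: PrivacyParams

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")


@dataclass
class SuppressionLog:
    """Records that could not be placed, and release-level infeasibility."""

    suppressed: list[tuple[int, int, str]] = field(default_factory=list)  # (quarter, case_id, reason)
    infeasible_terms: dict[int, list[str]] = field(default_factory=dict)  # quarter -> terms

    def flag_quarter(self, quarter: int, terms: list[str]) -> None:
        self.infeasible_terms.setdefault(quarter, []).extend(terms)


# ---------------------------------------------------------------------------
# Stage 1: super records and QID covering
# ---------------------------------------------------------------------------


def combine_super_records(schema: Schema, records: list[SRSRecord]) -> list[SuperRecord]:
    """One super record per CaseID: QID = least-common generalization of the
    member QIDs, sensitive/drug sets = unions.  Output sorted by CaseID."""
    by_case: dict[int, list[SRSRecord]] = {}
    for r in records:
        by_case.setdefault(r.case_id, []).append(r)
    out = []
    for cid in sorted(by_case):
        members = tuple(by_case[cid])
        out.append(SuperRecord(
            case_id=cid,
            quarter=members[0].quarter,
            qid=lub(schema, [m.qid for m in members]),
            members=members,
            sensitive=frozenset().union(*(m.sensitive for m in members)),
            drugs=frozenset().union(*(m.drugs for m in members)),
        ))
    return out


def cover_old_cases(schema: Schema, supers: list[SuperRecord],
                    history: list[Release], variant: str, lifespan_x: int,
                    ) -> tuple[list[SuperRecord], dict[int, bool]]:
    """Generalize old cases' QIDs to cover their designated prior published
    occurrence; return the (possibly rewritten) supers and a map
    case_id -> is_new (new = absent from the last ``lifespan_x`` releases)."""
    window = history[-lifespan_x:] if lifespan_x > 0 else []
    published_qid: dict[int, list] = {}  # case_id -> [qid per window release, newest last]
    for rel in window:
        seen_here: dict[int, object] = {}
        for rec in rel.records:
            seen_here.setdefault(rec.case_id, rec.qid)
        for cid, q in seen_here.items():
            published_qid.setdefault(cid, []).append(q)
    is_new = {s.case_id: s.case_id not in published_qid for s in supers}
    if variant == "ms":
        return supers, is_new
    out = []
    for s in supers:
        if is_new[s.case_id]:
            out.append(s)
            continue
        occ = published_qid[s.case_id]
        # ppms: cover the most recent occurrence; ppms+/ppms++: the earliest
        target = occ[-1] if variant == "ppms" else occ[0]
        new_qid = lub(schema, [s.qid, target])
        out.append(SuperRecord(case_id=s.case_id, quarter=s.quarter, qid=new_qid,
                               members=s.members, sensitive=s.sensitive, drugs=s.drugs))
    return out, is_new


# ---------------------------------------------------------------------------
# Vectorized quarter engine
# ---------------------------------------------------------------------------


class _Quarter:
    """Array-backed view of one quarter's super records, supporting
    vectorized delta-IL' against an evolving group or a set of groups."""

    def __init__(self, schema: Schema, supers: list[SuperRecord],
                 is_new: dict[int, bool], thresholds, ms_semantics: bool):
        self.schema = schema
        self.supers = supers  # sorted by case_id
        self.n = len(supers)
        self.ms = ms_semantics
        self.case_ids = np.array([s.case_id for s in supers], dtype=np.int64)
        self.is_new = np.array(
            [True] * self.n if ms_semantics else [is_new[s.case_id] for s in supers])

        self.num_idx = [i for i, a in enumerate(schema) if a.kind == "numeric"]
        self.cat_idx = [i for i, a in enumerate(schema) if a.kind == "categorical"]
        self.num_rng = np.array([schema[i].global_range for i in self.num_idx])
        self.lo = np.array([[s.qid[i][0] for i in self.num_idx] for s in supers],
                           dtype=float).reshape(self.n, len(self.num_idx))
        self.hi = np.array([[s.qid[i][1] for i in self.num_idx] for s in supers],
                           dtype=float).reshape(self.n, len(self.num_idx))
        # per categorical attribute: node index arrays + LCA / height tables
        self.node_maps, self.lca_tabs, self.h_norm, self.nodes_of = [], [], [], []
        self.cat_codes = np.zeros((self.n, len(self.cat_idx)), dtype=np.int32)
        for j, ai in enumerate(self.cat_idx):
            tax = schema[ai].taxonomy
            nodes = sorted(tax.nodes)
            nmap = {lab: x for x, lab in enumerate(nodes)}
            nn = len(nodes)
            tab = np.zeros((nn, nn), dtype=np.int32)
            for x, a in enumerate(nodes):
                for y, b in enumerate(nodes):
                    tab[x, y] = nmap[tax.lca([a, b])]
            self.node_maps.append(nmap)
            self.nodes_of.append(nodes)
            self.lca_tabs.append(tab)
            self.h_norm.append(np.array([tax.node_height(lab) for lab in nodes],
                                        dtype=float) / tax.height)
            self.cat_codes[:, j] = [nmap[s.qid[ai]] for s in supers]

        # sensitive-term indexing
        terms = sorted({t for s in supers for t in s.sensitive})
        self.terms = terms
        self.tmap = {t: x for x, t in enumerate(terms)}
        self.theta = np.array([thresholds[t] for t in terms], dtype=float)
        self.unbounded = self.theta >= 1.0 - 1e-12
        rows, cols = [], []
        for i, s in enumerate(supers):
            for t in s.sensitive:
                rows.append(i)
                cols.append(self.tmap[t])
        from scipy import sparse
        self.M = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n, len(terms)))
        # during growth the occurrence bound is anticipated at the target
        # new-case count k: eta = floor(theta * 2) = 0 would otherwise block
        # every sensitive-term-carrying candidate before the group can reach
        # a size at which the bound is satisfiable.  Emission still requires
        # sigma_s <= floor(theta_s * |NC(g)|) at the actual count.
        self.k_anticipate = 1

    # -- group state -------------------------------------------------------

    def new_group(self, seed: int) -> dict:
        g = {
            "members": [seed],
            "lo": self.lo[seed].copy(), "hi": self.hi[seed].copy(),
            "cat": self.cat_codes[seed].copy(),
            "size": 1,
            "nc": int(self.is_new[seed]),
            "sigma": np.zeros(len(self.terms)),
        }
        g["sigma"][self.M[seed].indices] = 1.0
        return g

    def add_to_group(self, g: dict, i: int) -> None:
        g["members"].append(i)
        if self.num_idx:
            np.minimum(g["lo"], self.lo[i], out=g["lo"])
            np.maximum(g["hi"], self.hi[i], out=g["hi"])
        for j in range(len(self.cat_idx)):
            g["cat"][j] = self.lca_tabs[j][g["cat"][j], self.cat_codes[i, j]]
        g["size"] += 1
        g["nc"] += int(self.is_new[i])
        g["sigma"][self.M[i].indices] += 1.0

    def per_record_loss(self, g: dict) -> float:
        tot = 0.0
        if self.num_idx:
            tot += float(np.sum((g["hi"] - g["lo"]) / self.num_rng))
        for j in range(len(self.cat_idx)):
            tot += float(self.h_norm[j][g["cat"][j]])
        return tot

    def group_qid(self, g: dict):
        q = [None] * len(self.schema)
        for j, ai in enumerate(self.num_idx):
            q[ai] = (float(g["lo"][j]), float(g["hi"][j]))
        for j, ai in enumerate(self.cat_idx):
            q[ai] = self.nodes_of[j][g["cat"][j]]
        return tuple(q)

    def _eta(self, nc: int, size: int) -> np.ndarray:
        """Occurrence bounds per term; theta = 1 terms are bounded only by
        the group size (confidence can never exceed 1)."""
        eta = np.floor(self.theta * nc + _EPS)
        eta[self.unbounded] = size
        return eta

    def group_feasible(self, g: dict) -> bool:
        eta = self._eta(g["nc"] if not self.ms else g["size"], g["size"])
        return bool(np.all(g["sigma"] <= eta + _EPS))

    # -- vectorized candidate scoring ---------------------------------------

    def delta_il_vec(self, g: dict, cand: np.ndarray) -> np.ndarray:
        m = g["size"]
        loss_g = self.per_record_loss(g)
        new_loss = np.zeros(len(cand))
        if self.num_idx:
            lo = np.minimum(g["lo"], self.lo[cand])
            hi = np.maximum(g["hi"], self.hi[cand])
            new_loss += ((hi - lo) / self.num_rng).sum(axis=1)
        for j in range(len(self.cat_idx)):
            merged = self.lca_tabs[j][g["cat"][j], self.cat_codes[cand, j]]
            new_loss += self.h_norm[j][merged]
        # widening charged to all m+1 members; zero for covered candidates
        return (m + 1) * (new_loss - loss_g)

    def pr_vec(self, g: dict, cand: np.ndarray) -> np.ndarray:
        """Privacy risk of adding each candidate: 1 + sum over the
        candidate's terms of (sigma+1)/(eta' - sigma); +inf past a bound."""
        sigma = g["sigma"]
        size_after = g["size"] + 1
        out = np.empty(len(cand))
        for newness in (True, False):
            sel = self.is_new[cand] == newness
            if not np.any(sel):
                continue
            nc_after = (g["nc"] + int(newness)) if not self.ms else size_after
            eta = self._eta(max(nc_after, self.k_anticipate), size_after)
            room = eta - sigma            # eta' - sigma(g) = eta' - sigma_after + 1
            bad = room < 1.0 - _EPS       # sigma_after would exceed eta'
            val = np.where(bad, 0.0, (sigma + 1.0) / np.maximum(room, 1.0 - _EPS))
            sub = cand[sel]
            contrib = self.M[sub] @ val
            nbad = self.M[sub] @ bad.astype(float)
            pr = 1.0 + contrib
            pr[nbad > 0] = math.inf
            out[sel] = pr
        return out

    def delta_il_prime_vec(self, g: dict, cand: np.ndarray) -> np.ndarray:
        dil = self.delta_il_vec(g, cand)
        pr = self.pr_vec(g, cand)
        blocked = np.isinf(pr)
        out = dil * np.where(blocked, 1.0, pr)
        out[blocked] = math.inf  # infeasible even at zero widening
        return out


# ---------------------------------------------------------------------------
# Stage 2: grouping
# ---------------------------------------------------------------------------


def _grouping(q: _Quarter, k: int, rng: np.random.Generator,
              allowed: np.ndarray | None = None) -> tuple[list[dict], list[int]]:
    """Form as many valid groups as possible out of the allowed records;
    return (groups, leftover indices)."""
    remaining = allowed.copy() if allowed is not None else np.ones(q.n, dtype=bool)
    groups: list[dict] = []
    last_added: int | None = None

    def requirement_met(g: dict) -> bool:
        base = g["size"] >= k if q.ms else g["nc"] >= k
        return base and q.group_feasible(g)

    def stop_now() -> bool:
        idx = np.flatnonzero(remaining)
        if len(idx) == 0:
            return True
        n_new = int(np.count_nonzero(q.is_new[idx])) if not q.ms else len(idx)
        if n_new < k:
            return True
        # remaining-pool feasibility: any bounded term over its threshold
        sigma_rem = np.asarray(q.M[idx].sum(axis=0)).ravel()
        eta_rem = np.floor(q.theta * n_new + _EPS)
        over = (sigma_rem > eta_rem + _EPS) & ~q.unbounded
        return bool(np.any(over))

    while not stop_now():
        idx = np.flatnonzero(remaining)
        if last_added is None:
            seed = int(rng.choice(idx))
        else:
            # next seed: record most distinguished from the last-added one,
            # measured by the pair's information-loss increase
            pair = q.new_group(last_added)
            dil = q.delta_il_vec(pair, idx)
            seed = int(idx[int(np.argmax(dil))])
        g = q.new_group(seed)
        remaining[seed] = False
        failed = False
        while not requirement_met(g):
            cand = np.flatnonzero(remaining)
            if len(cand) == 0:
                failed = True
                break
            scores = q.delta_il_prime_vec(g, cand)
            best = int(np.argmin(scores))
            if math.isinf(scores[best]):
                failed = True
                break
            pick = int(cand[best])
            q.add_to_group(g, pick)
            remaining[pick] = False
            last_added = pick
        if failed:
            # return members to the pool and stop forming groups
            for m in g["members"]:
                remaining[m] = True
            break
        groups.append(g)
        last_added = g["members"][-1]
    return groups, [int(i) for i in np.flatnonzero(remaining)]


# ---------------------------------------------------------------------------
# Stage 3: generalization
# ---------------------------------------------------------------------------


class _GroupBank:
    """All formed groups stacked into arrays so a record's delta-IL' against
    every group is one vectorized pass."""

    def __init__(self, q: _Quarter, groups: list[dict]):
        self.q = q
        self.members = [list(g["members"]) for g in groups]
        G = len(groups)
        n_num, n_cat = len(q.num_idx), len(q.cat_idx)
        self.lo = (np.stack([g["lo"] for g in groups]) if groups
                   else np.zeros((0, n_num))).reshape(G, n_num)
        self.hi = (np.stack([g["hi"] for g in groups]) if groups
                   else np.zeros((0, n_num))).reshape(G, n_num)
        self.cat = (np.stack([g["cat"] for g in groups]) if groups
                    else np.zeros((0, n_cat), dtype=np.int32)).reshape(G, n_cat)
        self.size = np.array([g["size"] for g in groups], dtype=np.int64)
        self.nc = np.array([g["nc"] for g in groups], dtype=np.int64)
        self.sig = (np.stack([g["sigma"] for g in groups]) if groups
                    else np.zeros((0, len(q.terms)))).reshape(G, len(q.terms))
        self.loss = self._loss_all()

    def __len__(self) -> int:
        return len(self.members)

    def _loss_all(self) -> np.ndarray:
        q = self.q
        loss = np.zeros(len(self.members))
        if q.num_idx:
            loss += ((self.hi - self.lo) / q.num_rng).sum(axis=1)
        for j in range(len(q.cat_idx)):
            loss += q.h_norm[j][self.cat[:, j]]
        return loss

    def best_placement(self, i: int) -> tuple[int | None, float]:
        """Group index minimizing delta-IL'(g, record i), or None when every
        placement is theta-infeasible."""
        q = self.q
        new_loss = np.zeros(len(self.members))
        if q.num_idx:
            lo = np.minimum(self.lo, q.lo[i])
            hi = np.maximum(self.hi, q.hi[i])
            new_loss += ((hi - lo) / q.num_rng).sum(axis=1)
        merged_cats = []
        for j in range(len(q.cat_idx)):
            merged = q.lca_tabs[j][self.cat[:, j], q.cat_codes[i, j]]
            merged_cats.append(merged)
            new_loss += q.h_norm[j][merged]
        dil = (self.size + 1) * (new_loss - self.loss)
        nc_after = self.nc + int(q.is_new[i]) if not q.ms else self.size + 1
        nc_eff = np.maximum(nc_after, q.k_anticipate)
        pr = np.ones(len(self.members))
        bad = np.zeros(len(self.members), dtype=bool)
        for t in q.M[i].indices:
            if q.unbounded[t]:
                eta = (self.size + 1).astype(float)
            else:
                eta = np.floor(q.theta[t] * nc_eff + _EPS)
            room = eta - self.sig[:, t]
            term_bad = room < 1.0 - _EPS
            bad |= term_bad
            pr += np.where(term_bad, 0.0, (self.sig[:, t] + 1.0) / np.maximum(room, 1.0))
        scores = dil * pr
        scores[bad] = math.inf
        gi = int(np.argmin(scores))
        if math.isinf(scores[gi]):
            return None, math.inf
        return gi, float(scores[gi])

    def place(self, gi: int, i: int) -> None:
        q = self.q
        self.members[gi].append(i)
        if q.num_idx:
            np.minimum(self.lo[gi], q.lo[i], out=self.lo[gi])
            np.maximum(self.hi[gi], q.hi[i], out=self.hi[gi])
        for j in range(len(q.cat_idx)):
            self.cat[gi, j] = q.lca_tabs[j][self.cat[gi, j], q.cat_codes[i, j]]
        self.size[gi] += 1
        self.nc[gi] += int(q.is_new[i])
        self.sig[gi, q.M[i].indices] += 1.0
        # refresh the cached per-record loss of this group
        loss = 0.0
        if q.num_idx:
            loss += float(((self.hi[gi] - self.lo[gi]) / q.num_rng).sum())
        for j in range(len(q.cat_idx)):
            loss += float(q.h_norm[j][self.cat[gi, j]])
        self.loss[gi] = loss

    def group_qid(self, gi: int):
        q = self.q
        out = [None] * len(q.schema)
        for j, ai in enumerate(q.num_idx):
            out[ai] = (float(self.lo[gi, j]), float(self.hi[gi, j]))
        for j, ai in enumerate(q.cat_idx):
            out[ai] = q.nodes_of[j][self.cat[gi, j]]
        return tuple(out)


def _generalization(q: _Quarter, bank: _GroupBank, to_place: list[int],
                    quarter: int, log: SuppressionLog) -> None:
    """Assign each remaining record to the feasible group with minimal
    delta-IL'; suppress records with no feasible placement."""
    for i in sorted(to_place, key=lambda i: int(q.case_ids[i])):
        if len(bank) == 0:
            log.suppressed.append((quarter, int(q.case_ids[i]), "no groups formed"))
            continue
        gi, score = bank.best_placement(i)
        if gi is None:
            log.suppressed.append(
                (quarter, int(q.case_ids[i]), "no theta-feasible placement"))
            continue
        bank.place(gi, i)


# ---------------------------------------------------------------------------
# Whole-quarter / whole-series driver
# ---------------------------------------------------------------------------


def check_quarter_feasibility(supers: list[SuperRecord], is_new: dict[int, bool],
                              thresholds) -> list[str]:
    """Terms s with sigma_s(D) / |NC(D)| > theta_s (theta_s < 1): no
    grouping of the quarter can satisfy the occurrence bounds for them."""
    nc = sum(1 for s in supers if is_new[s.case_id])
    counts: dict[str, int] = {}
    for s in supers:
        for t in s.sensitive:
            counts[t] = counts.get(t, 0) + 1
    bad = []
    for t, c in sorted(counts.items()):
        th = thresholds[t]
        if th >= 1.0:
            continue
        if nc == 0 or c > math.floor(th * nc + _EPS):
            bad.append(t)
    return bad


def anonymize_quarter(schema: Schema, records: list[SRSRecord], history: list[Release],
                      config: AnonymizerConfig, quarter: int, log: SuppressionLog,
                      rng: np.random.Generator, thresholds=None) -> Release:
    p = config.params
    thresholds = thresholds if thresholds is not None else p.thresholds
    supers = combine_super_records(schema, records)
    supers, is_new = cover_old_cases(schema, supers, history, config.variant, p.lifespan_x)
    if not supers:
        return Release(quarter=quarter, records=[])

    ms = config.variant == "ms"
    # the single-release baseline has no notion of old cases: its occurrence
    # bounds (and hence the feasibility diagnosis) run over all records
    feas_new = {s.case_id: True for s in supers} if ms else is_new
    bad_terms = check_quarter_feasibility(supers, feas_new, thresholds)
    if bad_terms:
        log.flag_quarter(quarter, bad_terms)
        for s in supers:
            log.suppressed.append((quarter, s.case_id, "quarter infeasible"))
        return Release(quarter=quarter, records=[])

    q = _Quarter(schema, supers, is_new, thresholds, ms_semantics=ms)
    q.k_anticipate = p.k

    # ppms++ groups new cases only; old cases go straight to generalization
    if config.variant == "ppms++":
        allowed = q.is_new.copy()
        held = [int(i) for i in np.flatnonzero(~q.is_new)]
    else:
        allowed = np.ones(q.n, dtype=bool)
        held = []

    groups, leftovers = _grouping(q, p.k, rng, allowed=allowed)
    bank = _GroupBank(q, groups)
    _generalization(q, bank, leftovers + held, quarter, log)

    out_records: list[PublishedRecord] = []
    for gi in range(len(bank)):
        gq = bank.group_qid(gi)
        for i in bank.members[gi]:
            sup = q.supers[i]
            for rec in sup.members:
                out_records.append(PublishedRecord(
                    case_id=rec.case_id, quarter=quarter, qid=gq,
                    drugs=rec.drugs, sensitive=rec.sensitive, leaf_qid=rec.qid))
    return Release(quarter=quarter, records=out_records)


def anonymize_series(schema: Schema, raw_quarters: list[list[SRSRecord]],
                     config: AnonymizerConfig,
                     per_quarter_thresholds=None) -> tuple[ReleaseSeries, SuppressionLog]:
    """Sequentially anonymize D_1..D_n; each quarter sees only the already
    published history.  Deterministic for a fixed rng_seed.

    ``per_quarter_thresholds`` (one ThresholdMap per quarter, e.g. from the
    frequency-based scheme) overrides the fixed map in the params.
    """
    if per_quarter_thresholds is not None and len(per_quarter_thresholds) != len(raw_quarters):
        raise ValueError("need one threshold map per quarter")
    log = SuppressionLog()
    series = ReleaseSeries(schema=schema, releases=[])
    for qi, records in enumerate(raw_quarters, start=1):
        rng = np.random.default_rng([config.params.rng_seed, qi])
        th = per_quarter_thresholds[qi - 1] if per_quarter_thresholds is not None else None
        rel = anonymize_quarter(schema, records, series.releases, config, qi, log, rng,
                                thresholds=th)
        series.releases.append(rel)
    return series, log


def term_counts(schema: Schema, records: list[SRSRecord]) -> dict[str, int]:
    """Case-level occurrence counts of sensitive terms in one raw quarter
    (input to the frequency-based threshold scheme)."""
    counts: dict[str, int] = {}
    for sup in combine_super_records(schema, records):
        for t in sup.sensitive:
            counts[t] = counts.get(t, 0) + 1
    return counts
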