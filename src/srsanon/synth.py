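"""Synthetic multi-quarter SRS streams and the worked three-quarter example.

The generator emulates the structural features that cross-release linkage
attacks exploit and that anonymization must survive:

* follow-up CaseIDs with gapped life spans — an event reported in one
  quarter may reappear in a later quarter, possibly skipping quarters,
  always with the same person's leaf QID;
* heavily skewed symptom frequencies (Zipf-ranked), multivalued per report;
* demographic-conditioned ADR rules planted at a chosen lift so signal
  recovery on raw vs anonymized data can be compared against ground truth.

It emits the same record objects the anonymizer consumes.  The
``worked_example_*`` functions return a small fixed three-quarter series of
18 cases (two groups per quarter, 3-anonymous per release) used throughout
the documentation: the published series is vulnerable to all three
cross-release attacks, and a companion series shows the repaired releases.
The named targets are Alice (CaseID 4, leaf {Female, 32}, quarter 2) and
John (CaseID 18, leaf {Male, 33}, first event in quarter 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import AttributeSchema, Schema, SRSRecord, make_qid
from .series import PublishedRecord, Release, ReleaseSeries
from .taxonomy import binary_gender_tree


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth ADR association: within the condition-satisfying
    subpopulation the (drug, reaction) pair is planted so its joint
    probability is ``lift`` times the independence baseline."""

    drug: str
    reaction: str
    attribute: str
    op: str
    value: object
    lift: float


@dataclass(frozen=True)
class SynthConfig:
    n_quarters: int = 6
    cases_per_quarter: int = 2000          # new cases per quarter
    followup_prob: float = 0.3             # per open prior case per quarter
    lifespan_max: int = 4                  # quarters a CaseID may reappear within
    gap_prob: float = 0.25                 # chance a due follow-up skips the quarter
    age_range: tuple[int, int] = (18, 85)
    female_prob: float = 0.5
    weight_mean: float = 70.0
    weight_sd: float = 15.0
    weight_range: tuple[float, float] = (30.0, 140.0)
    n_symptoms: int = 200
    zipf_exponent: float = 1.2
    extra_symptoms_mean: float = 0.7       # symptoms per case = 1 + Poisson(this)
    top_symptom_case_frac: float | None = None  # pin the top symptom's prevalence
    max_symptom_prevalence: float | None = None  # cap every symptom's per-case marginal
    n_drugs: int = 40
    drug_zipf: float = 1.0
    extra_drugs_mean: float = 0.3
    planted_rules: tuple[PlantedRule, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_quarters < 1 or self.cases_per_quarter < 1:
            raise ValueError("need at least one quarter and one case per quarter")
        if self.lifespan_max < 1:
            raise ValueError("lifespan_max must be >= 1")
        for p in (self.followup_prob, self.gap_prob, self.female_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.top_symptom_case_frac is not None and not 0 <= self.top_symptom_case_frac <= 1:
            raise ValueError("top_symptom_case_frac out of [0,1]")
        if self.max_symptom_prevalence is not None and not 0 < self.max_symptom_prevalence <= 1:
            raise ValueError("max_symptom_prevalence out of (0,1]")


def default_schema(config: SynthConfig | None = None) -> Schema:
    """Gender (two-level taxonomy), Age in years, Weight in kg."""
    c = config or SynthConfig()
    return (
        AttributeSchema(name="Gender", kind="categorical", taxonomy=binary_gender_tree()),
        AttributeSchema(name="Age", kind="numeric",
                        global_min=c.age_range[0], global_max=c.age_range[1]),
        AttributeSchema(name="Weight", kind="numeric",
                        global_min=c.weight_range[0], global_max=c.weight_range[1]),
    )


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def _draw_terms(rng: np.random.Generator, names: list[str], weights: np.ndarray,
                count: int) -> set[str]:
    count = min(count, len(names))
    idx = rng.choice(len(names), size=count, replace=False, p=weights)
    return {names[i] for i in idx}


def generate_series(config: SynthConfig) -> list[list[SRSRecord]]:
    """Raw quarters D_1..D_n (leaf-level QIDs), deterministic per seed."""
    schema = default_schema(config)
    rng = np.random.default_rng(config.rng_seed)
    sym_names = [f"SYM_{i:03d}" for i in range(config.n_symptoms)]
    drug_names = [f"DRUG_{i:02d}" for i in range(config.n_drugs)]
    sym_w = _zipf_weights(config.n_symptoms, config.zipf_exponent)
    drug_w = _zipf_weights(config.n_drugs, config.drug_zipf)

    mean_syms = 1.0 + config.extra_symptoms_mean
    if config.max_symptom_prevalence is not None:
        # cap every symptom's approximate per-case marginal 1-(1-w)^mean at
        # the requested prevalence by clipping the head of the Zipf weights
        w_max = 1.0 - (1.0 - config.max_symptom_prevalence) ** (1.0 / mean_syms)
        for _ in range(100):
            sym_w = sym_w / sym_w.sum()
            over = sym_w > w_max
            if not over.any():
                break
            sym_w = np.minimum(sym_w, w_max)
        sym_w = sym_w / sym_w.sum()

    top_frac = config.top_symptom_case_frac
    if top_frac is not None and config.n_symptoms > 1:
        sym_w_rest = sym_w.copy()
        sym_w_rest[0] = 0.0
        sym_w_rest /= sym_w_rest.sum()
    else:
        sym_w_rest = sym_w

    # analytic marginals for the planting probability (Poissonized approx.)
    mean_drugs = 1.0 + config.extra_drugs_mean
    marg_sym = 1.0 - np.exp(-mean_syms * sym_w)
    marg_drug = 1.0 - np.exp(-mean_drugs * drug_w)

    persons: dict[int, tuple] = {}      # case_id -> leaf qid
    drugs_of: dict[int, frozenset] = {}  # case_id -> drug set (stable per event)
    open_cases: list[tuple[int, int]] = []  # (case_id, birth quarter)
    quarters: list[list[SRSRecord]] = []
    next_id = 1

    def draw_symptoms() -> set[str]:
        m = 1 + rng.poisson(config.extra_symptoms_mean)
        if top_frac is None:
            return _draw_terms(rng, sym_names, sym_w, m)
        terms = _draw_terms(rng, sym_names[1:], sym_w_rest[1:] / sym_w_rest[1:].sum(), m)
        if rng.random() < top_frac:
            terms.add(sym_names[0])
        return terms

    for q in range(1, config.n_quarters + 1):
        records: list[SRSRecord] = []
        # follow-ups of open prior cases (gapped life spans)
        for cid, born in open_cases:
            if q - born >= config.lifespan_max:
                continue
            if rng.random() >= config.followup_prob:
                continue
            if rng.random() < config.gap_prob:
                continue  # skipped this quarter; may reappear later
            records.append(SRSRecord(
                case_id=cid, quarter=q, qid=persons[cid],
                drugs=drugs_of[cid], sensitive=frozenset(draw_symptoms())))
        # new cases
        for _ in range(config.cases_per_quarter):
            cid = next_id
            next_id += 1
            sex = "Female" if rng.random() < config.female_prob else "Male"
            age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
            weight = float(np.clip(round(rng.normal(config.weight_mean, config.weight_sd), 1),
                                   *config.weight_range))
            leaf = make_qid(schema, (sex, age, weight))
            persons[cid] = leaf
            drugs = _draw_terms(rng, drug_names, drug_w, 1 + rng.poisson(config.extra_drugs_mean))
            symptoms = draw_symptoms()
            # planted demographic-conditioned ADR rules
            for rule in config.planted_rules:
                from .signals import ADRRule, condition_entails
                cond = ADRRule(drug=rule.drug, reaction=rule.reaction,
                               attribute=rule.attribute, op=rule.op, value=rule.value)
                if not condition_entails(schema, leaf, cond):
                    continue
                di = drug_names.index(rule.drug) if rule.drug in drug_names else None
                si = sym_names.index(rule.reaction) if rule.reaction in sym_names else None
                base = (marg_drug[di] if di is not None else 0.02) * \
                       (marg_sym[si] if si is not None else 0.01)
                if rng.random() < min(1.0, (rule.lift - 1.0) * base):
                    drugs = drugs | {rule.drug}
                    symptoms = symptoms | {rule.reaction}
            drugs_of[cid] = frozenset(drugs)
            records.append(SRSRecord(case_id=cid, quarter=q, qid=leaf,
                                     drugs=frozenset(drugs), sensitive=frozenset(symptoms)))
            open_cases.append((cid, q))
        quarters.append(records)
    return quarters


# ---------------------------------------------------------------------------
# The three-quarter worked example
# ---------------------------------------------------------------------------

ALICE_QID = ("Female", (32.0, 32.0))   # CaseID 4, reported in quarters 1-2
JOHN_QID = ("Male", (33.0, 33.0))      # CaseID 18, first event in quarter 3
ALICE_CASE_ID = 4
JOHN_CASE_ID = 18


def example_schema() -> Schema:
    """Schema of the worked example: Gender + Age over [30, 40]."""
    return (
        AttributeSchema(name="Sex", kind="categorical", taxonomy=binary_gender_tree()),
        AttributeSchema(name="Age", kind="numeric", global_min=30, global_max=40),
    )


# (case_id, sex, age, disease) leaf rows per quarter.  Ages for unnamed cases
# are synthetic stand-ins chosen once, consistent with every published
# generalized value; Alice (4) and John (18) carry their stated leaves.
_RAW_ROWS = {
    1: [(1, "Male", 37, "Flu"), (2, "Male", 36, "Flu"), (3, "Male", 38, "Fever"),
        (4, "Female", 32, "HIV"), (5, "Female", 31, "Flu"), (6, "Female", 33, "Diabetes")],
    2: [(1, "Male", 37, "Flu"), (4, "Female", 32, "HIV"), (7, "Male", 34, "Diabetes"),
        (8, "Male", 30, "Fever"), (9, "Male", 31, "Flu"), (10, "Male", 32, "Diabetes"),
        (11, "Male", 34, "HIV"), (12, "Male", 35, "Flu")],
    3: [(13, "Female", 30, "Flu"), (14, "Female", 31, "Diabetes"), (15, "Female", 33, "Fever"),
        (16, "Female", 34, "Flu"), (17, "Female", 35, "Fever"), (7, "Male", 34, "Diabetes"),
        (8, "Male", 30, "Fever"), (18, "Male", 33, "HIV")],
}

# published generalized QIDs of the 3-anonymous (but BFL-vulnerable) series
_PUBLISHED_QIDS = {
    1: {1: ("Male", (35, 40)), 2: ("Male", (35, 40)), 3: ("Male", (35, 40)),
        4: ("Female", (30, 35)), 5: ("Female", (30, 35)), 6: ("Female", (30, 35))},
    2: {1: ("ANY", (30, 40)), 4: ("ANY", (30, 40)), 7: ("ANY", (30, 40)),
        8: ("Male", (30, 35)), 9: ("Male", (30, 35)), 10: ("Male", (30, 35)),
        11: ("Male", (30, 35)), 12: ("Male", (30, 35))},
    3: {13: ("Female", (30, 35)), 14: ("Female", (30, 35)), 15: ("Female", (30, 35)),
        16: ("Female", (30, 35)), 17: ("Female", (30, 35)),
        7: ("Male", (30, 35)), 8: ("Male", (30, 35)), 18: ("Male", (30, 35))},
}

# the repaired releases (quarter 1 unchanged; quarters 2-3 regrouped with
# NC-bounding and QID-covering; the source prints quarters 2 and 3 with
# swapped labels, matched here by content)
_PROTECTED_QIDS = {
    1: _PUBLISHED_QIDS[1],
    2: {1: ("ANY", (30, 40)), 4: ("ANY", (30, 40)), 7: ("ANY", (30, 40)),
        8: ("ANY", (30, 40)), 9: ("ANY", (30, 40)),
        10: ("Male", (30, 35)), 11: ("Male", (30, 35)), 12: ("Male", (30, 35))},
    3: {13: ("Female", (30, 35)), 14: ("Female", (30, 35)), 15: ("Female", (30, 35)),
        16: ("ANY", (30, 40)), 17: ("ANY", (30, 40)),
        7: ("ANY", (30, 40)), 8: ("ANY", (30, 40)), 18: ("ANY", (30, 40))},
}


def worked_example_raw() -> list[list[SRSRecord]]:
    """Leaf-level raw quarters D_1..D_3 of the worked example."""
    schema = example_schema()
    out = []
    for q in (1, 2, 3):
        out.append([SRSRecord(case_id=cid, quarter=q,
                              qid=make_qid(schema, (sex, age)),
                              sensitive=frozenset({disease}))
                    for cid, sex, age, disease in _RAW_ROWS[q]])
    return out


def _build_series(qids_by_quarter) -> ReleaseSeries:
    schema = example_schema()
    releases = []
    for q in (1, 2, 3):
        recs = []
        for cid, sex, age, disease in _RAW_ROWS[q]:
            recs.append(PublishedRecord(
                case_id=cid, quarter=q,
                qid=make_qid(schema, qids_by_quarter[q][cid]),
                sensitive=frozenset({disease}),
                leaf_qid=make_qid(schema, (sex, age))))
        releases.append(Release(quarter=q, records=recs))
    return ReleaseSeries(schema=schema, releases=releases)


def worked_example_published() -> ReleaseSeries:
    """The three printed 3-anonymous quarterly releases, per-release safe
    but vulnerable to the B-, F-, and L-attacks."""
    return _build_series(_PUBLISHED_QIDS)


def worked_example_protected() -> ReleaseSeries:
    """The repaired releases: every group keeps >= 3 new cases and old
    cases' QIDs cover their prior published values, so the full BFL audit
    leaves every target at effective anonymity >= 3."""
    return _build_series(_PROTECTED_QIDS)
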