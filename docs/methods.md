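# Methods

## Data model

A quarterly SRS table has one row per report: a CaseID (follow-up key; all rows sharing
it describe one event/person, within or across quarters), quasi-identifier (QID)
attributes — numeric (e.g. Weight in kg, Age in years) or categorical with a taxonomy
tree rooted at `ANY` — a drug set, and a multivalued sensitive set (indication/reaction
terms). Rows missing any QID or sensitive field are dropped at load time; true duplicate
reports (same event misfiled under different CaseIDs) are out of scope, as no mainstream
SRS deduplicates them either.

Generalized QID values are closed numeric intervals (containment inclusive at both ends;
the printed style `[30-35]`/`[35-40]` never disambiguates the shared bound, so the
inclusive convention was fixed here once) or taxonomy nodes. `covers` is the per-attribute
partial order "equal or more general"; `lub` is the least common generalization (interval
hull / lowest common ancestor). Numeric generalization uses min–max hulls; no numeric
hierarchy is imposed.

## Information loss

For a group g published under one generalized value, with L(q) the per-record loss

    L(q) = Σ_numeric (hi−lo)/(global range) + Σ_categorical h(node)/h(tree)

(node heights measured from the leaf level: leaf = 0, root = tree height), the group
loss is IL(g) = |g|·L(q) and the incremental cost of adding record r is

    ΔIL(g, r) = (|g|+1) · (L(g ∪ {r}) − L(g)).

The widening form (rather than the literal difference |g∪r|·L_new − |g|·L_old) makes an
addition that widens nothing free regardless of the group's current width — the property
the new-cases-first refinement (`ppms++`) relies on: adding a record already covered by
the group has ΔIL = 0.

The release-level metric is NIL = Σ_g IL(g) / (|QID| · #records) ∈ [0, 1].

## Privacy model

A series satisfies PPMS(k, θ\*)-bounding when every target's candidate CaseID set,
after removing the B/F/L-excludable CaseIDs, retains at least k members, and each
sensitive term's confidence stays within its threshold θ_s. Because the worst-case
attacker can exclude *every* old case from a group (they all appeared before), the
per-group occurrence bound is tied to new cases:

    η_s(g) = ⌊θ_s · |NC(g)|⌋,   feasible ⇔ σ_s(g) ≤ η_s(g),

where σ_s(g) counts cases in g containing s and NC(g) the CaseIDs new in this period
("new" = absent from the last x published releases; a CaseID older than the life-span
window counts as new, since neither the algorithm nor the attacker model looks further
back). Terms with θ_s = 1 are exempt from the bound: a confidence can never exceed 1,
and counting them against ⌊1·|NC|⌋ would spuriously reject groups rich in old cases.

The privacy risk of adding r to g is PR(g,r) = 1 + Σ_{s∈S_r} σ_s(g∪r)/(η_s(g∪r) −
σ_s(g∪r) + 1), infinite past a bound; the grouping objective is
ΔIL′ = ΔIL · PR (+∞ propagates even at ΔIL = 0). The "+1" offsets are fixed at one:
they only need to keep PR nonzero and preserve the ordering of Σ PR_s.

**Occurrence-bound anticipation.** Applied literally to an evolving 2-member group with
θ < 0.5, η = ⌊2θ⌋ = 0 blocks every candidate carrying any sensitive term and no group
could ever grow. During growth the engine therefore evaluates η at max(|NC|+1, k) — the
group is by construction grown to at least k new cases before emission — and re-checks
the exact bound σ_s ≤ ⌊θ_s·|NC(g)|⌋ on the final group (growing further if needed).
Emitted groups always satisfy the exact bound; only the intermediate pruning is
anticipatory.

## Anonymization pipeline

Per quarter, three stages:

1. **Covering.** Same-CaseID rows merge into super records (QID = lub of members,
   sensitive set = union) so an event is never split across groups. Old cases are
   generalized to cover a designated prior published occurrence: `ppms` covers the most
   recent one (covering transitivity then protects the whole chain), `ppms+`/`ppms++`
   only the earliest — the one release in which the case was new and hence genuinely at
   risk from the F-attack; later occurrences are already excludable as old cases anyway,
   so covering them buys nothing and only accumulates generalization.
2. **Grouping.** Greedy clustering: the first seed is drawn uniformly with the run's
   seeded generator; each group grows by argmin ΔIL′ (ties: smallest CaseID) until it
   holds ≥ k new CaseIDs (`ms`: total size ≥ k) and is feasible for every term; the next
   seed is the remaining record most distinguished from the last-added one, measured by
   the pair's ΔIL. Group formation stops when fewer than k new cases remain or some
   remaining term's ratio already exceeds its threshold. `ppms++` groups only new cases.
3. **Generalization.** Leftovers (and, for `ppms++`, all old cases) join the feasible
   group with minimal ΔIL′; records with no feasible placement are suppressed and
   logged. Super records split back to their original rows; every member publishes the
   group's lub.

A pre-check flags a term s with σ_s(D)/|NC(D)| > θ_s as globally infeasible: no grouping
of that quarter can meet the bound, the quarter is published empty and the term named in
the suppression log (the CLI exits nonzero). The `ms` baseline — single-release
semantics: no covering, total-size-k groups, bounds over |g| — exists to show nonzero
post-attack disclosure, not to reproduce its namesake in full.

All randomness flows through one seed; identical seeds give byte-identical releases
(the per-quarter generator is derived from (seed, quarter index)).

## Audit and metrics

The auditor plays the strongest attacker consistent with the attack definitions: it
knows every target's true leaf QID and, for the L-attack, whether the target's CaseID is
genuinely new in its release. Groups in a published release are recovered as maximal
sets of records with identical generalized QIDs — all a release exposes. A CaseID with
several records in another release is excluded if *any* of them fails the cover test.
DIR (resp. DSR) is the fraction of groups containing at least one audited target whose
effective anonymity falls below k (resp. whose post-exclusion confidence for some term
exceeds θ_s); a group counts once however many targets inside it are endangered, since
the ratio's denominator is the group count.

Under the guarantees above: new cases are never B/L-excludable (their CaseID has no
prior occurrence) and never F-excludable (covering), so the post-exclusion candidate set
contains all of NC(g); with σ_s(g) ≤ ⌊θ_s·|NC|⌋ the post-exclusion confidence is at most
θ_s. Hence DIR = DSR = 0 for all three periodical variants whenever every quarter passes
the global feasibility pre-check — the property the acceptance suite measures.

## Threshold schemes

* **uniform** — one θ for every term (0.2/0.4 are the conventional operating points).
* **frequency** — per quarter, with m and SD the mean and *population* standard
  deviation of the case-level term counts: below m−SD → 0.2, within one SD → 0.6, above
  m+SD → 1.0 (frequent terms are treated as non-sensitive). Population SD per quarter
  was chosen for determinism; scope and SD flavor are otherwise immaterial to the model.
* **levelwise** — user-supplied labels: high → 0.2, low → 0.4, non → 1.0. Mapping terms
  to medical sensitivity groups is the user's responsibility.

## Signal utility

For a rule *drug, condition → reaction* the 2×2 table is built within the
condition-*entailing* subpopulation: a generalized value counts only if every leaf
consistent with it satisfies the condition, so generalization can only shrink the
table ("missing counts"). Same-CaseID rows within a dataset count once (at the merged
case level), matching the super-record treatment. PRR = (a/(a+b))/(c/(c+d)); PRR is
forced to 0 when a < 3, so rare rules are invalidated outright by a single missing
count. Drug/reaction matching is exact after case-folding.

## Synthetic generator

`generate_series` emulates the structural features the method targets, not FAERS
content: each quarter adds `cases_per_quarter` new cases (person-level Gender/Age/Weight
drawn once and reused by all follow-ups — exactly the invariant the attacks exploit);
open cases reappear within `lifespan_max` quarters with probability `followup_prob`,
skipping a due quarter with probability `gap_prob` (gapped life spans); symptoms are
Zipf-ranked (`n_symptoms` = 200, exponent 1.2 by default) with 1 + Poisson(0.7) terms
per report; drugs likewise. `top_symptom_case_frac` pins the top symptom's per-case
prevalence exactly (for constructing infeasible regimes); `max_symptom_prevalence` caps
every symptom's approximate marginal by clipping the head of the Zipf weights (for
feasible regimes). Planted rules add a (drug, reaction) pair to condition-satisfying
cases with probability (lift−1)·p_drug·p_react, putting the joint at about `lift` times
the independence baseline (Poissonized marginal approximation).

What the generator does **not** emulate: FAERS's multi-file layout, real MedDRA term
structure, reporting-volume drift, missing-value patterns, or true duplicates. Passing
tests therefore demonstrate the model's guarantees and the algorithms' relative
behavior under controlled skew and follow-up structure, not performance on real FAERS
quarters.

## Problem sizes and study conditions

The guarantee checks run on 6 quarters × 2,000 new cases (≈ 17,000 records with
follow-ups), k = 5, lifespan 4, follow-up probability 0.3, uniform θ\* = 0.4 with the
symptom-prevalence cap at 0.15 so every per-quarter σ_s/|NC| (~0.25 worst case) sits
below θ — the feasible regime. The information-loss ordering of the refinements
(mean NIL: ppms++ ≤ ppms+ ≤ ppms) is a statistical property verified over 20 seeds at
150 new cases/quarter, a size at which 60 full anonymization runs remain cheap while the
ordering is already stable. The CaseID life span parameter x defaults to 8 quarters
(covering and newness only look that far back); the generator's 4-quarter life span sits
safely inside it.

## Known limitations

* Greedy clustering offers no optimality guarantee on NIL; seed choice matters only
  through the run seed.
* The auditor assumes leaf-level attacker knowledge for every record; weaker attackers
  (knowing only generalized values) are not modelled, so reported DIR/DSR are
  worst-case.
* A quarter failing the global feasibility pre-check is published empty rather than
  partially: utility for that quarter is sacrificed for an explicit diagnosis.
* Numeric serialization (`lo-hi`) assumes nonnegative values.
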