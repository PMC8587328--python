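"""Confidence, occurrence bounds, privacy risk, and threshold setting.

The privacy model bounds, for every published group g and sensitive term s,
the attacker's confidence conf(v -> s) = sigma_s(g)/|g| by a per-term
threshold theta_s, *after* cross-release exclusions.  Because the worst-case
attacker can exclude every old case from a group, the admissible occurrence
of s is tied to the number of new cases:

    eta_s(g) = floor(theta_s * |NC(g)|)

and g is theta-feasible for s iff sigma_s(g) <= eta_s(g).

During greedy clustering the candidate record minimizing

    delta_IL'(g, r) = delta_IL(g, r) * PR(g, r)

is added, where the privacy risk PR(g, r) = 1 + sum_{s in S_r} PR_s and

    PR_s = sigma_s(g+r) / (eta_s(g+r) - sigma_s(g+r) + 1)

is finite only while s stays within its bound (infinite otherwise), grows
with sigma_s, and so steers growth toward records whose sensitive terms are
rare in the group.  The "+1" increments avoid a zero product when all of
r's terms are new to g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdMap:
    """Per-term confidence thresholds theta_s in [0, 1] with a default for
    unseen terms (1.0 = unrestricted)."""

    thresholds: dict[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self) -> None:
        for s, t in self.thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ConfigError(f"theta for {s!r} out of [0,1]: {t}")
        if not 0.0 <= self.default <= 1.0:
            raise ConfigError(f"default theta out of [0,1]: {self.default}")

    def __getitem__(self, term: str) -> float:
        return self.thresholds.get(term, self.default)

    def items(self):
        return self.thresholds.items()

    @classmethod
    def uniform(cls, theta: float) -> "ThresholdMap":
        return cls(thresholds={}, default=theta)


@dataclass(frozen=True)
class PrivacyParams:
    """Run parameters: group-size requirement k (>= 2), per-term thresholds,
    the CaseID life span x in quarters (how far back follow-ups are
    searched), and the RNG seed for seed-record selection."""

    k: int
    thresholds: ThresholdMap
    lifespan_x: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.lifespan_x < 1:
            raise ConfigError("lifespan_x must be >= 1")


# ---------------------------------------------------------------------------
# Core quantities
# ---------------------------------------------------------------------------


def confidence(g, s: str) -> float:
    """conf(v -> s) = sigma_s(g) / |g| for a target residing in group g."""
    if g.size == 0:
        raise ValueError("confidence of an empty group")
    return g.sigma().get(s, 0) / g.size


def eta_bound(theta_s: float, nc_count: int) -> int:
    """Maximal number of cases in a group that may contain s without
    breaking theta_s once every old case is excluded:
    eta_s = floor(theta_s * |NC(g)|)."""
    if not 0.0 <= theta_s <= 1.0:
        raise ValueError(f"theta out of [0,1]: {theta_s}")
    if nc_count < 0:
        raise ValueError("negative new-case count")
    # guard float fuzz: floor(0.2*5) must be 1, not 0
    return math.floor(theta_s * nc_count + 1e-9)


def is_theta_feasible(sigma: dict[str, int], nc_count: int, thresholds: ThresholdMap) -> bool:
    """Group-level feasibility: sigma_s <= eta_s for every term present."""
    return all(c <= eta_bound(thresholds[s], nc_count) for s, c in sigma.items())


def privacy_risk_terms(sigma_after: dict[str, int], nc_after: int,
                       terms, thresholds: ThresholdMap) -> float:
    """PR(g, r) = 1 + sum over r's terms of PR_s, evaluated on the state
    after inclusion; +inf if any term exceeds its eta bound."""
    total = 1.0
    for s in terms:
        sig = sigma_after.get(s, 0)
        eta = eta_bound(thresholds[s], nc_after)
        if sig > eta:
            return math.inf
        total += sig / (eta - sig + 1)
    return total


def privacy_risk(g, r, thresholds: ThresholdMap, *, new_case=None) -> float:
    """Privacy risk of adding record ``r`` into group ``g``.

    ``new_case`` tells whether r carries a CaseID new in this period; when
    omitted, every member (and r) is treated as a new case, which is the
    single-release semantics.
    """
    sigma = g.sigma()
    sigma_after = dict(sigma)
    for s in r.sensitive:
        sigma_after[s] = sigma_after.get(s, 0) + 1
    if new_case is None:
        nc_after = g.size + 1
    else:
        nc_before = sum(1 for m in g.members if getattr(m, "is_new_case", True))
        nc_after = nc_before + (1 if new_case else 0)
    return privacy_risk_terms(sigma_after, nc_after, sorted(r.sensitive), thresholds)


def delta_il_prime(schema, g, r, thresholds: ThresholdMap, *, new_case=None) -> float:
    """delta_IL'(g, r) = delta_IL(g, r) * PR(g, r); +inf when inclusion is
    theta-infeasible (an infeasible record is never selected, even at zero
    information-loss increase)."""
    from .model import delta_il

    pr = privacy_risk(g, r, thresholds, new_case=new_case)
    if math.isinf(pr):
        return math.inf
    return delta_il(schema, g, r) * pr


@dataclass(frozen=True)
class QuarterDiagnosis:
    """Why a sensitive term makes a whole quarter unsatisfiable: its share
    of all cases, its share of new cases (the binding quantity), and whether
    the occurrence bound can be met at the given threshold."""

    term: str
    sigma: int
    n_cases: int
    n_new_cases: int
    theta: float

    @property
    def prevalence_pct(self) -> float:
        """sigma as a percentage of all cases in the quarter."""
        return 100.0 * self.sigma / self.n_cases

    @property
    def new_case_pct(self) -> float:
        """sigma as a percentage of new cases: the minimum confidence bound
        any grouping of the quarter could achieve for this term."""
        return 100.0 * self.sigma / self.n_new_cases

    @property
    def feasible(self) -> bool:
        return self.sigma <= eta_bound(self.theta, self.n_new_cases)


# ---------------------------------------------------------------------------
# Threshold setting schemes
# ---------------------------------------------------------------------------

LEVELWISE_THETA = {"high": 0.2, "low": 0.4, "non": 1.0}


def set_thresholds(counts: dict[str, int], mode: str, *, theta: float = None,
                   levels: dict[str, str] = None) -> ThresholdMap:
    """Build a ThresholdMap from per-term occurrence counts.

    ``uniform``: every term gets the single value ``theta``.

    ``frequency``: the more frequent a term, the less sensitive it is taken
    to be.  With m and SD the mean and population standard deviation of the
    occurrence counts, terms below m - SD get 0.2, terms within one SD get
    0.6, and terms above m + SD get 1.0.

    ``levelwise``: user-supplied sensitivity labels per term;
    high -> 0.2, low -> 0.4, non -> 1.0.
    """
    if not counts:
        raise ConfigError("empty term-count mapping")
    if mode == "uniform":
        if theta is None:
            raise ConfigError("uniform mode requires theta")
        return ThresholdMap.uniform(theta)
    if mode == "frequency":
        import numpy as np

        vals = np.array(list(counts.values()), dtype=float)
        m = vals.mean()
        sd = vals.std()  # population SD
        out = {}
        for term, c in counts.items():
            if c < m - sd:
                out[term] = 0.2
            elif c <= m + sd:
                out[term] = 0.6
            else:
                out[term] = 1.0
        return ThresholdMap(thresholds=out, default=0.2)
    if mode == "levelwise":
        if levels is None:
            raise ConfigError("levelwise mode requires term->level labels")
        bad = {lv for lv in levels.values() if lv not in LEVELWISE_THETA}
        if bad:
            raise ConfigError(f"unknown sensitivity levels: {sorted(bad)}")
        out = {term: LEVELWISE_THETA[levels.get(term, "low")] for term in counts}
        return ThresholdMap(thresholds=out, default=LEVELWISE_THETA["low"])
    raise ConfigError(f"unknown threshold mode {mode!r}")
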