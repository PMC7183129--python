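"""Hospital data-quality scoring against a reference rule set.

Given a cleaned rule set (whose stored confidences play the role of the
reference standard, e.g. from re-abstracted data) and a target dataset of
discharge records, each rule's confidence is recomputed per hospital and
two weighted metrics summarise departures:

* **bias** — per rule and hospital group, the sum over hospitals of
  ``(1 - Wilson CI range) x |hospital confidence - reference confidence|``.
  High bias flags systematic under- or over-coding relative to the
  reference standard.
* **variance** — per rule and group, the sum over all within-group
  hospital pairs of ``(2 - pairwise CI range) x |confidence difference|``,
  where the pairwise interval is a 95% simultaneous interval for the
  difference of two proportions built from the studentized range critical
  value ``q(level, k, inf) / sqrt(2)`` with a pooled score standard
  error.  High variance flags coding inconsistency across hospitals.

Both metrics weight narrow confidence intervals (well-estimated
confidences) more heavily.  Hospitals enter only if their annual volume
exceeds 1000 records (strictly), and a rule's statistic at a hospital
enters the sums only if its LHS occurs at least ``min_lhs_count`` times
there (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm, studentized_range

from .mining import AssociationRule, TransactionDB, build_transactions
from .records import DischargeRecord, hospital_volumes

DEFAULT_VOLUME_FLOOR = 1000
DEFAULT_MIN_LHS_COUNT = 5
DEFAULT_CI_LEVEL = 0.95
DEFAULT_TOP_K = 5


# ----------------------------------------------------------------------
# Interval primitives
# ----------------------------------------------------------------------

def wilson_interval(k: int, n: int,
                    level: float = DEFAULT_CI_LEVEL) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    With z the standard-normal quantile for the given level::

        centre = (p + z^2 / 2n) / (1 + z^2 / n)
        half   = z * sqrt(p(1-p)/n + z^2 / 4n^2) / (1 + z^2 / n)

    Bounds are clipped to [0, 1].  At the boundary counts the interval
    touches the boundary exactly (upper = 1 at k = n, lower = 0 at
    k = 0) while the opposite bound stays strictly interior.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    z = norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (float(max(0.0, centre - half)), float(min(1.0, centre + half)))


@lru_cache(maxsize=None)
def _studentized_critical(level: float, group_size: int) -> float:
    """q(level, k, inf) / sqrt(2): simultaneous pairwise critical value."""
    return float(studentized_range.ppf(level, group_size, np.inf)
                 / np.sqrt(2.0))


def pairwise_diff_interval(stat_i: "HospitalRuleStat",
                           stat_j: "HospitalRuleStat",
                           group_size: int,
                           level: float = DEFAULT_CI_LEVEL
                           ) -> tuple[float, float]:
    """Simultaneous interval for the confidence difference of two hospitals.

    Uses the pooled score standard error for a difference of independent
    proportions and the studentized-range critical value for ``k``
    simultaneous comparisons.  At ``group_size=2`` the critical value
    collapses to the standard-normal quantile and the unadjusted
    two-proportion score interval is recovered.  Bounds clip to [-1, 1].
    """
    if group_size < 2:
        raise ValueError("group size must be >= 2")
    crit = _studentized_critical(level, group_size)
    diff = stat_i.confidence - stat_j.confidence
    pooled = (stat_i.k + stat_j.k) / (stat_i.n + stat_j.n)
    se = np.sqrt(pooled * (1 - pooled) * (1 / stat_i.n + 1 / stat_j.n))
    return (float(max(-1.0, diff - crit * se)),
            float(min(1.0, diff + crit * se)))


# ----------------------------------------------------------------------
# Per-hospital statistics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HospitalRuleStat:
    """One rule's confidence at one hospital with its Wilson interval."""

    hospital_id: str
    group: str
    rule_id: str
    n: int  # LHS occurrence count
    k: int  # joint occurrence count
    ci_lower: float
    ci_upper: float
    sufficient: bool = True

    @property
    def confidence(self) -> float:
        return self.k / self.n if self.n else float("nan")

    @property
    def ci_range(self) -> float:
        return self.ci_upper - self.ci_lower


def eligible_hospitals(records: Iterable[DischargeRecord],
                       min_volume: int = DEFAULT_VOLUME_FLOOR
                       ) -> frozenset[str]:
    """Hospitals with record count strictly greater than ``min_volume``."""
    return frozenset(h for h, v in hospital_volumes(records).items()
                     if v > min_volume)


def hospital_rule_stats(rules: Sequence[AssociationRule],
                        records: Sequence[DischargeRecord],
                        hospital_groups: Mapping[str, str],
                        min_lhs_count: int = DEFAULT_MIN_LHS_COUNT,
                        level: float = DEFAULT_CI_LEVEL
                        ) -> list[HospitalRuleStat]:
    """Recompute every rule's confidence per hospital.

    ``records`` should be pre-filtered to eligible hospitals (every
    hospital present must appear in ``hospital_groups``).  Counting runs
    over each hospital's transactions in the rule's age stratum at the
    rule's digit level.  Stats with fewer than ``min_lhs_count`` LHS
    occurrences are flagged insufficient and excluded from metric sums.
    """
    by_hospital: dict[str, list[DischargeRecord]] = {}
    for r in records:
        by_hospital.setdefault(r.hospital_id, []).append(r)
    unknown = set(by_hospital) - set(hospital_groups)
    if unknown:
        raise ValueError(f"hospitals without group label: {sorted(unknown)}")

    db_cache: dict[tuple[str, str, int], TransactionDB] = {}
    stats: list[HospitalRuleStat] = []
    for rule in rules:
        for hospital_id in sorted(by_hospital):
            key = (hospital_id, rule.age_group, rule.level)
            db = db_cache.get(key)
            if db is None:
                db = build_transactions(by_hospital[hospital_id],
                                        rule.level, rule.age_group)
                db_cache[key] = db
            n = db.count(rule.lhs)
            k = db.count(set(rule.lhs) | {rule.rhs}) if n else 0
            if n >= max(min_lhs_count, 1):
                lo, hi = wilson_interval(k, n, level)
                sufficient = True
            else:
                lo, hi, sufficient = 0.0, 1.0, False
            stats.append(HospitalRuleStat(
                hospital_id=hospital_id,
                group=hospital_groups[hospital_id],
                rule_id=rule.rule_id, n=n, k=k,
                ci_lower=lo, ci_upper=hi, sufficient=sufficient,
            ))
    return stats


# ----------------------------------------------------------------------
# Bias
# ----------------------------------------------------------------------

@dataclass
class BiasResult:
    rule_id: str
    group: str
    reference_confidence: float
    #: (hospital id, contribution) for each usable hospital.
    contributions: list[tuple[str, float]]
    bias: Optional[float]

    @property
    def defined(self) -> bool:
        return self.bias is not None

    @property
    def mean_contribution(self) -> Optional[float]:
        if not self.contributions:
            return None
        return self.bias / len(self.contributions)


def rule_bias(stats: Sequence[HospitalRuleStat],
              reference_confidence: float) -> BiasResult:
    """Bias of one rule over one hospital group.

    ``sum over hospitals of (1 - CI range) x |confidence - reference|``;
    undefined (flagged) when no hospital has sufficient LHS support.
    """
    if not 0.0 <= reference_confidence <= 1.0:
        raise ValueError("reference confidence outside [0, 1]")
    _one_rule_one_group(stats)
    usable = [s for s in stats if s.sufficient]
    contributions = [
        (s.hospital_id,
         (1.0 - s.ci_range) * abs(s.confidence - reference_confidence))
        for s in usable
    ]
    bias = sum(c for _, c in contributions) if usable else None
    rule_id = stats[0].rule_id if stats else ""
    group = stats[0].group if stats else ""
    return BiasResult(rule_id=rule_id, group=group,
                      reference_confidence=reference_confidence,
                      contributions=contributions, bias=bias)


# ----------------------------------------------------------------------
# Variance
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseDiffStat:
    hospital_pair: tuple[str, str]
    difference: float
    ci_lower: float
    ci_upper: float

    @property
    def ci_range(self) -> float:
        return self.ci_upper - self.ci_lower

    @property
    def contribution(self) -> float:
        return (2.0 - self.ci_range) * abs(self.difference)


@dataclass
class VarianceResult:
    rule_id: str
    group: str
    pairs: list[PairwiseDiffStat]
    variance: Optional[float]

    @property
    def defined(self) -> bool:
        return self.variance is not None

    @property
    def mean_contribution(self) -> Optional[float]:
        if not self.pairs:
            return None
        return self.variance / len(self.pairs)


def pairwise_diff_stats(stats: Sequence[HospitalRuleStat],
                        level: float = DEFAULT_CI_LEVEL
                        ) -> list[PairwiseDiffStat]:
    """Simultaneous difference intervals for all within-group pairs."""
    usable = sorted((s for s in stats if s.sufficient),
                    key=lambda s: s.hospital_id)
    k = len(usable)
    out = []
    for si, sj in combinations(usable, 2):
        lo, hi = pairwise_diff_interval(si, sj, group_size=k, level=level)
        out.append(PairwiseDiffStat(
            hospital_pair=(si.hospital_id, sj.hospital_id),
            difference=si.confidence - sj.confidence,
            ci_lower=lo, ci_upper=hi,
        ))
    return out


def variance_from_pairs(rule_id: str, group: str,
                        pairs: Sequence[PairwiseDiffStat]) -> VarianceResult:
    """``sum over pairs of (2 - CI range) x |confidence difference|``."""
    variance = sum(p.contribution for p in pairs) if pairs else None
    return VarianceResult(rule_id=rule_id, group=group,
                          pairs=list(pairs), variance=variance)


def rule_variance(stats: Sequence[HospitalRuleStat],
                  level: float = DEFAULT_CI_LEVEL) -> VarianceResult:
    """Variance of one rule over one hospital group.

    Undefined (flagged) with fewer than two sufficient hospitals.
    """
    _one_rule_one_group(stats)
    rule_id = stats[0].rule_id if stats else ""
    group = stats[0].group if stats else ""
    usable = [s for s in stats if s.sufficient]
    if len(usable) < 2:
        return VarianceResult(rule_id, group, [], None)
    return variance_from_pairs(rule_id, group,
                               pairwise_diff_stats(usable, level))


def _one_rule_one_group(stats: Sequence[HospitalRuleStat]) -> None:
    if len({s.rule_id for s in stats}) > 1:
        raise ValueError("stats span multiple rules")
    if len({s.group for s in stats}) > 1:
        raise ValueError("stats span multiple hospital groups")


# ----------------------------------------------------------------------
# Assessment orchestration and ranking
# ----------------------------------------------------------------------

@dataclass
class AssessmentResult:
    biases: list[BiasResult]
    variances: list[VarianceResult]
    stats: list[HospitalRuleStat]


def assess(rules: Sequence[AssociationRule],
           records: Sequence[DischargeRecord],
           hospital_groups: Mapping[str, str],
           reference_confidences: Optional[Mapping[str, float]] = None,
           min_volume: int = DEFAULT_VOLUME_FLOOR,
           min_lhs_count: int = DEFAULT_MIN_LHS_COUNT,
           level: float = DEFAULT_CI_LEVEL) -> AssessmentResult:
    """Score a target dataset against a reference rule set.

    The reference confidence per rule defaults to the confidence stored
    in the rule set at mining time (the re-abstracted-data role) and can
    be overridden per rule id via ``reference_confidences``.
    """
    eligible = eligible_hospitals(records, min_volume)
    kept = [r for r in records if r.hospital_id in eligible]
    groups = {h: g for h, g in hospital_groups.items() if h in eligible}
    stats = hospital_rule_stats(rules, kept, groups, min_lhs_count, level)

    by_rule_group: dict[tuple[str, str], list[HospitalRuleStat]] = {}
    for s in stats:
        by_rule_group.setdefault((s.rule_id, s.group), []).append(s)

    biases, variances = [], []
    for rule in rules:
        reference = rule.confidence
        if reference_confidences and rule.rule_id in reference_confidences:
            reference = reference_confidences[rule.rule_id]
        rule.reference_confidence = reference
        for group in sorted({g for g in groups.values()}):
            group_stats = by_rule_group.get((rule.rule_id, group), [])
            if not group_stats:
                continue
            biases.append(rule_bias(group_stats, reference))
            variances.append(rule_variance(group_stats, level))
    return AssessmentResult(biases=biases, variances=variances, stats=stats)


def rank_rules(results: AssessmentResult, metric: str,
               top_k: int = DEFAULT_TOP_K
               ) -> dict[str, list]:
    """Top-k rules per hospital group, descending by bias or variance.

    Ties break by rule id; undefined results are omitted.
    """
    if metric not in ("bias", "variance"):
        raise ValueError("metric must be 'bias' or 'variance'")
    pool = results.biases if metric == "bias" else results.variances
    by_group: dict[str, list] = {}
    for res in pool:
        if not res.defined:
            continue
        by_group.setdefault(res.group, []).append(res)
    ranked = {}
    for group, items in sorted(by_group.items()):
        items.sort(key=lambda r: (-(r.bias if metric == "bias"
                                    else r.variance), r.rule_id))
        ranked[group] = items[:top_k]
    return ranked
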