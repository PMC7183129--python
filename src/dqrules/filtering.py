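"""Rule-cleaning cascade.

Raw mined rule sets are too large and too redundant for expert review or
quality scoring.  Four stages clean them, in this order:

1. **Nested pruning** — two rules are nested when they share the RHS and
   one LHS is a strict subset of the other; if their confidences differ
   by less than ``delta`` (default 0.1) only the simpler rule is kept.
   Pruning compares all subset pairs among surviving rules, resolved
   bottom-up to a unique fixpoint.
2. **Statistical significance** — each rule's 2x2 contingency table over
   the training transactions is tested (Pearson chi-squared without
   continuity correction when all expected cell counts are >= 5, else
   Fisher's exact two-sided test), p-values are Benjamini-Hochberg
   adjusted within the (age group, level) family, and rules with adjusted
   p >= alpha (default 0.05) are removed as non-significant.
3. **Stability** — each rule's confidence is recomputed on held-out
   validation transactions; rules whose training/validation confidence
   differs by more than 0.05 (absolute), or whose LHS never occurs in
   validation, are removed.
4. **Dagger-asterisk exclusion** — rules that pair an etiology (dagger)
   code with its manifestation (asterisk) code reflect a coding
   convention, not a clinical association, and are removed.

Every stage reports exactly which rules it removed and why, so the
cascade's bookkeeping reconciles: input = removed + retained at each
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency, fisher_exact

from .icd import AsteriskRegistry, is_asterisk, parse_code
from .mining import AssociationRule, TransactionDB
from .records import DischargeRecord

DEFAULT_NESTED_DELTA = 0.1
DEFAULT_ALPHA = 0.05
DEFAULT_STABILITY_MAX_DIFF = 0.05
DEFAULT_TRAIN_FRACTION = 0.7

#: Closed vocabulary of removal reasons.
REASON_NESTED = "nested"
REASON_NON_SIGNIFICANT = "non-significant"
REASON_UNSTABLE = "unstable"
REASON_UNSUPPORTED = "unsupported-in-validation"
REASON_DAGGER_ASTERISK = "dagger-asterisk"


@dataclass
class StageReport:
    stage: str
    n_input: int
    n_retained: int
    removals: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removals)


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: str, n_input: int, retained_n: int,
            removals: list[tuple[str, str]]) -> None:
        report = StageReport(stage, n_input, retained_n, removals)
        if report.n_input != report.n_removed + report.n_retained:
            raise AssertionError(
                f"stage {stage}: {report.n_input} != "
                f"{report.n_removed} + {report.n_retained}"
            )
        self.stages.append(report)

    def merged(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(self.stages + other.stages)

    def to_rows(self) -> list[tuple[str, str, str]]:
        return [(s.stage, rule_id, reason)
                for s in self.stages for rule_id, reason in s.removals]


# ----------------------------------------------------------------------
# Train / validation split
# ----------------------------------------------------------------------

def split_records(records: Sequence[DischargeRecord],
                  train_fraction: float = DEFAULT_TRAIN_FRACTION,
                  seed: int = 0
                  ) -> tuple[list[DischargeRecord], list[DischargeRecord]]:
    """Random record-level partition; ``floor(n * fraction)`` to training."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)  # both parts non-empty
    train_idx = sorted(perm[:n_train])
    val_idx = sorted(perm[n_train:])
    return ([records[i] for i in train_idx],
            [records[i] for i in val_idx])


# ----------------------------------------------------------------------
# Nested-rule pruning
# ----------------------------------------------------------------------

def prune_nested(rules: Sequence[AssociationRule],
                 delta: float = DEFAULT_NESTED_DELTA
                 ) -> tuple[list[AssociationRule], FilterReport]:
    """Drop the more complex of two nested rules with close confidences.

    A rule is removed when a *surviving* rule with the same RHS and a
    strict-subset LHS (any subset, not only immediate ones) has a
    confidence within ``delta``.  Survivorship is resolved bottom-up by
    LHS size — a removed rule cannot shield or remove anything — which
    makes the fixpoint unique and independent of input order.
    """
    if len({r.rule_id for r in rules}) != len(rules):
        raise ValueError("duplicate rule ids")
    removed: list[tuple[str, str]] = []
    survivors: dict[tuple, list[AssociationRule]] = {}
    for r in sorted(rules, key=lambda r: len(r.lhs)):
        nested_under = survivors.get((r.age_group, r.level, r.rhs), [])
        if any(s.lhs < r.lhs and abs(s.confidence - r.confidence) < delta
               for s in nested_under):
            removed.append((r.rule_id, REASON_NESTED))
        else:
            survivors.setdefault((r.age_group, r.level, r.rhs),
                                 []).append(r)
    removed_ids = {rule_id for rule_id, _ in removed}
    kept = [r for r in rules if r.rule_id not in removed_ids]
    removed.sort()
    report = FilterReport()
    report.add("nested", len(rules), len(kept), removed)
    return kept, report


# ----------------------------------------------------------------------
# Statistical significance
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification of LHS and RHS presence over N records."""

    a: int  # LHS and RHS
    b: int  # LHS without RHS
    c: int  # RHS without LHS
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationTestResult:
    p_value: float
    statistic: Optional[float]
    method: str  # "chi-squared" | "fisher" | "degenerate"
    degenerate: bool = False


def contingency_for(rule: AssociationRule,
                    db: TransactionDB) -> ContingencyTable:
    """Exact 2x2 counts of the rule's sides over all transactions."""
    lhs = set(rule.lhs)
    a = b = c = d = 0
    for _, codes in db.transactions:
        has_x = lhs <= codes
        has_y = rule.rhs in codes
        if has_x and has_y:
            a += 1
        elif has_x:
            b += 1
        elif has_y:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def association_test(table: ContingencyTable) -> AssociationTestResult:
    """Test LHS-RHS association on a 2x2 table.

    Pearson chi-squared (no continuity correction) when every expected
    cell count is >= 5, Fisher's exact two-sided test otherwise.  A table
    with a zero margin carries no information about association and
    returns p = 1 with a warning.
    """
    if table.n < 1:
        raise ValueError("empty table")
    row1, row2 = table.a + table.b, table.c + table.d
    col1, col2 = table.a + table.c, table.b + table.d
    if 0 in (row1, row2, col1, col2):
        warnings.warn("degenerate contingency table (zero margin); p = 1",
                      stacklevel=2)
        return AssociationTestResult(1.0, None, "degenerate",
                                     degenerate=True)
    expected_min = min(r * c for r in (row1, row2) for c in (col1, col2))
    cells = [[table.a, table.b], [table.c, table.d]]
    if expected_min / table.n >= 5.0:
        stat, p, _, _ = chi2_contingency(cells, correction=False)
        return AssociationTestResult(float(p), float(stat), "chi-squared")
    stat, p = fisher_exact(cells, alternative="two-sided")
    return AssociationTestResult(float(p), float(stat), "fisher")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def significance_filter(rules: Sequence[AssociationRule],
                        db: TransactionDB,
                        alpha: float = DEFAULT_ALPHA
                        ) -> tuple[list[AssociationRule], FilterReport]:
    """Keep rules whose BH-adjusted association p-value is below alpha.

    The rules passed in form one testing family (one age group and digit
    level mining run).
    """
    report = FilterReport()
    if not rules:
        report.add("significance", 0, 0, [])
        return [], report
    p_values = []
    for r in rules:
        result = association_test(contingency_for(r, db))
        r.p_value = result.p_value
        p_values.append(result.p_value)
    adjusted = bh_adjust(p_values)
    kept, removed = [], []
    for r, p_adj in zip(rules, adjusted):
        r.p_adjusted = float(p_adj)
        if p_adj < alpha:
            kept.append(r)
        else:
            removed.append((r.rule_id, REASON_NON_SIGNIFICANT))
    report.add("significance", len(rules), len(kept), removed)
    return kept, report


# ----------------------------------------------------------------------
# Train / validation stability
# ----------------------------------------------------------------------

def stability_filter(rules: Sequence[AssociationRule],
                     validation_db: TransactionDB,
                     max_diff: float = DEFAULT_STABILITY_MAX_DIFF
                     ) -> tuple[list[AssociationRule], FilterReport]:
    """Keep rules whose confidence replicates on held-out records.

    The absolute difference between training and validation confidence
    must not exceed ``max_diff``; rules whose LHS never occurs in the
    validation data cannot be checked and are removed.
    """
    kept, removed = [], []
    for r in rules:
        lhs_count = validation_db.count(r.lhs)
        if lhs_count == 0:
            removed.append((r.rule_id, REASON_UNSUPPORTED))
            continue
        joint = validation_db.count(set(r.lhs) | {r.rhs})
        r.confidence_validation = joint / lhs_count
        if abs(r.confidence - r.confidence_validation) <= max_diff:
            kept.append(r)
        else:
            removed.append((r.rule_id, REASON_UNSTABLE))
    report = FilterReport()
    report.add("stability", len(rules), len(kept), removed)
    return kept, report


# ----------------------------------------------------------------------
# Dagger-asterisk exclusion
# ----------------------------------------------------------------------

def dagger_asterisk_filter(rules: Sequence[AssociationRule],
                           registry: AsteriskRegistry,
                           strict: bool = False
                           ) -> tuple[list[AssociationRule], FilterReport]:
    """Remove rules that encode the dagger-asterisk coding convention.

    A rule is removed when an asterisk code on one side faces one of its
    paired dagger codes on the other side; with ``strict=True`` any rule
    containing an asterisk code is removed.
    """
    kept, removed = [], []
    for r in rules:
        if _is_convention_rule(r, registry, strict):
            removed.append((r.rule_id, REASON_DAGGER_ASTERISK))
        else:
            kept.append(r)
    report = FilterReport()
    report.add("dagger-asterisk", len(rules), len(kept), removed)
    return kept, report


def _is_convention_rule(rule: AssociationRule, registry: AsteriskRegistry,
                        strict: bool) -> bool:
    sides = (set(rule.lhs), {rule.rhs})
    if strict:
        return any(is_asterisk(c, registry) for side in sides for c in side)
    for this, other in (sides, sides[::-1]):
        for code in this:
            if not is_asterisk(code, registry):
                continue
            parsed = parse_code(code)
            daggers = (registry.paired_daggers(parsed.code)
                       | registry.paired_daggers(parsed.category))
            dagger_cats = {parse_code(d).category for d in daggers}
            for o in other:
                op = parse_code(o)
                if op.code in daggers or op.category in dagger_cats:
                    return True
    return False


# ----------------------------------------------------------------------
# The full cascade
# ----------------------------------------------------------------------

def run_cascade(rules: Sequence[AssociationRule],
                train_db: TransactionDB,
                validation_db: TransactionDB,
                registry: Optional[AsteriskRegistry] = None,
                nested_delta: float = DEFAULT_NESTED_DELTA,
                alpha: float = DEFAULT_ALPHA,
                stability_max_diff: float = DEFAULT_STABILITY_MAX_DIFF,
                strict_asterisk: bool = False
                ) -> tuple[list[AssociationRule], FilterReport]:
    """Nested pruning -> significance -> stability -> dagger-asterisk."""
    registry = registry if registry is not None else AsteriskRegistry()
    kept, report = prune_nested(rules, nested_delta)
    kept, stage = significance_filter(kept, train_db, alpha)
    report = report.merged(stage)
    kept, stage = stability_filter(kept, validation_db, stability_max_diff)
    report = report.merged(stage)
    kept, stage = dagger_asterisk_filter(kept, registry, strict_asterisk)
    report = report.merged(stage)
    return kept, report
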