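"""Association-rule mining on coded discharge abstracts.

Records are reduced to per-age-group *transactions*: the set of in-scope
diagnosis codes truncated to the three- or four-character level, with set
semantics (a code repeated on an abstract counts once).  Frequent code
sets are found with the Apriori algorithm — candidate (k)-itemsets are
joined from frequent (k-1)-itemsets and pruned by downward closure before
counting — and rules ``X => y`` with a single consequent code are derived
from them.

For a rule ``X => y`` over ``N`` transactions:

* support count — number of transactions containing ``X ∪ {y}``;
* support ``P(X, y)`` — that count divided by ``N``;
* LHS support ``P(X)`` — coverage of the rule;
* confidence ``P(y | X)`` — reliability of the inference, the joint count
  divided by the LHS count.

Confidence is always >= support.  Default thresholds are confidence
>= 0.05 and joint support count >= 20; both are enforced explicitly, as
a confidence floor alone does not bound the joint count from below.

:func:`brute_force_mine` enumerates every candidate rule exhaustively and
serves as the independent verification oracle for small databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .icd import in_analysis_scope, parse_code, truncate_code
from .records import DischargeRecord, age_bounds

DEFAULT_MIN_CONFIDENCE = 0.05
DEFAULT_MIN_SUPPORT_COUNT = 20
DEFAULT_MAX_ITEMSET_SIZE = 3

#: brute_force_mine refuses databases with more distinct codes than this.
BRUTE_FORCE_CODE_CAP = 16


@dataclass
class TransactionDB:
    """Deduplicated code sets per record for one age stratum and level."""

    age_group: str
    level: int
    transactions: tuple[tuple[int, frozenset[str]], ...]
    n_dropped_empty: int = 0
    _masks: Optional[dict[str, int]] = field(default=None, repr=False,
                                             compare=False)

    @property
    def n(self) -> int:
        return len(self.transactions)

    def item_masks(self) -> dict[str, int]:
        """Per-code transaction bitmasks (bit t set iff code in transaction t)."""
        if self._masks is None:
            masks: dict[str, int] = {}
            for t, (_, codes) in enumerate(self.transactions):
                bit = 1 << t
                for c in codes:
                    masks[c] = masks.get(c, 0) | bit
            self._masks = masks
        return self._masks

    def count(self, itemset: Iterable[str]) -> int:
        """Number of transactions containing every code of ``itemset``."""
        masks = self.item_masks()
        acc = -1  # all-ones
        for c in itemset:
            acc &= masks.get(c, 0)
            if not acc:
                return 0
        if acc == -1:
            return self.n
        return acc.bit_count()


@dataclass(frozen=True)
class FrequentItemset:
    itemset: frozenset[str]
    support_count: int


@dataclass
class AssociationRule:
    """A mined rule ``lhs => rhs`` with its stored metrics.

    The optional fields are filled in by the filtering cascade
    (significance, validation confidence) and by assessment (reference
    confidence) as the rule moves through the pipeline.
    """

    rule_id: str
    lhs: frozenset[str]
    rhs: str
    age_group: str
    level: int
    joint_count: int
    lhs_count: int
    n: int
    p_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    confidence_validation: Optional[float] = None
    reference_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rhs in self.lhs:
            raise ValueError(f"{self.rule_id}: RHS must not appear in LHS")
        if not 0 <= self.joint_count <= self.lhs_count <= self.n:
            raise ValueError(f"{self.rule_id}: inconsistent counts")

    @property
    def support(self) -> float:
        """Joint support P(lhs, rhs)."""
        return self.joint_count / self.n

    @property
    def lhs_support(self) -> float:
        return self.lhs_count / self.n

    @property
    def confidence(self) -> float:
        return self.joint_count / self.lhs_count

    def key(self) -> tuple:
        """Identity of the rule irrespective of assigned rule id."""
        return (self.age_group, self.level, tuple(sorted(self.lhs)),
                self.rhs, self.joint_count, self.lhs_count, self.n)


def build_transactions(records: Iterable[DischargeRecord], level: int,
                       age_group: str) -> TransactionDB:
    """Project records of one age stratum onto mining transactions.

    Codes are truncated to ``level``, out-of-scope codes (chapters outside
    I-XVII) are dropped, duplicates collapse, and records left without any
    in-scope code are excluded (their number is recorded on the DB).
    """
    if level not in (3, 4):
        raise ValueError(f"digit level must be 3 or 4, got {level!r}")
    lo, hi = age_bounds(age_group)  # raises on unknown label
    transactions: list[tuple[int, frozenset[str]]] = []
    dropped = 0
    for rec in records:
        if rec.age < lo or (hi is not None and rec.age > hi):
            continue
        kept = frozenset(
            truncate_code(code, level)
            for code in rec.codes
            if in_analysis_scope(parse_code(code))
        )
        if kept:
            transactions.append((rec.record_id, kept))
        else:
            dropped += 1
    return TransactionDB(age_group=age_group, level=level,
                         transactions=tuple(transactions),
                         n_dropped_empty=dropped)


def mine_frequent_itemsets(db: TransactionDB, min_support_count: int,
                           max_itemset_size: int = DEFAULT_MAX_ITEMSET_SIZE
                           ) -> list[FrequentItemset]:
    """Apriori: all itemsets of size <= max with count >= the minimum."""
    if min_support_count < 1:
        raise ValueError("min support count must be >= 1")
    if max_itemset_size < 2:
        raise ValueError("max itemset size must be >= 2")
    counts = _apriori_counts(db, min_support_count, max_itemset_size)
    return [FrequentItemset(frozenset(items), c)
            for items, c in sorted(counts.items())]


def _apriori_counts(db: TransactionDB, min_count: int,
                    max_size: int) -> dict[tuple[str, ...], int]:
    """Frequent-itemset counts keyed by sorted code tuple."""
    masks = db.item_masks()
    counts: dict[tuple[str, ...], int] = {}
    level_k = []
    for code in sorted(masks):
        c = masks[code].bit_count()
        if c >= min_count:
            counts[(code,)] = c
            level_k.append((code,))
    k = 1
    while level_k and k < max_size:
        frequent_prev = set(level_k)
        candidates = []
        for i, a in enumerate(level_k):
            for b in level_k[i + 1:]:
                if a[:-1] != b[:-1]:
                    break  # sorted list: shared prefixes are contiguous
                cand = a + (b[-1],)
                if all(tuple(s) in frequent_prev
                       for s in combinations(cand, k)):
                    candidates.append(cand)
        next_level = []
        for cand in candidates:
            acc = masks[cand[0]]
            for code in cand[1:]:
                acc &= masks[code]
                if not acc:
                    break
            c = acc.bit_count()
            if c >= min_count:
                counts[cand] = c
                next_level.append(cand)
        level_k = next_level
        k += 1
    return counts


def derive_rules(itemsets: Sequence[FrequentItemset], db: TransactionDB,
                 min_confidence: float = DEFAULT_MIN_CONFIDENCE,
                 min_support_count: int = DEFAULT_MIN_SUPPORT_COUNT
                 ) -> list[AssociationRule]:
    """Emit every rule ``(Z - {y}) => y`` meeting both thresholds.

    ``itemsets`` must come from :func:`mine_frequent_itemsets` on the same
    database with a minimum count no larger than ``min_support_count``, so
    that every LHS is itself in the collection (downward closure).
    """
    counts = {fi.itemset: fi.support_count for fi in itemsets}
    rules: list[AssociationRule] = []
    for fi in itemsets:
        if len(fi.itemset) < 2 or fi.support_count < min_support_count:
            continue
        for y in sorted(fi.itemset):
            lhs = fi.itemset - {y}
            lhs_count = counts.get(lhs)
            if lhs_count is None:
                lhs_count = db.count(lhs)
            if fi.support_count / lhs_count >= min_confidence:
                rules.append(AssociationRule(
                    rule_id="", lhs=lhs, rhs=y, age_group=db.age_group,
                    level=db.level, joint_count=fi.support_count,
                    lhs_count=lhs_count, n=db.n,
                ))
    return _finalise(rules)


def _finalise(rules: list[AssociationRule]) -> list[AssociationRule]:
    """Deterministic ordering and rule-id assignment."""
    rules.sort(key=lambda r: (r.age_group, r.level, r.rhs,
                              tuple(sorted(r.lhs))))
    for i, r in enumerate(rules):
        r.rule_id = f"{r.age_group}/L{r.level}/{i:04d}"
    return rules


def mine_rules(records: Iterable[DischargeRecord], level: int,
               age_group: str,
               min_confidence: float = DEFAULT_MIN_CONFIDENCE,
               min_support_count: int = DEFAULT_MIN_SUPPORT_COUNT,
               max_itemset_size: int = DEFAULT_MAX_ITEMSET_SIZE
               ) -> tuple[list[AssociationRule], TransactionDB]:
    """Convenience: build transactions, mine itemsets, derive rules."""
    db = build_transactions(records, level, age_group)
    itemsets = mine_frequent_itemsets(db, min_support_count,
                                      max_itemset_size)
    return derive_rules(itemsets, db, min_confidence,
                        min_support_count), db


def brute_force_mine(db: TransactionDB, min_support_count: int,
                     min_confidence: float,
                     max_itemset_size: int = DEFAULT_MAX_ITEMSET_SIZE
                     ) -> list[AssociationRule]:
    """Exhaustive enumeration of every candidate rule (verification oracle).

    Counts every subset of the code universe directly against the
    transaction list — deliberately independent of the Apriori path and
    its bitmask counting.  Refuses databases with more than
    ``BRUTE_FORCE_CODE_CAP`` distinct codes.
    """
    universe = sorted({c for _, codes in db.transactions for c in codes})
    if len(universe) > BRUTE_FORCE_CODE_CAP:
        raise ValueError(
            f"brute force caps at {BRUTE_FORCE_CODE_CAP} distinct codes, "
            f"got {len(universe)}"
        )

    def count(items: tuple[str, ...]) -> int:
        s = set(items)
        return sum(1 for _, codes in db.transactions if s <= codes)

    rules: list[AssociationRule] = []
    for size in range(2, max_itemset_size + 1):
        for itemset in combinations(universe, size):
            joint = count(itemset)
            if joint < min_support_count:
                continue
            for y in itemset:
                lhs = tuple(c for c in itemset if c != y)
                lhs_count = count(lhs)
                if joint / lhs_count >= min_confidence:
                    rules.append(AssociationRule(
                        rule_id="", lhs=frozenset(lhs), rhs=y,
                        age_group=db.age_group, level=db.level,
                        joint_count=joint, lhs_count=lhs_count, n=db.n,
                    ))
    return _finalise(rules)
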