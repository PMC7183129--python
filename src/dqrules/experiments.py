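"""Validation experiments run against the synthetic ground truth.

These are the package's own checks that the machinery does what it
claims: the Apriori miner is compared with exhaustive enumeration on
random databases, Wilson intervals are checked for empirical coverage,
and the bias/variance metrics are challenged to detect under-coding
deliberately injected at one hospital.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assessment import assess
from .mining import (TransactionDB, brute_force_mine, derive_rules,
                     mine_frequent_itemsets)
from .synthetic import (SimulationConfig, generate_records,
                        inject_undercoding, reference_ruleset)


def mining_oracle_trials(n_trials: int = 100, seed: int = 0,
                         max_codes: int = 10,
                         max_transactions: int = 300) -> tuple[int, int]:
    """Compare Apriori with brute force on random databases.

    Each trial draws a random transaction database (up to ``max_codes``
    distinct codes, up to ``max_transactions`` transactions) and random
    thresholds, mines it both ways, and compares the rule sets exactly.
    Returns (number of agreeing trials, number of trials).
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        n_codes = int(rng.integers(2, max_codes + 1))
        codes = np.array([f"A{i:02d}" for i in range(n_codes)])
        n_trans = int(rng.integers(2, max_transactions + 1))
        density = float(rng.uniform(0.05, 0.6))
        items = [frozenset(codes[rng.random(n_codes) < density])
                 for _ in range(n_trans)]
        items = [s for s in items if s]
        db = TransactionDB(age_group="65+", level=3,
                           transactions=tuple(enumerate(items)))
        min_count = int(rng.integers(1, 16))
        min_conf = float(rng.uniform(0.0, 0.9))
        max_size = int(rng.integers(2, 5))
        apriori = derive_rules(
            mine_frequent_itemsets(db, min_count, max_size),
            db, min_conf, min_count)
        oracle = brute_force_mine(db, min_count, min_conf, max_size)
        if {r.key() for r in apriori} == {r.key() for r in oracle}:
            agree += 1
    return agree, n_trials


def wilson_coverage(n: int, p: float, draws: int, seed: int = 0,
                    level: float = 0.95) -> float:
    """Empirical coverage of the Wilson interval over binomial draws."""
    from .assessment import wilson_interval

    rng = np.random.default_rng(seed)
    ks = rng.binomial(n, p, size=draws)
    covered = 0
    for k in np.unique(ks):
        lo, hi = wilson_interval(int(k), n, level)
        if lo <= p <= hi:
            covered += int(np.sum(ks == k))
    return covered / draws


@dataclass
class DetectionResult:
    """Outcome of the under-coding injection experiment."""

    rule_id: str
    hospital_id: str
    group: str
    rates: tuple[float, ...]
    #: rate -> mean (over seeds) bias of the affected rule in the group.
    mean_bias: dict[float, float]
    mean_variance: dict[float, float]
    #: rate -> rank (1 = highest) of the affected rule by mean bias
    #: among all rules in the group.
    bias_rank: dict[int, int] | dict[float, int]


def undercoding_detection(config: SimulationConfig, rule_id: str,
                          hospital_id: str,
                          rates: Sequence[float] = (0.0, 0.2, 0.4),
                          n_seeds: int = 20,
                          seed: int = 0) -> DetectionResult:
    """Inject under-coding of one rule's RHS code at one hospital.

    For each seed a fresh dataset is generated and the RHS code of
    ``rule_id`` is dropped at ``hospital_id`` with each rate in turn;
    the planted rules (confidences at their closed forms) serve as the
    reference rule set.  Bias and variance of the affected rule within
    the hospital's peer group are averaged over seeds per rate.
    """
    planted = {r.rule_id: r for r in config.planted_rules}[rule_id]
    target_code = planted.rhs
    group = config.hospital(hospital_id).group
    groups = {h.hospital_id: h.group for h in config.hospitals}
    rules = reference_ruleset(config, level=4)

    bias_sums: dict[float, dict[str, float]] = {r: {} for r in rates}
    var_sums: dict[float, float] = {r: 0.0 for r in rates}
    for i in range(n_seeds):
        records = generate_records(config, seed=seed + i)
        for rate in rates:
            injected = inject_undercoding(records, hospital_id,
                                          target_code, rate,
                                          seed=seed + 10_000 + i)
            result = assess(rules, injected, groups)
            for b in result.biases:
                if b.group == group and b.defined:
                    bias_sums[rate][b.rule_id] = (
                        bias_sums[rate].get(b.rule_id, 0.0) + b.bias)
            for v in result.variances:
                if (v.group == group and v.rule_id == rule_id
                        and v.defined):
                    var_sums[rate] += v.variance

    mean_bias, mean_variance, bias_rank = {}, {}, {}
    for rate in rates:
        means = {rid: s / n_seeds for rid, s in bias_sums[rate].items()}
        mean_bias[rate] = means[rule_id]
        mean_variance[rate] = var_sums[rate] / n_seeds
        ordered = sorted(means, key=lambda rid: (-means[rid], rid))
        bias_rank[rate] = ordered.index(rule_id) + 1
    return DetectionResult(rule_id=rule_id, hospital_id=hospital_id,
                           group=group, rates=tuple(rates),
                           mean_bias=mean_bias,
                           mean_variance=mean_variance,
                           bias_rank=bias_rank)
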