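"""Synthetic hospital discharge abstracts with known coding structure.

Real re-abstracted discharge data are confidential, so the pipeline is
exercised on simulated abstracts whose generative model is simple enough
to admit closed-form expected rule confidences:

* each record draws a hospital (proportional to volume weights) and an
  age group, with age uniform within the group;
* baseline diagnosis codes are included independently, code ``c`` with
  marginal probability ``pi_c`` from the age group's pool;
* *planted rules* then fire in rule-id order: whenever a rule's LHS codes
  are all present, its RHS code is added with conditional probability
  ``theta`` (single pass, no fixpoint iteration, so chained rules are
  reproducible);
* a per-hospital error model drops each present code with that hospital's
  under-coding probability and spuriously adds over-coding candidates;
* records are capped at 25 codes (random removal of baseline codes) and
  empty records are redrawn.

Under this model the confidence of a planted rule ``X => y`` at a
hospital with under-coding probability ``u`` and over-coding probability
``o`` for ``y`` is::

    s = theta + (1 - theta) * pi_y        # present before errors
    p = s * (1 - u)                       # survives under-coding
    confidence = p + (1 - p) * o          # over-coding contribution

which :func:`expected_rule_confidence` returns as the analytic oracle for
parameter-recovery tests.

The default configuration emulates the shape of re-abstracted inpatient
data: a median of 3 codes per record (IQR 2-4), age-specific code pools
(perinatal P-codes for 0-4, obstetric O-codes for 20-44, circulatory /
endocrine / genitourinary codes for 45+), ten planted associations per
mined stratum spanning weak to strong conditional probabilities, twelve
hospitals in three volume groups (so the >1000-record volume filter has
both sides), and a dagger-asterisk pair whose rule exists only by coding
convention.  It does not attempt to model true disease prevalence or
comorbidity networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .icd import AsteriskRegistry, in_analysis_scope, parse_code
from .records import (AGE_GROUPS, MAX_CODES_PER_RECORD, DischargeRecord,
                      age_bounds)

#: Upper age used when drawing uniformly within the open-ended 65+ group.
_OPEN_GROUP_MAX_AGE = 99


@dataclass(frozen=True)
class HospitalProfile:
    """A submitting hospital: identity, peer group, volume, error rates."""

    hospital_id: str
    group: str
    volume_weight: float
    #: code -> probability of dropping that code when present.
    undercode: Mapping[str, float] = field(default_factory=dict)
    #: code -> probability of spuriously adding that code.
    overcode: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume_weight <= 0:
            raise ValueError(f"{self.hospital_id}: volume weight must be > 0")
        for name, probs in (("undercode", self.undercode),
                            ("overcode", self.overcode)):
            for code, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"{self.hospital_id}: {name} probability for "
                        f"{code} outside [0, 1]"
                    )


@dataclass(frozen=True)
class PlantedRule:
    """A generative code association: LHS present => RHS added w.p. theta."""

    rule_id: str
    age_group: str
    lhs: frozenset[str]
    rhs: str
    theta: float
    #: "clinical" for genuine associations, "dagger-asterisk" for pairs
    #: that exist only by coding convention (excluded from recovery scoring).
    kind: str = "clinical"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"{self.rule_id}: theta outside [0, 1]")
        if self.rhs in self.lhs:
            raise ValueError(f"{self.rule_id}: RHS must not appear in LHS")
        if not self.lhs:
            raise ValueError(f"{self.rule_id}: empty LHS")
        for code in [*self.lhs, self.rhs]:
            if not in_analysis_scope(code):
                raise ValueError(
                    f"{self.rule_id}: {code} outside analysis scope"
                )


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset."""

    n_records: int
    seed: int
    hospitals: tuple[HospitalProfile, ...]
    #: age group label -> probability (must sum to 1).
    age_distribution: dict[str, float]
    #: age group label -> {code: marginal inclusion probability}.
    pools: dict[str, dict[str, float]]
    planted_rules: tuple[PlantedRule, ...] = ()
    max_codes: int = MAX_CODES_PER_RECORD

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if not self.hospitals:
            raise ValueError("at least one hospital is required")
        if not 1 <= self.max_codes <= MAX_CODES_PER_RECORD:
            raise ValueError(f"max_codes must be in [1, {MAX_CODES_PER_RECORD}]")
        total = sum(self.age_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"age-group probabilities sum to {total}, not 1")
        known = {label for label, _, _ in AGE_GROUPS}
        for label, p in self.age_distribution.items():
            if label not in known:
                raise ValueError(f"unknown age group {label!r}")
            if p < 0:
                raise ValueError(f"negative probability for group {label}")
        for label in self.age_distribution:
            pool = self.pools.get(label, {})
            if self.age_distribution[label] > 0 and not any(
                    p > 0 for p in pool.values()):
                raise ValueError(
                    f"unsatisfiable config: age group {label} has no code "
                    "with positive inclusion probability"
                )
            for code, p in pool.items():
                parse_code(code)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"pi({code}) outside [0, 1]")
        ids = [r.rule_id for r in self.planted_rules]
        if len(set(ids)) != len(ids):
            raise ValueError("planted rule ids must be unique")
        for rule in self.planted_rules:
            pool = self.pools.get(rule.age_group, {})
            missing = ({rule.rhs} | rule.lhs) - set(pool)
            if missing:
                raise ValueError(
                    f"{rule.rule_id}: codes {sorted(missing)} not in the "
                    f"{rule.age_group} pool"
                )

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "seed": self.seed,
            "max_codes": self.max_codes,
            "age_distribution": dict(self.age_distribution),
            "pools": {g: dict(p) for g, p in self.pools.items()},
            "hospitals": [
                {"hospital_id": h.hospital_id, "group": h.group,
                 "volume_weight": h.volume_weight,
                 "undercode": dict(h.undercode),
                 "overcode": dict(h.overcode)}
                for h in self.hospitals
            ],
            "planted_rules": [
                {"rule_id": r.rule_id, "age_group": r.age_group,
                 "lhs": sorted(r.lhs), "rhs": r.rhs, "theta": r.theta,
                 "kind": r.kind}
                for r in self.planted_rules
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        cfg = cls(
            n_records=int(d["n_records"]),
            seed=int(d["seed"]),
            max_codes=int(d.get("max_codes", MAX_CODES_PER_RECORD)),
            age_distribution=dict(d["age_distribution"]),
            pools={g: dict(p) for g, p in d["pools"].items()},
            hospitals=tuple(
                HospitalProfile(
                    hospital_id=h["hospital_id"], group=h["group"],
                    volume_weight=float(h["volume_weight"]),
                    undercode=dict(h.get("undercode", {})),
                    overcode=dict(h.get("overcode", {})),
                )
                for h in d["hospitals"]
            ),
            planted_rules=tuple(
                PlantedRule(
                    rule_id=r["rule_id"], age_group=r["age_group"],
                    lhs=frozenset(r["lhs"]), rhs=r["rhs"],
                    theta=float(r["theta"]), kind=r.get("kind", "clinical"),
                )
                for r in d.get("planted_rules", [])
            ),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hospital(self, hospital_id: str) -> HospitalProfile:
        for h in self.hospitals:
            if h.hospital_id == hospital_id:
                return h
        raise KeyError(hospital_id)


# ----------------------------------------------------------------------
# Generation
# ----------------------------------------------------------------------

def generate_records(config: SimulationConfig,
                     seed: Optional[int] = None) -> list[DischargeRecord]:
    """Generate discharge records under ``config``.

    Deterministic: the same config and seed yield byte-identical records.
    ``seed`` overrides ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_records

    hosp_weights = np.array([h.volume_weight for h in config.hospitals],
                            dtype=float)
    hosp_idx = rng.choice(len(config.hospitals), size=n,
                          p=hosp_weights / hosp_weights.sum())

    labels = [label for label, _, _ in AGE_GROUPS
              if config.age_distribution.get(label, 0.0) > 0]
    probs = np.array([config.age_distribution[g] for g in labels])
    grp_idx = rng.choice(len(labels), size=n, p=probs / probs.sum())

    out: list[Optional[DischargeRecord]] = [None] * n
    for gi, label in enumerate(labels):
        rows = np.flatnonzero(grp_idx == gi)
        if rows.size == 0:
            continue
        lo, hi = age_bounds(label)
        hi = _OPEN_GROUP_MAX_AGE if hi is None else hi
        ages = rng.integers(lo, hi + 1, size=rows.size)

        codes, mat = _simulate_group(config, label, hosp_idx[rows], rng)
        for k, row in enumerate(rows):
            present = frozenset(codes[j] for j in np.flatnonzero(mat[k]))
            out[row] = DischargeRecord(
                record_id=int(row),
                hospital_id=config.hospitals[hosp_idx[row]].hospital_id,
                age=int(ages[k]),
                codes=present,
            )
    return [r for r in out if r is not None]


def _simulate_group(config: SimulationConfig, label: str,
                    hosp_of_row: np.ndarray,
                    rng: np.random.Generator
                    ) -> tuple[list[str], np.ndarray]:
    """Simulate the code matrix for all rows of one age group."""
    pool = config.pools.get(label, {})
    over_codes = sorted({c for h in config.hospitals for c in h.overcode})
    codes = sorted(set(pool) | set(over_codes))
    col = {c: j for j, c in enumerate(codes)}
    pi = np.array([pool.get(c, 0.0) for c in codes])
    rules = sorted((r for r in config.planted_rules if r.age_group == label),
                   key=lambda r: r.rule_id)

    m = hosp_of_row.size
    mat, planted = _draw_rows(config, label, codes, col, pi, rules,
                              hosp_of_row, rng)

    # Cap over-long records by random removal of baseline (non-planted)
    # codes; fall back to planted ones only if baseline runs out.
    counts = mat.sum(axis=1)
    for k in np.flatnonzero(counts > config.max_codes):
        while mat[k].sum() > config.max_codes:
            baseline = np.flatnonzero(mat[k] & ~planted[k])
            candidates = baseline if baseline.size else np.flatnonzero(mat[k])
            mat[k, rng.choice(candidates)] = False

    # Redraw records left empty (the error model can strip everything).
    for _ in range(100):
        empty = np.flatnonzero(~mat.any(axis=1))
        if empty.size == 0:
            break
        sub, sub_planted = _draw_rows(config, label, codes, col, pi, rules,
                                      hosp_of_row[empty], rng)
        mat[empty] = sub
        planted[empty] = sub_planted
    else:
        raise RuntimeError(
            f"could not produce non-empty records for age group {label}"
        )
    return codes, mat


def _draw_rows(config: SimulationConfig, label: str, codes: list[str],
               col: dict[str, int], pi: np.ndarray,
               rules: Sequence[PlantedRule], hosp_of_row: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    m = hosp_of_row.size
    mat = rng.random((m, len(codes))) < pi
    planted = np.zeros_like(mat)

    for rule in rules:  # fixed rule-id order; single pass
        lhs_cols = [col[c] for c in sorted(rule.lhs)]
        fire = mat[:, lhs_cols].all(axis=1)
        draw = rng.random(m) < rule.theta
        add = fire & draw
        mat[add, col[rule.rhs]] = True
        planted[add, col[rule.rhs]] = True

    for hi, hosp in enumerate(config.hospitals):
        here = hosp_of_row == hi
        for code, p in sorted(hosp.undercode.items()):
            if code not in col:
                continue
            drop = here & mat[:, col[code]] & (rng.random(m) < p)
            mat[drop, col[code]] = False
            planted[drop, col[code]] = False
        for code, p in sorted(hosp.overcode.items()):
            add = here & (rng.random(m) < p)
            mat[add, col[code]] = True
    return mat, planted


# ----------------------------------------------------------------------
# Analytic oracle and error injection
# ----------------------------------------------------------------------

def expected_rule_confidence(rule: PlantedRule, config: SimulationConfig,
                             hospital: Optional[HospitalProfile] = None
                             ) -> float:
    """Generative P(RHS present | LHS present) for a planted rule.

    Closed form under the independence model (see module docstring)::

        s = theta + (1 - theta) * pi_rhs
        p = s * (1 - u_rhs)
        p + (1 - p) * o_rhs

    With ``hospital=None`` the volume-weighted average over all hospitals
    is returned (the confidence a pooled mining run converges to).  The
    form neglects the vanishing perturbations from the 25-code cap and
    the redraw of empty records.
    """
    if rule not in config.planted_rules:
        raise ValueError(f"{rule.rule_id} is not part of the configuration")
    pi_rhs = config.pools[rule.age_group].get(rule.rhs, 0.0)
    s = rule.theta + (1.0 - rule.theta) * pi_rhs

    def one(h: HospitalProfile) -> float:
        p = s * (1.0 - h.undercode.get(rule.rhs, 0.0))
        return p + (1.0 - p) * h.overcode.get(rule.rhs, 0.0)

    if hospital is not None:
        if hospital not in config.hospitals:
            raise ValueError(f"unknown hospital {hospital.hospital_id}")
        return one(hospital)
    weights = np.array([h.volume_weight for h in config.hospitals])
    values = np.array([one(h) for h in config.hospitals])
    return float(np.average(values, weights=weights))


def inject_undercoding(records: Sequence[DischargeRecord], hospital_id: str,
                       code: str, drop_probability: float,
                       seed: int) -> list[DischargeRecord]:
    """Independently remove ``code`` at one hospital with given probability.

    Other hospitals and codes are untouched; deterministic under ``seed``.
    A record whose only code is dropped disappears from the output
    (discharge abstracts carry at least one diagnosis).
    """
    if not 0.0 <= drop_probability <= 1.0:
        raise ValueError("drop probability outside [0, 1]")
    canonical = parse_code(code).code
    if not any(r.hospital_id == hospital_id for r in records):
        raise KeyError(f"unknown hospital id {hospital_id!r}")
    rng = np.random.default_rng(seed)
    out: list[DischargeRecord] = []
    for rec in records:
        if (rec.hospital_id == hospital_id and canonical in rec.codes
                and rng.random() < drop_probability):
            remaining = rec.codes - {canonical}
            if remaining:
                out.append(replace(rec, codes=remaining))
        else:
            out.append(rec)
    return out


# ----------------------------------------------------------------------
# Default study configuration
# ----------------------------------------------------------------------

#: Conditional probabilities planted per mined stratum: two sweeps from
#: weak to strong association.
_THETA_GRID = (0.2, 0.35, 0.5, 0.65, 0.8, 0.2, 0.35, 0.5, 0.65, 0.8)

#: Marginal inclusion probability of each planted antecedent (anchor)
#: code; common enough to resemble high-prevalence index conditions.
_PI_ANCHOR = 0.18
#: Baseline inclusion of each consequent code absent its rule.
_PI_RHS = 0.02

# anchor (LHS) and consequent (RHS) codes per mined stratum; all
# categories within a stratum are distinct so that three-digit truncation
# maps each planted rule onto a unique category-level rule.
_STRATUM_CODES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "0-4": (
        ("P07.3", "P22.0", "P05.1", "P08.1", "P01.1",
         "P02.7", "P03.4", "P04.0", "P92.2", "P96.8"),
        ("P59.0", "P28.4", "P70.0", "P61.0", "P74.1",
         "P91.6", "P52.1", "P25.1", "P29.3", "P94.2"),
    ),
    "20-44": (
        ("O60.1", "O68.0", "O70.1", "O34.2", "O24.4",
         "O36.3", "O42.0", "O62.0", "O63.1", "O99.0"),
        ("O72.1", "O75.6", "O69.1", "O71.0", "O73.0",
         "O80.0", "O81.4", "O82.1", "O86.0", "O92.7"),
    ),
    "45-64": (
        ("I10", "E11.9", "I25.1", "E78.5", "N18.9",
         "I48", "E66.9", "K21.9", "I20.0", "N39.0"),
        ("I50.0", "N17.9", "E87.6", "I21.4", "I63.9",
         "E86", "N19", "K76.0", "I49.9", "E03.9"),
    ),
    "65+": (
        ("I10", "I48", "E11.9", "I25.1", "N18.9",
         "I50.0", "J44.9", "E78.5", "N39.0", "K21.9"),
        ("I69.4", "E87.7", "N17.9", "J18.9", "I21.9",
         "E86", "I63.9", "L89", "E03.9", "K59.0"),
    ),
}

#: Codes kept for realism but invisible to mining (chapters XVIII-XXII):
#: delivery-outcome and encounter codes, symptom codes.
_OUT_OF_SCOPE: dict[str, dict[str, float]] = {
    "0-4": {"Z38.0": 0.12},
    "20-44": {"Z37.0": 0.10},
    "45-64": {"R07.4": 0.08, "Z51.1": 0.05},
    "65+": {"R29.6": 0.06, "Z51.5": 0.04},
}

#: Pool for the never-mined 5-19 stratum (no planted structure).
_POOL_5_19: dict[str, float] = {
    "J45.9": 0.40, "A09": 0.30, "K35.8": 0.25, "S42.0": 0.30,
    "F32.9": 0.15, "J03.9": 0.30, "E10.9": 0.12, "T78.4": 0.10,
    "L20.9": 0.15, "B34.9": 0.20, "M79.6": 0.20, "H66.9": 0.25,
    "R10.4": 0.35,
}

#: Dagger-asterisk convention pair planted in the 65+ stratum
#: (tuberculous meningitis, coded etiology + manifestation).
DAGGER_CODE = "A17.0"
ASTERISK_CODE = "G01"

DEFAULT_SEED = 101


def default_registry() -> AsteriskRegistry:
    """Registry matching the synthetic dagger-asterisk pair."""
    return AsteriskRegistry(
        asterisk_codes=frozenset({ASTERISK_CODE}),
        pairings=frozenset({("A17", ASTERISK_CODE)}),
    )


def default_hospitals() -> tuple[HospitalProfile, ...]:
    weights = {
        "teaching": (18000, 15000, 13000, 12000),
        "large_community": (8000, 7000, 6000, 5000),
        "small_community": (1500, 1200, 1000, 800),
    }
    prefix = {"teaching": "T", "large_community": "C", "small_community": "S"}
    return tuple(
        HospitalProfile(hospital_id=f"{prefix[g]}{i + 1}", group=g,
                        volume_weight=w)
        for g, ws in weights.items() for i, w in enumerate(ws)
    )


def default_config(n_records: int = 20_000,
                   seed: int = DEFAULT_SEED) -> SimulationConfig:
    """The study configuration used throughout the test-bed.

    Calibrated so the codes-per-record distribution has median 3 with
    IQR 2-4 across 10,000+ records, matching the shape of re-abstracted
    inpatient data.
    """
    pools: dict[str, dict[str, float]] = {"5-19": dict(_POOL_5_19)}
    rules: list[PlantedRule] = []
    for label, (anchors, rhss) in _STRATUM_CODES.items():
        pool = {c: _PI_ANCHOR for c in anchors}
        pool.update({c: _PI_RHS for c in rhss})
        pool.update(_OUT_OF_SCOPE.get(label, {}))
        pools[label] = pool
        for i, (lhs, rhs) in enumerate(zip(anchors, rhss)):
            rules.append(PlantedRule(
                rule_id=f"{label}-r{i:02d}", age_group=label,
                lhs=frozenset({lhs}), rhs=rhs, theta=_THETA_GRID[i],
            ))
    pools["65+"][DAGGER_CODE] = 0.02
    pools["65+"][ASTERISK_CODE] = 0.004
    rules.append(PlantedRule(
        rule_id="65+-dagger0", age_group="65+",
        lhs=frozenset({DAGGER_CODE}), rhs=ASTERISK_CODE, theta=0.95,
        kind="dagger-asterisk",
    ))
    cfg = SimulationConfig(
        n_records=n_records,
        seed=seed,
        hospitals=default_hospitals(),
        age_distribution={"0-4": 0.14, "5-19": 0.06, "20-44": 0.26,
                          "45-64": 0.24, "65+": 0.30},
        pools=pools,
        planted_rules=tuple(rules),
    )
    cfg.validate()
    return cfg


def clinical_rules(config: SimulationConfig) -> list[PlantedRule]:
    """Planted rules that represent genuine (non-convention) associations."""
    return [r for r in config.planted_rules if r.kind == "clinical"]


def reference_ruleset(config: SimulationConfig, level: int = 4) -> list:
    """Planted clinical rules as an association-rule set.

    Stands in for a reference-standard rule set (the re-abstracted-data
    role): each planted rule becomes a rule at the given digit level
    whose stored confidence equals its closed-form expected confidence
    (to within 1e-6 count rounding), suitable for
    :func:`dqrules.assessment.assess`.
    """
    from .icd import truncate_code
    from .mining import AssociationRule

    denom = 1_000_000
    rules = []
    for planted in sorted(clinical_rules(config), key=lambda r: r.rule_id):
        conf = expected_rule_confidence(planted, config)
        rules.append(AssociationRule(
            rule_id=planted.rule_id,
            lhs=frozenset(truncate_code(c, level) for c in planted.lhs),
            rhs=truncate_code(planted.rhs, level),
            age_group=planted.age_group, level=level,
            joint_count=round(conf * denom), lhs_count=denom, n=4 * denom,
        ))
    return rules
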