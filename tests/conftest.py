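import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from dqrules.filtering import run_cascade, split_records
from dqrules.icd import truncate_code
from dqrules.mining import (build_transactions, derive_rules,
                            mine_frequent_itemsets)
from dqrules.records import MINED_AGE_GROUPS
from dqrules.synthetic import (clinical_rules, default_config,
                               default_registry, expected_rule_confidence,
                               generate_records)


@pytest.fixture(scope="session")
def study_config():
    return default_config(n_records=20_000)


@pytest.fixture(scope="session")
def study_records(study_config):
    return generate_records(study_config)


@pytest.fixture(scope="session")
def recovery_run(study_config, study_records):
    """Full mine+clean run at the three-digit level, scored against the
    planted ground truth: which planted rules survive the cascade and how
    far each survivor's mined confidence sits from its closed form."""
    train, validation = split_records(study_records, 0.7,
                                      seed=study_config.seed)
    registry = default_registry()
    survivors = {}
    for group in MINED_AGE_GROUPS:
        train_db = build_transactions(train, 3, group)
        val_db = build_transactions(validation, 3, group)
        itemsets = mine_frequent_itemsets(train_db, 20, 3)
        mined = derive_rules(itemsets, train_db, 0.05, 20)
        kept, _ = run_cascade(mined, train_db, val_db, registry)
        survivors[group] = {(tuple(sorted(r.lhs)), r.rhs): r for r in kept}

    recovered, lost, errors = {}, [], {}
    for planted in clinical_rules(study_config):
        key = (tuple(sorted(truncate_code(c, 3) for c in planted.lhs)),
               truncate_code(planted.rhs, 3))
        rule = survivors[planted.age_group].get(key)
        if rule is None:
            lost.append(planted.rule_id)
        else:
            recovered[planted.rule_id] = rule
            errors[planted.rule_id] = abs(
                rule.confidence
                - expected_rule_confidence(planted, study_config))
    return {"recovered": recovered, "lost": lost, "errors": errors,
            "n_planted": len(clinical_rules(study_config)),
            "survivors": survivors}
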