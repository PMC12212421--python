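"""Shared fixtures: one embedded signal cohort reused across the suite.

The cohort follows the generator's standard study conditions (texture- and
size-driven risk) at n_train=300 / n_test=200 with the 128-dimensional toy
extractor; building it is the expensive step, so it is session-scoped.
"""

import numpy as np
import pytest

from hnmil import features as feat
from hnmil import mil as milmod
from hnmil import preprocess as prep
from hnmil import synthetic as syn

TRAIN_SEED, TEST_SEED = 11, 22
EXTRACTOR_SEED, EMBED_RNG_SEED = 5, 3
EMBED_DIM = 128


def included_split(records, endpoint="OS"):
    """(patient_ids, labels) for patients not excluded by dichotomization."""
    labs = syn.label_cohort(records, endpoint)
    ids = [l.patient_id for l in labs if l.label != "excluded"]
    y = np.array(
        [1 if l.label == "positive" else 0 for l in labs if l.label != "excluded"],
        dtype=int,
    )
    return ids, y


@pytest.fixture(scope="session")
def signal_cohorts():
    train = syn.generate_cohort(syn.CohortConfig(n_patients=300, seed=TRAIN_SEED))
    test = syn.generate_cohort(syn.CohortConfig(n_patients=200, seed=TEST_SEED))
    return train, test


@pytest.fixture(scope="session")
def signal_bags(signal_cohorts):
    train, test = signal_cohorts
    extractor = feat.toy_extractor(
        feat.ExtractorSpec(embedding_dim=EMBED_DIM, seed=EXTRACTOR_SEED)
    )
    rng = np.random.default_rng(EMBED_RNG_SEED)

    def embed(records):
        bags = {}
        for r in records:
            patches = prep.preprocess_for_2d(
                r.ct, r.gtvp_mask, r.spacing, patient_id=r.patient_id
            )
            bags[r.patient_id] = feat.embed_bag(patches, extractor, rng)
        return bags

    return embed(train), embed(test)


@pytest.fixture(scope="session")
def os_split(signal_cohorts, signal_bags):
    train, test = signal_cohorts
    train_bags, test_bags = signal_bags
    tr_ids, y_tr = included_split(train)
    te_ids, y_te = included_split(test)
    by_id = {r.patient_id: r for r in test}
    return {
        "train_records": train,
        "test_records": test,
        "tr_ids": tr_ids,
        "te_ids": te_ids,
        "y_train": y_tr,
        "y_test": y_te,
        "bags_train": [train_bags[i] for i in tr_ids],
        "bags_test": [test_bags[i] for i in te_ids],
        "test_times": np.array([by_id[i].endpoints["OS"][0] for i in te_ids]),
        "test_events": np.array([by_id[i].endpoints["OS"][1] for i in te_ids]),
    }


MIL_RECOVERY_CONFIG = dict(
    embed_dim_in=EMBED_DIM, model_dim=64, n_heads=4, n_layers=2,
    epochs=10, patience=10, seed=1337, batch_size=8,
)


@pytest.fixture(scope="session")
def mil_deployment(os_split):
    cfg = milmod.MILConfig(**MIL_RECOVERY_CONFIG)
    fold_models = milmod.train_mil_cv(os_split["bags_train"], os_split["y_train"], cfg)
    deployed = milmod.select_deployment_model(fold_models)
    test_scores = np.array(
        [milmod.mil_forward(b, deployed).score for b in os_split["bags_test"]]
    )
    train_scores = np.array(
        [milmod.mil_forward(b, deployed).score for b in os_split["bags_train"]]
    )
    # label-permuted control trained under identical conditions
    y_perm = np.random.default_rng(99).permutation(os_split["y_train"])
    perm_models = milmod.train_mil_cv(os_split["bags_train"], y_perm, cfg)
    perm_deployed = milmod.select_deployment_model(perm_models)
    perm_scores = np.array(
        [milmod.mil_forward(b, perm_deployed).score for b in os_split["bags_test"]]
    )
    return {
        "fold_models": fold_models,
        "deployed": deployed,
        "train_scores": train_scores,
        "test_scores": test_scores,
        "perm_scores": perm_scores,
    }
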