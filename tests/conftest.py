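"""Shared fixtures: toy corpora and the synthetic study-condition corpora.

The expensive synthetic pipeline objects (reference corpus, taxonomy, policy
corpus, profiles) are session-scoped so the recovery properties and the
end-to-end checks reuse one simulation.
"""

from __future__ import annotations

import pytest

import policymap as pm

#: Dictionary-builder configuration used for the synthetic recovery
#: experiments: summed within-area tf with pooled IDF makes area-exclusive
#: vocabulary dominate the ranking (see docs/methods.md).
RECOVERY_BUILD = dict(fraction=0.1, aggregation="sum", per_area_idf=False)

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study_config() -> pm.GeneratorConfig:
    return pm.GeneratorConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def scientific_sim(study_config):
    return pm.simulate_scientific_corpus(study_config)


@pytest.fixture(scope="session")
def study_taxonomy(study_config, scientific_sim):
    corpus, _ = scientific_sim
    return pm.build_taxonomy(corpus, areas=study_config.areas, **RECOVERY_BUILD)


@pytest.fixture(scope="session")
def policy_sim(study_config, scientific_sim):
    _, truth = scientific_sim
    return pm.simulate_policy_corpus(
        study_config, pools=(truth.area_pools, truth.shared_pool)
    )


@pytest.fixture(scope="session")
def policy_profiles(policy_sim, study_taxonomy):
    corpus, _ = policy_sim
    return pm.classify_corpus(corpus, study_taxonomy)


@pytest.fixture
def toy_policy_records() -> list[dict]:
    return [
        {"doc_id": "p1", "text": "Amends rules for physical education programs.",
         "state": "TX", "year": 2009, "settings": ["school and after school"]},
        {"doc_id": "p2", "text": "Community gardens and physical activity funding.",
         "state": "TX", "year": 2010,
         "settings": ["community", "school and after school"]},
        {"doc_id": "p3", "text": "Menu labeling in restaurants; nutrition standards.",
         "state": "CA", "year": 2010, "settings": ["restaurant and food retail"]},
        {"doc_id": "p4", "text": "Physical education and physical activity in schools.",
         "state": "CA", "year": 2011, "settings": ["community"]},
    ]


@pytest.fixture
def toy_policy_corpus(toy_policy_records) -> pm.Corpus:
    return pm.corpus_from_records(toy_policy_records)
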