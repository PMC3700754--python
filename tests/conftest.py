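import pytest

from chemblrdf import (
    FixtureConfig,
    PlantedSelectivity,
    UriPolicy,
    generate_snapshot,
    triplify_snapshot,
)
from chemblrdf.links import link_snapshot


@pytest.fixture(scope="session")
def policy():
    return UriPolicy()


@pytest.fixture(scope="session")
def planted_config():
    return FixtureConfig(
        n_molecules=30,
        n_assays=12,
        n_targets=8,
        n_activities=90,
        n_documents=6,
        seed=17,
        fraction_assays_missing_type=0.25,
        include_sentinel_doc=True,
        planted=PlantedSelectivity(n_molecules=7),
        fraction_overlong_inchi=0.2,
        fraction_approved=0.2,
    )


@pytest.fixture(scope="session")
def planted_snapshot(planted_config):
    return generate_snapshot(planted_config)


@pytest.fixture(scope="session")
def planted_graph(planted_snapshot, policy):
    return triplify_snapshot(planted_snapshot, policy)


@pytest.fixture(scope="session")
def full_graph(planted_snapshot, policy):
    """Converted triples plus all link-outs, as one queryable graph."""
    graph = triplify_snapshot(planted_snapshot, policy)
    graph += link_snapshot(
        planted_snapshot, policy,
        {planted_snapshot.molecules[0].chembl_id: 2157},
    )
    return graph


def brute_force_selective(snapshot, query):
    """Exhaustive relational filter: the independent oracle for the
    selectivity query (returns chembl_ids)."""
    typed_assays = {a.assay_id for a in snapshot.assays
                    if a.assay_type is not None}
    assay_targets = {}
    for asg in snapshot.assignments:
        assay_targets.setdefault(asg.assay_id, []).append(
            (asg.target_id, asg.confidence_score))
    hits_a, hits_b = set(), set()
    for act in snapshot.activities:
        if (act.activity_type != query.activity_type
                or act.std_value is None
                or act.std_units != query.units
                or act.assay_id not in typed_assays):
            continue
        for target_id, confidence in assay_targets.get(act.assay_id, []):
            if (query.min_confidence is not None
                    and confidence < query.min_confidence):
                continue
            if target_id == query.target_a and act.std_value < query.threshold_a:
                hits_a.add(act.chembl_id)
            if target_id == query.target_b and act.std_value > query.threshold_b:
                hits_b.add(act.chembl_id)
    return hits_a & hits_b
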