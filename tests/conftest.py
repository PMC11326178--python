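import pytest

import spliceburden as sb
from spliceburden.synthetic import CohortSpec, simulate_annotation, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 samples x 200 events, one cluster, no planted aberration."""
    return simulate_cohort(CohortSpec(n_samples=20, n_events=200, seed=7))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    tables = [sb.apply_junction_filter(t) for t in small_cohort.tables]
    return sb.build_psi_matrix(tables)


@pytest.fixture(scope="session")
def clustered_cohort():
    """60 samples in 4 well-separated clusters."""
    return simulate_cohort(
        CohortSpec(n_samples=60, n_events=400, n_clusters=4, seed=13)
    )


@pytest.fixture(scope="session")
def annotation_fixture():
    """Toy GTF text, features, SE events and per-base expected truth."""
    return simulate_annotation(n_transcripts=30, seed=5)


@pytest.fixture(scope="session")
def toy_models(annotation_fixture, tmp_path_factory):
    from spliceburden.functional_impact import load_transcript_models

    gtf_text, _, _, _ = annotation_fixture
    path = tmp_path_factory.mktemp("gtf") / "toy.gtf"
    path.write_text(gtf_text)
    return load_transcript_models(path)
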