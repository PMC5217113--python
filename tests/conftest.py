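import warnings

import pytest

from shscreen import (
    LibraryManifest,
    ShRNAConstruct,
    make_pilot_like_config,
    simulate_screen,
)


@pytest.fixture
def tiny_manifest() -> LibraryManifest:
    """Three genes x two constructs with disjoint 12-mers; one negative gene."""
    rows = [
        ("g1_sh1", "GENE1", "test", "ACGTACGTACCA"),
        ("g1_sh2", "GENE1", "test", "TTGGCCAATTGG"),
        ("g2_sh1", "GENE2", "positive", "GGGTTTAAACCA"),
        ("g2_sh2", "GENE2", "positive", "CATGCATGGTAC"),
        ("neg_sh1", "NEGX", "negative", "AATTGCGCAAGG"),
        ("neg_sh2", "NEGX", "negative", "CCGGATATCCTA"),
    ]
    return LibraryManifest(
        [ShRNAConstruct(*r) for r in rows], name="tiny"
    )


@pytest.fixture(scope="session")
def pilot_screen():
    """One simulated pilot-like screen shared across tests (seed fixed)."""
    cfg = make_pilot_like_config(seed=11)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def pilot_groups(pilot_screen):
    return {
        b: pilot_screen.tables_for_bio_rep(b) for b in pilot_screen.bio_rep_ids
    }


@pytest.fixture(autouse=True)
def _quiet_single_replicate_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="single biological replicate"
        )
        yield
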