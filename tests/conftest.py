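import numpy as np
import pandas as pd
import pytest

from mockqc import (
    FeatureTable,
    MockCommunityDef,
    even_mock,
    generate_clone_references,
    staggered_mock,
)


@pytest.fixture(scope="session")
def even_def():
    return even_mock()


@pytest.fixture(scope="session")
def staggered_def():
    return staggered_mock()


@pytest.fixture(scope="session")
def toy_refs():
    """Two well-separated 300 bp synthetic references."""
    return generate_clone_references(2, length=300, seed=123, labels=["a", "b"])


@pytest.fixture(scope="session")
def toy2_def(toy_refs):
    return MockCommunityDef(
        community_id="toy2",
        kind="staggered",
        members=((toy_refs[0], 0.5), (toy_refs[1], 0.5)),
    )


def make_table(counts: dict, meta_rows: list[dict]) -> FeatureTable:
    counts_df = pd.DataFrame(counts, dtype=np.int64)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return FeatureTable(counts=counts_df, metadata=meta)


@pytest.fixture()
def simple_table(staggered_def):
    """One run, two mock replicates + one blank, feature_id == clone_id."""
    rng = np.random.default_rng(11)
    exp = staggered_def.proportions
    cids = list(staggered_def.clone_ids)
    p = np.array([exp[c] for c in cids])
    cols = {
        "runA_mock1": dict(zip(cids, rng.multinomial(50_000, p))),
        "runA_mock2": dict(zip(cids, rng.multinomial(50_000, p))),
        "runA_blank": {c: 0 for c in cids},
    }
    meta = [
        {"sample_id": "runA_mock1", "run_id": "runA", "platform": "sim",
         "role": "mock", "community_id": staggered_def.community_id},
        {"sample_id": "runA_mock2", "run_id": "runA", "platform": "sim",
         "role": "mock", "community_id": staggered_def.community_id},
        {"sample_id": "runA_blank", "run_id": "runA", "platform": "sim",
         "role": "blank", "community_id": ""},
    ]
    return make_table({k: v for k, v in cols.items()}, meta)
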