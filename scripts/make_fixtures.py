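"""Regenerate the packaged mock-community fixtures.

The clone identities and the staggered rank-abundance series are fixed
here; the reference sequences are synthetic (deterministically generated,
pairwise identity <= 97%) because the real clone sequences are not
redistributed with the package.  Run from the repository root:

    python scripts/make_fixtures.py
"""

from __future__ import annotations

import sys
from pathlib import Path

SRC = Path(__file__).resolve().parents[1] / "src"
sys.path.insert(0, str(SRC))

from mockqc.mock import CloneReference, MockCommunityDef, write_mock_definition
from mockqc.simulate import generate_clone_references

DATA = SRC / "mockqc" / "data"

# 11-clone even community
EVEN_TAXA = [
    "MGII",
    "SAR11",
    "Thaumarchaea",
    "Prochlorococcus",
    "Flavobacteria",
    "SAR202",
    "Planctomyces",
    "MarineGroupA",
    "SAR116",
    "SAR86",
    "Synechococcus",
]

# 27-clone staggered community: a marine-like rank-abundance series.
# Only the MGII proportion (1.8%) is anchored to the communities this
# package mimics; the remainder is a design choice spanning ~2 decades.
STAGGERED = {
    "SAR11": 0.200,
    "Prochlorococcus": 0.130,
    "SAR86": 0.090,
    "Synechococcus": 0.070,
    "Roseobacter": 0.060,
    "Flavobacteria": 0.055,
    "SAR116": 0.050,
    "MarineGroupA": 0.045,
    "Thaumarchaea": 0.040,
    "SAR202": 0.035,
    "OCS155_b": 0.030,
    "Planctomyces": 0.030,
    "SAR92": 0.025,
    "OM43": 0.022,
    "MGII": 0.018,
    "SAR324": 0.018,
    "SUP05": 0.015,
    "OM60": 0.012,
    "NS5": 0.010,
    "NS4": 0.009,
    "Actinomarina": 0.008,
    "Puniceispirillum": 0.007,
    "Verrucomicrobia": 0.006,
    "Lentisphaerae": 0.005,
    "OM182": 0.004,
    "AEGEAN169": 0.003,
    "Nitrospina": 0.003,
}

SEQ_SEED = 20180201  # fixed forever; regeneration must be byte-identical
SEQ_LENGTH = 800


def main() -> None:
    assert abs(sum(STAGGERED.values()) - 1.0) < 1e-12, sum(STAGGERED.values())
    assert len(STAGGERED) == 27 and len(EVEN_TAXA) == 11

    taxa = sorted(set(EVEN_TAXA) | set(STAGGERED))
    refs = generate_clone_references(
        len(taxa), length=SEQ_LENGTH, seed=SEQ_SEED, labels=taxa
    )
    by_id = {r.clone_id: r for r in refs}

    even = MockCommunityDef(
        community_id="even_mock",
        kind="even",
        members=tuple((by_id[t], 1.0 / len(EVEN_TAXA)) for t in EVEN_TAXA),
    )
    write_mock_definition(even, DATA / "even_mock.json", DATA / "even_mock_synthetic.fasta")

    staggered = MockCommunityDef(
        community_id="staggered_mock",
        kind="staggered",
        members=tuple((by_id[t], p) for t, p in STAGGERED.items()),
    )
    write_mock_definition(
        staggered, DATA / "staggered_mock.json", DATA / "staggered_mock_synthetic.fasta"
    )
    print(f"wrote fixtures for {len(taxa)} distinct clones to {DATA}")


if __name__ == "__main__":
    main()
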