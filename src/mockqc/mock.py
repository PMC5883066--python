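"""Mock community definitions and the in-silico expected ("perfect mock") profile.

A mock community is a defined mixture of cloned marker-gene sequences
(here: marine 16S rRNA clones) added to every sequencing run as a standard
of known composition.  Two designs are packaged: an *even* community
(11 clones, equal proportions) and a *staggered* community (27 clones at
deliberately unequal proportions mimicking a natural marine assemblage).

The in-silico expected profile is the community at its exact known
proportions; it serves both as the x-axis of the observed-vs-expected QC
regression and, rendered as a read file by :func:`make_insilico_spike`, as
a tracer that can be carried through an external clustering pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CloneReference",
    "MockCommunityDef",
    "ExpectedProfile",
    "load_mock_definition",
    "write_mock_definition",
    "build_expected_profile",
    "make_insilico_spike",
    "even_mock",
    "staggered_mock",
]

_ACGT = frozenset("ACGT")
#: minimum accepted reference length (shorter than any real 16S amplicon)
MIN_REFERENCE_LENGTH = 100


@dataclass(frozen=True)
class CloneReference:
    """One cloned reference sequence of a mock community member.

    Parameters
    ----------
    clone_id
        Short unique identifier (e.g. ``"MGII"``, ``"SAR11"``).
    taxon_label
        Free-text taxon name as it would appear in a figure legend.
    sequence
        Nucleotide sequence over A/C/G/T; ambiguity codes are rejected.
    group_tag
        Optional coarse group used by bias profiles.
    """

    clone_id: str
    taxon_label: str
    sequence: str
    group_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.clone_id:
            raise ValueError("clone_id must be a non-empty string")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < MIN_REFERENCE_LENGTH:
            raise ValueError(
                f"clone {self.clone_id!r}: sequence length {len(seq)} "
                f"< {MIN_REFERENCE_LENGTH}"
            )
        bad = set(seq) - _ACGT
        if bad:
            raise ValueError(
                f"clone {self.clone_id!r}: non-ACGT characters {sorted(bad)} "
                "(ambiguity codes are not allowed in references)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MockCommunityDef:
    """A mock community: clones plus their expected proportions.

    ``members`` maps each :class:`CloneReference` to its expected proportion
    (a fraction in (0, 1]); proportions must sum to 1 and, for ``kind ==
    "even"``, must all be equal.
    """

    community_id: str
    kind: str  # "even" | "staggered"
    members: tuple[tuple[CloneReference, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("even", "staggered"):
            raise ValueError(f"kind must be 'even' or 'staggered', got {self.kind!r}")
        if len(self.members) < 2:
            raise ValueError("a mock community needs at least 2 members")
        ids = [ref.clone_id for ref, _ in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate clone_id(s): {dupes}")
        total = sum(p for _, p in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"expected proportions sum to {total!r}, not 1")
        for ref, p in self.members:
            if not 0.0 < p <= 1.0:
                raise ValueError(f"clone {ref.clone_id!r}: proportion {p} not in (0, 1]")
        if self.kind == "even":
            first = self.members[0][1]
            if any(abs(p - first) > 1e-9 for _, p in self.members):
                raise ValueError("kind 'even' requires all proportions equal")

    @property
    def clone_ids(self) -> tuple[str, ...]:
        return tuple(ref.clone_id for ref, _ in self.members)

    @property
    def proportions(self) -> dict[str, float]:
        return {ref.clone_id: p for ref, p in self.members}

    @property
    def references(self) -> dict[str, CloneReference]:
        return {ref.clone_id: ref for ref, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ExpectedProfile:
    """Per-clone expected relative abundance — the in-silico "perfect mock"."""

    community_id: str
    abundances: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"expected abundances sum to {total!r}, not 1")

    def as_percent(self) -> dict[str, float]:
        """Abundances on the percent scale used in reports and figures."""
        return {k: 100.0 * v for k, v in self.abundances.items()}


def load_mock_definition(def_path: str | Path, fasta_path: str | Path) -> MockCommunityDef:
    """Load a mock community from a JSON definition plus a reference FASTA.

    The JSON lists ``community_id``, ``kind`` and ``members`` (each with
    ``clone_id``, ``taxon_label``, ``expected_proportion`` and optionally
    ``group_tag``); the FASTA headers carry the matching clone_ids.

    Proportions are renormalized silently when they differ from 1 by at
    most 1e-6, renormalized with a warning when within 1e-3, and rejected
    otherwise.
    """
    with open(def_path) as fh:
        spec = json.load(fh)
    for key in ("community_id", "kind", "members"):
        if key not in spec:
            raise ValueError(f"mock definition JSON missing key {key!r}")

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate clone_id {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq)

    member_ids = [m["clone_id"] for m in spec["members"]]
    if len(set(member_ids)) != len(member_ids):
        dupes = sorted({i for i in member_ids if member_ids.count(i) > 1})
        raise ValueError(f"duplicate clone_id(s) in definition JSON: {dupes}")
    missing = set(member_ids) - set(seqs)
    if missing:
        raise ValueError(f"clones without a FASTA sequence: {sorted(missing)}")
    extra = set(seqs) - set(member_ids)
    if extra:
        raise ValueError(f"FASTA sequences without a JSON member: {sorted(extra)}")

    props = {m["clone_id"]: float(m["expected_proportion"]) for m in spec["members"]}
    total = sum(props.values())
    if abs(total - 1.0) > 1e-3:
        raise ValueError(
            f"expected proportions sum to {total:.6f}; more than 1e-3 from 1 — rejected"
        )
    if abs(total - 1.0) > 1e-6:
        warnings.warn(
            f"expected proportions sum to {total:.6f}; renormalizing to 1",
            stacklevel=2,
        )
    if abs(total - 1.0) > 1e-9:  # keep stored proportions bit-exact otherwise
        props = {k: v / total for k, v in props.items()}

    members = tuple(
        (
            CloneReference(
                clone_id=m["clone_id"],
                taxon_label=m.get("taxon_label", m["clone_id"]),
                sequence=seqs[m["clone_id"]],
                group_tag=m.get("group_tag"),
            ),
            props[m["clone_id"]],
        )
        for m in spec["members"]
    )
    return MockCommunityDef(
        community_id=spec["community_id"], kind=spec["kind"], members=members
    )


def write_mock_definition(
    definition: MockCommunityDef, def_path: str | Path, fasta_path: str | Path
) -> None:
    """Write a definition back to JSON + FASTA (round-trips proportions exactly)."""
    spec = {
        "community_id": definition.community_id,
        "kind": definition.kind,
        "members": [
            {
                "clone_id": ref.clone_id,
                "taxon_label": ref.taxon_label,
                "expected_proportion": p,
                **({"group_tag": ref.group_tag} if ref.group_tag else {}),
            }
            for ref, p in definition.members
        ],
    }
    with open(def_path, "w") as fh:
        json.dump(spec, fh, indent=1)
        fh.write("\n")
    records = [
        SeqRecord(Seq(ref.sequence), id=ref.clone_id, description=ref.taxon_label)
        for ref, _ in definition.members
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def build_expected_profile(definition: MockCommunityDef) -> ExpectedProfile:
    """The in-silico expected profile: each clone at its exact proportion."""
    return ExpectedProfile(
        community_id=definition.community_id, abundances=definition.proportions
    )


def _largest_remainder(proportions: dict[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` integer copies to clones by largest remainder.

    Guarantees the counts sum to ``total`` exactly.  Ties in fractional part
    are broken by clone_id so the result is deterministic.
    """
    quotas = {cid: p * total for cid, p in proportions.items()}
    counts = {cid: int(q) for cid, q in quotas.items()}
    leftover = total - sum(counts.values())
    by_remainder = sorted(
        quotas, key=lambda cid: (-(quotas[cid] - counts[cid]), cid)
    )
    for cid in by_remainder[:leftover]:
        counts[cid] += 1
    return counts


def make_insilico_spike(
    definition: MockCommunityDef, total_reads: int
) -> list[SeqRecord]:
    """Render the expected profile as sequences, for spiking into a pipeline.

    Emits ``round(p_i * total_reads)`` copies of each clone's reference
    (largest-remainder rounding, so copies sum to ``total_reads`` exactly),
    ordered by clone_id.  If ``total_reads`` is too small to represent the
    rarest clone at one copy, that clone is still emitted once (with a
    warning) and the excess is removed from the most abundant clones.
    """
    n = len(definition)
    if total_reads < n:
        raise ValueError(f"total_reads={total_reads} < number of clones ({n})")
    counts = _largest_remainder(definition.proportions, int(total_reads))
    zeros = sorted(cid for cid, c in counts.items() if c == 0)
    if zeros:
        warnings.warn(
            f"total_reads={total_reads} too small for clone(s) {zeros}; "
            "emitting them at 1 copy and rebalancing",
            stacklevel=2,
        )
        for cid in zeros:
            counts[cid] = 1
        excess = sum(counts.values()) - int(total_reads)
        while excess > 0:
            richest = max(sorted(counts), key=lambda cid: counts[cid])
            counts[richest] -= 1
            excess -= 1
    refs = definition.references
    records: list[SeqRecord] = []
    for cid in sorted(counts):
        ref = refs[cid]
        for i in range(counts[cid]):
            records.append(
                SeqRecord(
                    Seq(ref.sequence),
                    id=f"{cid}_spike_{i + 1}",
                    description=f"in-silico {definition.community_id}",
                )
            )
    return records


def _packaged(name: str) -> MockCommunityDef:
    root = resources.files("mockqc.data")
    with resources.as_file(root / f"{name}_mock.json") as jp, resources.as_file(
        root / f"{name}_mock_synthetic.fasta"
    ) as fp:
        return load_mock_definition(jp, fp)


def even_mock() -> MockCommunityDef:
    """The packaged 11-clone even mock community (synthetic reference sequences)."""
    return _packaged("even")


def staggered_mock() -> MockCommunityDef:
    """The packaged 27-clone staggered mock community (synthetic reference sequences)."""
    return _packaged("staggered")
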