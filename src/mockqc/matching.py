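"""Feature tables, feature-to-clone attribution, and blank checks.

Observed features (OTUs or ASVs — the table is agnostic to their origin)
are assigned to mock clones by global pairwise identity against the clone
references, reusing the 99% similarity level at which the features were
clustered.  Identity is matches over full alignment length, so gap columns
count against identity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .mock import MockCommunityDef

__all__ = [
    "FeatureTable",
    "CloneMap",
    "CloneProfile",
    "BlankResult",
    "read_feature_table",
    "read_representative_seqs",
    "match_features",
    "collapse_profile",
    "blank_check",
]

ROLES = ("mock", "blank", "field")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class FeatureTable:
    """Counts of features per sample, with per-sample metadata.

    ``counts`` is a features x samples DataFrame of non-negative integers;
    ``metadata`` is indexed by sample_id with columns ``run_id``,
    ``platform``, ``role`` (mock/blank/field) and ``community_id``
    (required for mock samples).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if not np.issubdtype(counts.to_numpy().dtype, np.integer):
            arr = counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("feature counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("feature counts must be non-negative")
        self.counts = counts

        meta = self.metadata
        required = {"run_id", "platform", "role"}
        missing_cols = required - set(meta.columns)
        if missing_cols:
            raise ValueError(f"metadata missing column(s): {sorted(missing_cols)}")
        if "community_id" not in meta.columns:
            meta = meta.assign(community_id=pd.NA)
        missing = set(counts.columns) - set(meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad_roles = set(meta["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown role value(s): {sorted(bad_roles)}; expected {ROLES}")
        mock_no_comm = [
            s
            for s in meta.index
            if meta.at[s, "role"] == "mock" and not _present(meta.at[s, "community_id"])
        ]
        if mock_no_comm:
            raise ValueError(f"mock sample(s) without community_id: {mock_no_comm}")
        self.metadata = meta.loc[list(counts.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples(self, run_id: str | None = None, role: str | None = None) -> list[str]:
        meta = self.metadata
        mask = pd.Series(True, index=meta.index)
        if run_id is not None:
            mask &= meta["run_id"] == run_id
        if role is not None:
            mask &= meta["role"] == role
        return list(meta.index[mask])

    @property
    def run_ids(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["run_id"]))


def _present(value) -> bool:
    return not (pd.isna(value) or value == "")


@dataclass(frozen=True)
class CloneMap:
    """Feature-to-clone assignments with the supporting alignment identity."""

    assignments: dict[str, str | None] = field(hash=False)
    identities: dict[str, float] = field(hash=False)
    identity_threshold: float = 0.99

    def clone_of(self, feature_id: str) -> str | None:
        return self.assignments.get(feature_id)

    @property
    def assigned(self) -> dict[str, str]:
        return {f: c for f, c in self.assignments.items() if c is not None}


@dataclass(frozen=True)
class CloneProfile:
    """Per-clone relative abundances of one mock sample.

    ``mode`` records the normalization: ``"assigned"`` (over counts mapped
    to any clone; matches plotting percentages over mock members) or
    ``"total"`` (over all counts in the sample).
    """

    sample_id: str
    abundances: dict[str, float] = field(hash=False)
    unassigned_fraction: float = 0.0
    mode: str = "assigned"

    def as_vector(self, clone_ids) -> np.ndarray:
        return np.array([self.abundances[c] for c in clone_ids], dtype=float)


def read_feature_table(table_path: str | Path, meta_path: str | Path) -> FeatureTable:
    """Read a features x samples TSV and a sample-metadata TSV.

    Both files are UTF-8 tab-delimited; lines starting with ``#`` are
    ignored.  The first table column holds feature_ids; metadata needs
    ``sample_id``, ``run_id``, ``platform``, ``role`` and ``community_id``
    columns.
    """
    counts = pd.read_csv(table_path, sep="\t", comment="#", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata TSV must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    return FeatureTable(counts=counts, metadata=meta)


def read_representative_seqs(fasta_path: str | Path) -> dict[str, str]:
    """Representative sequences keyed by feature_id from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def global_identity(a: str, b: str) -> float:
    """Global (end-to-end) alignment identity: matches / alignment length.

    Gap columns are part of the alignment length, so they count against
    identity.  Empty sequences have identity 0.
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    align_len = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (align_len - res["editDistance"]) / align_len


def match_features(
    rep_seqs: Mapping[str, str],
    definition: MockCommunityDef,
    identity_threshold: float = 0.99,
) -> CloneMap:
    """Assign each feature to the clone with the highest global identity.

    A feature is assigned only when its best identity reaches
    ``identity_threshold`` (default 0.99, the clustering similarity level);
    ties are broken by higher identity, then lexicographic clone_id.
    """
    refs = definition.references
    assignments: dict[str, str | None] = {}
    identities: dict[str, float] = {}
    for fid, seq in rep_seqs.items():
        if not seq:
            warnings.warn(f"feature {fid!r} has an empty sequence; left unassigned")
            assignments[fid] = None
            identities[fid] = 0.0
            continue
        best_clone, best_ident = None, -1.0
        for cid in sorted(refs):
            ident = global_identity(seq, refs[cid].sequence)
            if ident > best_ident:
                best_clone, best_ident = cid, ident
        identities[fid] = best_ident
        assignments[fid] = best_clone if best_ident >= identity_threshold else None
    return CloneMap(
        assignments=assignments,
        identities=identities,
        identity_threshold=identity_threshold,
    )


def collapse_profile(
    table: FeatureTable,
    clone_map: CloneMap,
    sample_id: str,
    definition: MockCommunityDef | None = None,
    mode: str = "assigned",
) -> CloneProfile:
    """Collapse one mock sample's feature counts to per-clone abundances.

    Clones with zero observed counts are present at abundance 0 (the
    "disappearing taxon" case the QC exists to catch).  ``mode="assigned"``
    normalizes over counts assigned to any clone; ``mode="total"`` over all
    counts in the sample.
    """
    if mode not in ("assigned", "total"):
        raise ValueError(f"mode must be 'assigned' or 'total', got {mode!r}")
    if sample_id not in table.sample_ids:
        raise KeyError(f"sample {sample_id!r} not in table")
    if table.metadata.at[sample_id, "role"] != "mock":
        raise ValueError(f"sample {sample_id!r} is not a mock sample")
    col = table.counts[sample_id]
    total = int(col.sum())
    if total == 0:
        raise ValueError(f"sample {sample_id!r} has zero total counts")

    clone_counts: dict[str, int] = {}
    if definition is not None:
        clone_counts.update({cid: 0 for cid in definition.clone_ids})
    else:
        clone_counts.update({c: 0 for c in clone_map.assigned.values()})
    assigned_total = 0
    for fid, count in col.items():
        cid = clone_map.clone_of(fid)
        if cid is not None:
            clone_counts[cid] = clone_counts.get(cid, 0) + int(count)
            assigned_total += int(count)
    if assigned_total == 0:
        raise ValueError(f"sample {sample_id!r} has no counts assigned to any clone")
    denom = assigned_total if mode == "assigned" else total
    abundances = {cid: c / denom for cid, c in clone_counts.items()}
    return CloneProfile(
        sample_id=sample_id,
        abundances=abundances,
        unassigned_fraction=(total - assigned_total) / total,
        mode=mode,
    )


@dataclass(frozen=True)
class BlankResult:
    sample_id: str
    total_counts: int
    max_allowed: float
    passed: bool


def blank_check(
    table: FeatureTable, run_id: str, max_fraction: float = 0.01
) -> dict[str, BlankResult]:
    """Check that a run's blanks are clean (few reads).

    A blank passes when its total counts are below ``max_fraction`` (default
    1%) of the median total counts over the run's mock samples.  Returns one
    result per blank; an empty dict when the run has no blanks.  With no
    mock samples in the run the check is skipped with a warning.
    """
    blanks = table.samples(run_id=run_id, role="blank")
    mocks = table.samples(run_id=run_id, role="mock")
    if not mocks:
        warnings.warn(f"run {run_id!r} has no mock samples; blank check skipped")
        return {}
    median_mock = float(np.median([table.counts[s].sum() for s in mocks]))
    limit = max_fraction * median_mock
    return {
        s: BlankResult(
            sample_id=s,
            total_counts=int(table.counts[s].sum()),
            max_allowed=limit,
            passed=int(table.counts[s].sum()) < limit,
        )
        for s in blanks
    }
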