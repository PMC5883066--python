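"""Synthetic mock-community runs with controlled biases and read errors.

The generator is the package's stand-in for real sequencing runs: it draws
mock-replicate feature counts from a multinomial over bias-perturbed
expected proportions, and reads as substrings of the clone references with
independent per-base substitution errors.  Two named bias presets bracket
the regimes a lab's run QC must distinguish:

* ``normal``   — all multipliers 1 with per-clone lognormal jitter
  (sigma 0.1, so per-clone folds stay essentially below 1.3-fold, the
  normal run-to-run spread between platforms);
* ``aberrant`` — the disappearing-taxon pattern: the marine group II
  (MGII) archaea clone drops out (or to ~0.15% in the even design),
  SAR11 and Flavobacteria are over-represented more than twofold, and
  Thaumarchaea and Prochlorococcus under-represented more than twofold.

Everything is seeded; identical configurations give byte-identical output
bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import FeatureTable
from .mock import CloneReference, MockCommunityDef, write_mock_definition

__all__ = [
    "BiasProfile",
    "SimConfig",
    "normal_bias",
    "aberrant_bias",
    "generate_clone_references",
    "biased_proportions",
    "simulate_mock_sample",
    "simulate_study",
    "MockSample",
    "StudyBundle",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: aberrant multipliers for the staggered design: MGII dropout, two clones
#: over- and two under-represented beyond twofold, everything else unbiased.
#: The input multipliers exceed 2 (and fall below 1/2) by enough margin
#: that the *renormalized* observed abundances still deviate more than
#: twofold from baseline — renormalization compresses the applied bias.
ABERRANT_STAGGERED_MULTIPLIERS: dict[str, float] = {
    "MGII": 0.0,
    "SAR11": 3.0,
    "Flavobacteria": 3.0,
    "Thaumarchaea": 0.4,
    "Prochlorococcus": 0.4,
}

_ABERRANT_EVEN_OTHERS: dict[str, float] = {
    "SAR11": 3.0,
    "Flavobacteria": 3.0,
    "Thaumarchaea": 0.4,
    "Prochlorococcus": 0.4,
}

#: MGII multiplier for the aberrant even design, solved from
#: m / (m + S) = 0.0015 with S the summed multipliers of the 10 other
#: even-mock clones, so the renormalized biased even-mock MGII abundance
#: lands at exactly 0.15% (the observed near-disappearance)
_S_OTHERS = sum(_ABERRANT_EVEN_OTHERS.values()) + (11 - 1 - len(_ABERRANT_EVEN_OTHERS))
ABERRANT_EVEN_MGII_MULTIPLIER = _S_OTHERS * 0.0015 / (1 - 0.0015)

ABERRANT_EVEN_MULTIPLIERS: dict[str, float] = {
    "MGII": ABERRANT_EVEN_MGII_MULTIPLIER,
    **_ABERRANT_EVEN_OTHERS,
}

#: run-to-run lognormal jitter of a well-behaved run (folds < ~1.3)
DEFAULT_SIGMA = 0.1


@dataclass(frozen=True)
class BiasProfile:
    """Per-clone multiplicative biases plus per-replicate lognormal jitter.

    ``multipliers`` maps clone_id to a non-negative factor (0 = dropout);
    clones not listed get 1.  ``sigma`` is the standard deviation of the
    per-clone, per-replicate lognormal noise on the natural-log scale.
    """

    name: str
    multipliers: Mapping[str, float] = field(default_factory=dict)
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for cid, m in self.multipliers.items():
            if m < 0:
                raise ValueError(f"multiplier for {cid!r} must be >= 0")

    def multiplier(self, clone_id: str) -> float:
        return float(self.multipliers.get(clone_id, 1.0))


def normal_bias(sigma: float = DEFAULT_SIGMA) -> BiasProfile:
    """The well-behaved-run preset: no systematic bias, jitter only."""
    return BiasProfile(name="normal", multipliers={}, sigma=sigma)


def aberrant_bias(kind: str = "staggered", sigma: float = DEFAULT_SIGMA) -> BiasProfile:
    """The disappearing-taxon preset for the given community design."""
    if kind == "staggered":
        return BiasProfile(
            name="aberrant_staggered",
            multipliers=dict(ABERRANT_STAGGERED_MULTIPLIERS),
            sigma=sigma,
        )
    if kind == "even":
        return BiasProfile(
            name="aberrant_even", multipliers=dict(ABERRANT_EVEN_MULTIPLIERS), sigma=sigma
        )
    raise ValueError(f"kind must be 'even' or 'staggered', got {kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated run.

    depth
        Reads per mock replicate (counts drawn multinomially).
    n_replicates
        Mock replicates per run (real runs carried 1-4).
    seed
        Mandatory; there is no implicit randomness anywhere.
    bias
        The :class:`BiasProfile` applied to the expected proportions.
    read_length / per_base_error
        Read simulation: substring length and i.i.d. substitution
        probability (default 3.3e-4, the top of the observed per-run
        error-rate range).
    reads_per_replicate
        Number of reads to emit per replicate (0 = counts only).
    """

    community_id: str
    seed: int
    depth: int = 100_000
    n_replicates: int = 3
    bias: BiasProfile = field(default_factory=normal_bias)
    read_length: int = 250
    per_base_error: float = 3.3e-4
    reads_per_replicate: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if not 0 <= self.per_base_error < 1:
            raise ValueError("per_base_error must be in [0, 1)")


# ---------------------------------------------------------------------------
# clone reference generation

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_clone_references(
    n_clones: int,
    length: int = 800,
    min_pairwise_divergence: float = 0.03,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
    max_tries_per_clone: int = 100,
) -> list[CloneReference]:
    """Random clone references with bounded pairwise similarity.

    Rejection-samples random sequences until every pair is at most
    ``1 - min_pairwise_divergence`` identical (global identity), so that a
    99% identity threshold attributes mutated copies unambiguously.
    Deterministic for a given seed.  Stands in for real clone sequences,
    which are not redistributed with this package.
    """
    from .matching import global_identity

    if n_clones < 2:
        raise ValueError("n_clones must be >= 2")
    if labels is not None and len(labels) != n_clones:
        raise ValueError("labels length must equal n_clones")
    rng = np.random.default_rng(seed)
    max_identity = 1.0 - min_pairwise_divergence
    accepted: list[str] = []
    for i in range(n_clones):
        for _ in range(max_tries_per_clone):
            cand = _random_sequence(rng, length)
            if all(global_identity(cand, s) <= max_identity for s in accepted):
                accepted.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not generate clone {i + 1} at divergence "
                f">= {min_pairwise_divergence} after {max_tries_per_clone} tries"
            )
    names = labels if labels is not None else [f"clone{i + 1:02d}" for i in range(n_clones)]
    return [
        CloneReference(clone_id=name, taxon_label=name, sequence=seq)
        for name, seq in zip(names, accepted)
    ]


# ---------------------------------------------------------------------------
# biased proportions and sampling

def biased_proportions(
    definition: MockCommunityDef,
    bias: BiasProfile,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Apply a bias profile to the expected proportions and renormalize.

    p'_i is proportional to p_i * multiplier_i * exp(N(0, sigma^2)); the
    jitter is drawn per clone (pass a seed or Generator; with sigma 0 the
    result is deterministic regardless).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cids = list(definition.clone_ids)
    props = definition.proportions
    mult = np.array([bias.multiplier(c) for c in cids])
    if np.all(mult == 0):
        raise ValueError("all bias multipliers are zero")
    p = np.array([props[c] for c in cids]) * mult
    if bias.sigma > 0:
        p = p * np.exp(rng.normal(0.0, bias.sigma, size=len(cids)))
    p = p / p.sum()
    return dict(zip(cids, p.tolist()))


@dataclass(frozen=True)
class MockSample:
    """One simulated mock replicate: counts, representative seqs, reads."""

    sample_id: str
    counts: dict[str, int] = field(hash=False)
    rep_seqs: dict[str, str] = field(hash=False)
    reads: tuple[str, ...] = ()
    proportions_used: dict[str, float] = field(default_factory=dict, hash=False)


def _mutate(read: np.ndarray, rng: np.random.Generator, per_base_error: float) -> np.ndarray:
    n_err = rng.binomial(len(read), per_base_error)
    if n_err == 0:
        return read
    pos = rng.choice(len(read), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != read[p]]
        read[p] = rng.choice(choices)
    return read


def simulate_mock_sample(
    definition: MockCommunityDef,
    config: SimConfig,
    replicate: int = 0,
    sample_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> MockSample:
    """Simulate one mock replicate.

    Counts are multinomial(depth, biased proportions) with one feature per
    clone (feature_id == clone_id); reads are random substrings of length
    ``read_length`` from the clone references with i.i.d. substitutions at
    ``per_base_error``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, replicate])
    refs = definition.references
    min_ref = min(len(r.sequence) for r in refs.values())
    if config.reads_per_replicate and config.read_length > min_ref:
        raise ValueError(
            f"read_length {config.read_length} exceeds the shortest reference ({min_ref})"
        )
    props = biased_proportions(definition, config.bias, seed=rng)
    cids = list(definition.clone_ids)
    pvec = np.array([props[c] for c in cids])
    counts = rng.multinomial(config.depth, pvec)
    count_map = dict(zip(cids, (int(c) for c in counts)))

    reads: list[str] = []
    if config.reads_per_replicate:
        clone_idx = rng.choice(len(cids), size=config.reads_per_replicate, p=pvec)
        for ci in clone_idx:
            seq = refs[cids[ci]].sequence
            start = int(rng.integers(0, len(seq) - config.read_length + 1))
            frag = np.frombuffer(
                seq[start : start + config.read_length].encode(), dtype="S1"
            ).copy()
            reads.append(_mutate(frag, rng, config.per_base_error).tobytes().decode())

    sid = sample_id or f"{definition.community_id}_rep{replicate + 1}"
    return MockSample(
        sample_id=sid,
        counts=count_map,
        rep_seqs={c: refs[c].sequence for c in cids},
        reads=tuple(reads),
        proportions_used=props,
    )


# ---------------------------------------------------------------------------
# whole-study simulation

@dataclass
class StudyBundle:
    """A simulated multi-run study: feature table, reads, manifest."""

    definition: MockCommunityDef
    table: FeatureTable
    reads: dict[str, tuple[str, ...]]  # sample_id -> reads
    manifest: dict

    @property
    def run_ids(self) -> list[str]:
        return self.table.run_ids

    @property
    def aberrant_run_id(self) -> str | None:
        return self.manifest.get("aberrant_run_id")

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle as the TSV/FASTA/JSON files the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.counts.rename_axis("feature_id").to_csv(
            out / "feature_table.tsv", sep="\t"
        )
        self.table.metadata.rename_axis("sample_id").to_csv(
            out / "sample_metadata.tsv", sep="\t"
        )
        write_mock_definition(
            self.definition, out / "mock_def.json", out / "mock_refs.fasta"
        )
        with open(out / "rep_seqs.fasta", "w") as fh:
            for ref, _ in self.definition.members:
                fh.write(f">{ref.clone_id}\n{ref.sequence}\n")
        for sid, reads in self.reads.items():
            if not reads:
                continue
            with open(out / f"reads_{sid}.fasta", "w") as fh:
                for i, r in enumerate(reads):
                    fh.write(f">{sid}_read{i + 1}\n{r}\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")


def simulate_study(
    definition: MockCommunityDef,
    k_runs: int = 5,
    seed: int = 0,
    depth: int = 100_000,
    n_replicates: int = 3,
    normal: BiasProfile | None = None,
    aberrant: BiasProfile | None = None,
    include_aberrant: bool = True,
    reads_per_replicate: int = 0,
    platform: str = "sim",
) -> StudyBundle:
    """Simulate ``k_runs`` normal runs plus (optionally) one aberrant run.

    Each run carries ``n_replicates`` mock replicates and one near-empty
    blank.  The output bundle holds one feature table spanning all runs
    with per-sample metadata, per-sample reads (when requested) and a
    manifest of every parameter and seed.
    """
    if k_runs < 1:
        raise ValueError("k_runs must be >= 1")
    normal = normal or normal_bias()
    if aberrant is None:
        aberrant = aberrant_bias(definition.kind)

    runs: list[tuple[str, BiasProfile]] = [
        (f"run{i + 1:02d}", normal) for i in range(k_runs)
    ]
    aberrant_run_id = None
    if include_aberrant:
        aberrant_run_id = f"run{k_runs + 1:02d}_aberrant"
        runs.append((aberrant_run_id, aberrant))

    columns: dict[str, dict[str, int]] = {}
    meta_rows: list[dict] = []
    reads: dict[str, tuple[str, ...]] = {}
    for run_idx, (run_id, bias) in enumerate(runs):
        config = SimConfig(
            community_id=definition.community_id,
            seed=seed,
            depth=depth,
            n_replicates=n_replicates,
            bias=bias,
            reads_per_replicate=reads_per_replicate,
        )
        for rep in range(n_replicates):
            rng = np.random.default_rng([seed, run_idx, rep])
            sid = f"{run_id}_mock{rep + 1}"
            sample = simulate_mock_sample(
                definition, config, replicate=rep, sample_id=sid, rng=rng
            )
            columns[sid] = sample.counts
            reads[sid] = sample.reads
            meta_rows.append(
                {
                    "sample_id": sid,
                    "run_id": run_id,
                    "platform": platform,
                    "role": "mock",
                    "community_id": definition.community_id,
                }
            )
        # blank: a handful of stray reads on random clones
        brng = np.random.default_rng([seed, run_idx, 9999])
        blank_counts = {c: 0 for c in definition.clone_ids}
        for _ in range(int(brng.poisson(3))):
            blank_counts[definition.clone_ids[brng.integers(len(definition))]] += 1
        bsid = f"{run_id}_blank"
        columns[bsid] = blank_counts
        meta_rows.append(
            {
                "sample_id": bsid,
                "run_id": run_id,
                "platform": platform,
                "role": "blank",
                "community_id": "",
            }
        )

    counts = pd.DataFrame(
        {sid: pd.Series(col) for sid, col in columns.items()}, dtype=np.int64
    ).fillna(0).astype(np.int64)
    counts = counts.loc[list(definition.clone_ids)]
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = FeatureTable(counts=counts, metadata=meta)

    manifest = {
        "community_id": definition.community_id,
        "kind": definition.kind,
        "k_runs": k_runs,
        "aberrant_run_id": aberrant_run_id,
        "depth": depth,
        "n_replicates": n_replicates,
        "seed": int(seed),
        "normal_bias": {"name": normal.name, "sigma": normal.sigma,
                        "multipliers": dict(normal.multipliers)},
        "aberrant_bias": None
        if not include_aberrant
        else {"name": aberrant.name, "sigma": aberrant.sigma,
              "multipliers": dict(aberrant.multipliers)},
        "reads_per_replicate": reads_per_replicate,
        "platform": platform,
    }
    return StudyBundle(definition=definition, table=table, reads=reads, manifest=manifest)
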