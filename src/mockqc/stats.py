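"""QC statistics for mock-community sequencing runs.

The central statistic is the coefficient of determination (R^2) of an
ordinary least-squares regression of observed on expected clone abundances,
both on a log10(x + 0.001) scale.  The pseudocount keeps dropped-out clones
(observed abundance 0) finite, and acts at the magnitude of the rarest
staggered members (~0.1-2%), which is exactly the regime a run-QC must
discriminate.  A run whose R^2 falls below ~0.85 warrants questioning; the
complementary per-clone checks flag any clone >10-fold below the baseline
average over other runs, or multiple clones >2-fold off it.

Also here: Bray-Curtis distances between mock replicates, Wilcoxon
rank-sum and ANOSIM tests for comparing groups of runs or platforms, and
the alignment-based sequence error rate (sum of mismatches to the
reference over the sum of query bases).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iterpermutations
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.stats import norm, rankdata

from .mock import ExpectedProfile, MockCommunityDef
from .matching import CloneProfile

__all__ = [
    "RegressionResult",
    "DeviationFlags",
    "ErrorRateResult",
    "log_shift",
    "r2_qc",
    "fold_deviations",
    "bray_curtis",
    "bray_curtis_matrix",
    "wilcoxon_rank_sum",
    "anosim",
    "estimate_error_rate",
]

#: pseudocount on the fraction scale — 0.1 percentage points
DEFAULT_PSEUDOCOUNT = 1e-3


# ---------------------------------------------------------------------------
# log-shift transform and observed-vs-expected regression

def log_shift(x, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log10(x + pseudocount) for relative abundances x in [0, 1].

    Accepts scalars or arrays; negative abundances are rejected.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    out = np.log10(arr + pseudocount)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of log-shifted observed on log-shifted expected abundances."""

    slope: float
    intercept: float
    r2: float
    n_points: int

    def __str__(self) -> str:
        return (
            f"R^2 = {self.r2:.3f} (slope {self.slope:.3f}, "
            f"intercept {self.intercept:.3f}, n = {self.n_points})"
        )


def _as_abundance_dict(profile) -> Mapping[str, float]:
    if isinstance(profile, (CloneProfile, ExpectedProfile)):
        return profile.abundances
    return profile


def r2_qc(
    observed,
    expected,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RegressionResult:
    """Observed-vs-expected regression of one mock sample.

    Ordinary least squares (with intercept) of log10(observed + pc) on
    log10(expected + pc) over all clones, dropped-out clones included at
    observed 0.  R^2 equals the squared Pearson correlation of the
    log-shifted vectors.

    ``observed`` and ``expected`` may be :class:`~mockqc.matching.CloneProfile`,
    :class:`~mockqc.mock.ExpectedProfile` or plain clone->fraction mappings
    sharing the same clone set.  Staggered designs are required in practice:
    an even design has no variation on the expected axis and the regression
    is degenerate.
    """
    obs = _as_abundance_dict(observed)
    exp = _as_abundance_dict(expected)
    if set(obs) != set(exp):
        raise ValueError(
            "observed and expected clone sets differ: "
            f"{sorted(set(obs) ^ set(exp))}"
        )
    clones = sorted(exp)
    if len(clones) < 3:
        raise ValueError("regression needs at least 3 clones")
    x = log_shift(np.array([exp[c] for c in clones]), pseudocount)
    y = log_shift(np.array([obs[c] for c in clones]), pseudocount)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx < 1e-24:
        raise ValueError(
            "expected abundances have no variation on the log scale "
            "(even design?); the QC regression requires a staggered mock"
        )
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy < 1e-24:
        # flat-but-perfectly-predicted observations: define R^2 = 1
        r2 = 1.0
    else:
        ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
        r2 = 1.0 - ss_res / syy
    return RegressionResult(
        slope=slope, intercept=intercept, r2=min(max(r2, 0.0), 1.0), n_points=len(clones)
    )


# ---------------------------------------------------------------------------
# per-clone fold deviations against a multi-run baseline

@dataclass(frozen=True)
class DeviationFlags:
    """Per-clone fold deviations of one run from the baseline average.

    ``folds`` maps clone_id to a (fold, direction) pair with fold >= 1 and
    direction "deficit" (baseline above observed) or "excess".  ``flags``
    may contain ``"single_10fold"`` (some clone >10-fold below baseline,
    the disappearing-taxon signature) and ``"multi_2fold"`` (at least
    ``min_multiple`` clones >2-fold off baseline in either direction).
    """

    folds: dict[str, tuple[float, str]] = field(hash=False)
    flags: frozenset[str] = frozenset()
    offenders: dict[str, list[str]] = field(default_factory=dict, hash=False)

    def fold(self, clone_id: str) -> float:
        return self.folds[clone_id][0]


def fold_deviations(
    observed,
    baseline_means: Mapping[str, float],
    ten_fold: float = 10.0,
    two_fold: float = 2.0,
    min_multiple: int = 2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DeviationFlags:
    """Flag clones far from the average over other mock-community runs.

    Folds are pseudocount-adjusted ratios, deficit = (baseline + pc) /
    (observed + pc) and excess the reciprocal arrangement, so a dropout
    against a 1.8% baseline still yields a finite ~19-fold deficit.
    """
    if not baseline_means:
        raise ValueError("baseline is empty")
    obs = _as_abundance_dict(observed)
    missing = set(obs) - set(baseline_means)
    if missing:
        raise ValueError(f"baseline does not cover clone(s): {sorted(missing)}")
    folds: dict[str, tuple[float, str]] = {}
    ten_offenders: list[str] = []
    two_offenders: list[str] = []
    for cid in sorted(obs):
        o = obs[cid] + pseudocount
        b = baseline_means[cid] + pseudocount
        deficit = b / o
        excess = o / b
        if deficit >= excess:
            folds[cid] = (deficit, "deficit")
        else:
            folds[cid] = (excess, "excess")
        if deficit > ten_fold:
            ten_offenders.append(cid)
        if max(deficit, excess) > two_fold:
            two_offenders.append(cid)
    flags = set()
    offenders: dict[str, list[str]] = {}
    if ten_offenders:
        flags.add("single_10fold")
        offenders["single_10fold"] = ten_offenders
    if len(two_offenders) >= min_multiple:
        flags.add("multi_2fold")
        offenders["multi_2fold"] = two_offenders
    return DeviationFlags(folds=folds, flags=frozenset(flags), offenders=offenders)


# ---------------------------------------------------------------------------
# Bray-Curtis distances

def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum|a_i - b_i| / sum(a_i + b_i)."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("vectors must have equal length")
    if np.any(av < 0) or np.any(bv < 0):
        raise ValueError("abundance vectors must be non-negative")
    if av.sum() == 0 and bv.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(av, bv))


def bray_curtis_matrix(profiles: Mapping[str, Sequence[float]]):
    """Pairwise Bray-Curtis distances as a scikit-bio DistanceMatrix.

    ``profiles`` maps sample_id to an abundance vector; vectors must share
    one clone ordering.
    """
    from skbio import DistanceMatrix

    ids = list(profiles)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(profiles[ids[i]], profiles[ids[j]])
    return DistanceMatrix(mat, ids)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) with exact small-sample mode

#: combined sample size at or below which the exact null is used
EXACT_RANKSUM_LIMIT = 12


def _ranksum_null_pmf(doubled_ranks: Sequence[int], n_a: int) -> dict[int, int]:
    """Number of size-n_a subsets attaining each doubled-rank sum.

    Midranks are half-integers, so ranks are doubled to integers and the
    distribution is built by dynamic programming over items (a generating
    function in subset size and sum).
    """
    # dp[k] maps doubled sum -> count, for subsets of size k
    dp: list[dict[int, int]] = [dict() for _ in range(n_a + 1)]
    dp[0][0] = 1
    for r in doubled_ranks:
        for k in range(min(n_a, len(doubled_ranks)) - 1, -1, -1):
            if not dp[k]:
                continue
            nxt = dp[k + 1]
            for s, c in dp[k].items():
                nxt[s + r] = nxt.get(s + r, 0) + c
    return dp[n_a]


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of group_a, p).

    Ties get midranks.  For combined sizes up to 12 the p-value is exact
    (full enumeration of the permutation null via a subset-sum recursion);
    beyond that the normal approximation with tie correction and a 0.5
    continuity correction is used.  Identical pooled values give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    w = float(ranks[:n_a].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0

    if n <= EXACT_RANKSUM_LIMIT:
        doubled = [int(round(2 * r)) for r in ranks]
        pmf = _ranksum_null_pmf(doubled, n_a)
        total = sum(pmf.values())
        w2 = int(round(2 * w))
        p_le = sum(c for s, c in pmf.items() if s <= w2) / total
        p_ge = sum(c for s, c in pmf.items() if s >= w2) / total
        return w, min(1.0, 2.0 * min(p_le, p_ge))

    mean_w = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
    return w, float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# ANOSIM

def _anosim_r(cond_ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    r_within = cond_ranks[within].mean()
    r_between = cond_ranks[~within].mean()
    return float((r_between - r_within) / (n * (n - 1) / 4.0))


def anosim(
    distance_matrix,
    grouping,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    on midranks of the condensed distances; R near 1 means groups are well
    separated, near 0 means no structure.  The p-value is a permutation
    test on group labels: p = (1 + #{R_perm >= R_obs}) / (1 + permutations).
    With ``permutations="exact"`` all distinct label permutations are
    enumerated instead (feasible for a handful of samples).

    ``distance_matrix`` is a square symmetric array or scikit-bio
    DistanceMatrix; ``grouping`` is a sample->group mapping (by id for a
    DistanceMatrix) or a sequence of labels in matrix order.  Every group
    must hold at least 2 samples.
    """
    dm = distance_matrix
    if hasattr(dm, "data") and hasattr(dm, "ids"):  # skbio DistanceMatrix
        mat = np.asarray(dm.data, dtype=float)
        ids = list(dm.ids)
    else:
        mat = np.asarray(dm, dtype=float)
        ids = list(range(mat.shape[0]))
    n = mat.shape[0]
    if mat.shape != (n, n) or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if isinstance(grouping, Mapping):
        labels = np.array([grouping[i] for i in ids])
    else:
        labels = np.asarray(list(grouping))
        if labels.size != n:
            raise ValueError("grouping length does not match matrix size")
    uniq, group_sizes = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if np.any(group_sizes < 2):
        singles = [str(g) for g, c in zip(uniq, group_sizes) if c < 2]
        raise ValueError(f"every group needs >= 2 samples; offending: {singles}")

    iu = np.triu_indices(n, k=1)
    cond_ranks = rankdata(mat[iu])

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(cond_ranks, within_mask(labels), n)

    if permutations == "exact":
        count = total = 0
        seen = set()
        for perm in _iterpermutations(range(n)):
            lab = labels[list(perm)]
            key = tuple(lab)
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if _anosim_r(cond_ranks, within_mask(lab), n) >= r_obs - 1e-12:
                count += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(permutations)):
        lab = rng.permutation(labels)
        if _anosim_r(cond_ranks, within_mask(lab), n) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + int(permutations))


# ---------------------------------------------------------------------------
# sequence error rate

@dataclass(frozen=True)
class ErrorRateResult:
    """Alignment-based sequence error rate of a run's mock reads.

    error_rate_percent = 100 * total_mismatches / total_query_bases, where
    mismatches count substitution columns plus inserted query bases plus
    deleted reference bases inside the aligned span.
    """

    error_rate_percent: float
    total_mismatches: int
    total_query_bases: int
    n_reads: int
    n_rejected: int = 0


def _make_error_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # reads are fragments of the references, so reference overhangs
    # (end gaps in the query row) are free
    for attr, legacy in (
        ("open_left_deletion_score", "query_left_open_gap_score"),
        ("extend_left_deletion_score", "query_left_extend_gap_score"),
        ("open_right_deletion_score", "query_right_open_gap_score"),
        ("extend_right_deletion_score", "query_right_extend_gap_score"),
    ):
        setattr(aligner, attr if hasattr(aligner, attr) else legacy, 0)
    return aligner


def _count_mismatches(aligned_ref: str, aligned_read: str) -> int:
    """Mismatch columns + internal indel bases, reference overhangs excluded."""
    start, end = 0, len(aligned_read)
    while start < end and aligned_read[start] == "-":
        start += 1
    while end > start and aligned_read[end - 1] == "-":
        end -= 1
    mism = 0
    for rc, qc in zip(aligned_ref[start:end], aligned_read[start:end]):
        if rc != qc:  # substitution, insertion (rc == '-') or deletion (qc == '-')
            mism += 1
    return mism


def estimate_error_rate(
    reads: Iterable, definition: MockCommunityDef
) -> ErrorRateResult:
    """Estimate the per-base sequence error rate of mock-community reads.

    Each read is matched to its best clone reference (semi-global edit
    distance over all clones) and then scored against that clone with an
    affine-gap alignment (match +1, mismatch -1, gap open -2, gap extend
    -1) in which the read is global and reference overhangs are free.  The
    error rate is the summed mismatches over the summed read lengths, in
    percent.  Reads longer than twice the longest reference (likely
    chimeras or artifacts) are excluded with a warning.
    """
    seqs: list[str] = []
    for r in reads:
        seqs.append(str(r.seq) if hasattr(r, "seq") else str(r))
    if not seqs:
        raise ValueError("no reads supplied")
    refs = definition.references
    ref_items = sorted((cid, refs[cid].sequence) for cid in refs)
    max_len = 2 * max(len(s) for _, s in ref_items)
    aligner = _make_error_aligner()

    total_mism = 0
    total_bases = 0
    n_used = 0
    n_rejected = 0
    for seq in seqs:
        seq = seq.upper()
        if len(seq) > max_len:
            n_rejected += 1
            continue
        best_cid, best_dist = None, None
        for cid, ref in ref_items:
            d = edlib.align(seq, ref, mode="HW", task="distance")["editDistance"]
            if best_dist is None or d < best_dist:
                best_cid, best_dist = cid, d
        if best_dist == 0:
            total_bases += len(seq)
            n_used += 1
            continue
        aln = aligner.align(refs[best_cid].sequence, seq)[0]
        total_mism += _count_mismatches(str(aln[0]), str(aln[1]))
        total_bases += len(seq)
        n_used += 1
    if n_rejected:
        warnings.warn(
            f"{n_rejected} read(s) longer than 2x the longest reference were "
            "excluded (likely chimeras or artifacts)"
        )
    if total_bases == 0:
        raise ValueError("no usable reads (all rejected)")
    return ErrorRateResult(
        error_rate_percent=100.0 * total_mism / total_bases,
        total_mismatches=total_mism,
        total_query_bases=total_bases,
        n_reads=n_used,
        n_rejected=n_rejected,
    )
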