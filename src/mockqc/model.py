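"""Run-level QC model: one sequencing run's mock observations vs expectation.

:class:`MockRunQC` is built from the data for one run (feature table, mock
community definition, optionally representative sequences, reads and a
multi-run baseline); :meth:`MockRunQC.fit` computes everything — per-
replicate clone profiles and regressions, the run R^2 (median over
replicates), fold-deviation flags against the baseline, blank checks and
the read error rate — and returns a :class:`MockRunQCResults` carrying the
estimates, diagnostics, verdict and a ``summary()`` table.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .baseline import BaselineStore
from .matching import (
    BlankResult,
    CloneMap,
    CloneProfile,
    FeatureTable,
    blank_check,
    collapse_profile,
    match_features,
)
from .mock import ExpectedProfile, MockCommunityDef, build_expected_profile
from .stats import (
    DEFAULT_PSEUDOCOUNT,
    DeviationFlags,
    ErrorRateResult,
    RegressionResult,
    estimate_error_rate,
    fold_deviations,
    log_shift,
    r2_qc,
)

__all__ = ["MockRunQC", "MockRunQCResults", "RunVerdict", "evaluate_run",
           "update_baseline", "write_report"]

#: default flag line for the run R^2 — a starting point, not a law of
#: nature: the attainable R^2 varies with lab protocol, so it is exposed
#: as a parameter of fit()
DEFAULT_R2_THRESHOLD = 0.85


@dataclass(frozen=True)
class RunVerdict:
    """Pass/flagged verdict for one run with the reasons that fired."""

    run_id: str
    status: str  # "pass" | "flagged"
    reasons: tuple[str, ...]
    r2: float | None
    thresholds: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if (self.status == "flagged") != bool(self.reasons):
            raise ValueError("status must be 'flagged' iff reasons are non-empty")


class MockRunQC:
    """QC model for one sequencing run containing mock-community samples.

    Parameters
    ----------
    table
        Feature table spanning at least the run under evaluation.
    definition
        The mock community sequenced in the run.
    run_id
        Which run to evaluate (must have >= 1 mock sample).
    rep_seqs
        feature_id -> representative sequence; used to attribute features
        to clones at ``identity_threshold``.  May be omitted when
        ``clone_map`` is given, or when feature_ids are clone_ids already
        (e.g. simulated tables), in which case features map directly.
    baseline
        Optional multi-run :class:`~mockqc.baseline.BaselineStore`; fold
        flags need at least one *other* run in it.
    reads
        Optional mock reads for the run (sequences or SeqRecords) for
        error-rate estimation.
    """

    def __init__(
        self,
        table: FeatureTable,
        definition: MockCommunityDef,
        run_id: str,
        rep_seqs: Mapping[str, str] | None = None,
        clone_map: CloneMap | None = None,
        baseline: BaselineStore | None = None,
        reads: Iterable | None = None,
        identity_threshold: float = 0.99,
    ) -> None:
        self.table = table
        self.definition = definition
        self.run_id = run_id
        self.baseline = baseline
        self.reads = list(reads) if reads is not None else None
        self.expected: ExpectedProfile = build_expected_profile(definition)

        mocks = table.samples(run_id=run_id, role="mock")
        if not mocks:
            raise ValueError(
                f"run {run_id!r} has no mock samples; a mock community is "
                "required in every sequencing run to evaluate it"
            )
        self.mock_samples = mocks

        if clone_map is not None:
            self.clone_map = clone_map
        elif rep_seqs is not None:
            self.clone_map = match_features(
                rep_seqs, definition, identity_threshold=identity_threshold
            )
        else:
            clone_ids = set(definition.clone_ids)
            run_features = [
                f
                for f in table.feature_ids
                if table.counts.loc[f, mocks].sum() > 0
            ]
            unknown = [f for f in run_features if f not in clone_ids]
            if unknown:
                raise ValueError(
                    "no representative sequences or clone map given and "
                    f"feature_id(s) {unknown[:5]} are not clone_ids"
                )
            self.clone_map = CloneMap(
                assignments={f: f for f in run_features},
                identities={f: 1.0 for f in run_features},
            )

    def fit(
        self,
        r2_threshold: float = DEFAULT_R2_THRESHOLD,
        ten_fold: float = 10.0,
        two_fold: float = 2.0,
        min_multiple: int = 2,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        blank_max_fraction: float = 0.01,
        mode: str = "assigned",
    ) -> "MockRunQCResults":
        """Run the full QC evaluation and return the results object."""
        profiles: dict[str, CloneProfile] = {}
        regressions: dict[str, RegressionResult | None] = {}
        for sid in self.mock_samples:
            prof = collapse_profile(
                self.table, self.clone_map, sid, definition=self.definition, mode=mode
            )
            profiles[sid] = prof
            try:
                regressions[sid] = r2_qc(prof, self.expected, pseudocount=pseudocount)
            except ValueError:
                # even design: no variation on the expected axis
                regressions[sid] = None

        r2s = [r.r2 for r in regressions.values() if r is not None]
        r2 = float(statistics.median(r2s)) if r2s else None

        clone_run_means = {
            cid: float(np.mean([profiles[s].abundances[cid] for s in self.mock_samples]))
            for cid in self.definition.clone_ids
        }

        deviations: DeviationFlags | None = None
        baseline_n = 0
        if self.baseline is not None:
            baseline_n = self.baseline.n_runs(exclude_run=self.run_id)
            if baseline_n >= 1:
                deviations = fold_deviations(
                    clone_run_means,
                    self.baseline.baseline_means(exclude_run=self.run_id),
                    ten_fold=ten_fold,
                    two_fold=two_fold,
                    min_multiple=min_multiple,
                    pseudocount=pseudocount,
                )

        blanks = blank_check(self.table, self.run_id, max_fraction=blank_max_fraction)

        error_rate: ErrorRateResult | None = None
        if self.reads:
            error_rate = estimate_error_rate(self.reads, self.definition)

        reasons: list[str] = []
        if r2 is not None and r2 < r2_threshold:
            reasons.append("r2_below_threshold")
        if deviations is not None:
            for flag in ("single_10fold", "multi_2fold"):
                if flag in deviations.flags:
                    reasons.append(flag)
        if any(not b.passed for b in blanks.values()):
            reasons.append("blank_failure")

        thresholds = {
            "r2_threshold": r2_threshold,
            "ten_fold": ten_fold,
            "two_fold": two_fold,
            "min_multiple": min_multiple,
            "pseudocount": pseudocount,
            "blank_max_fraction": blank_max_fraction,
        }
        verdict = RunVerdict(
            run_id=self.run_id,
            status="flagged" if reasons else "pass",
            reasons=tuple(reasons),
            r2=r2,
            thresholds=thresholds,
        )
        return MockRunQCResults(
            model=self,
            run_id=self.run_id,
            community_id=self.definition.community_id,
            profiles=profiles,
            regressions=regressions,
            r2=r2,
            clone_run_means=clone_run_means,
            deviations=deviations,
            baseline_n=baseline_n,
            blanks=blanks,
            error_rate=error_rate,
            verdict=verdict,
            pseudocount=pseudocount,
        )


@dataclass
class MockRunQCResults:
    """Fitted QC results for one run.

    Attributes mirror the quantities a lab would log per run: per-replicate
    clone profiles and observed-vs-expected regressions, the run R^2
    (median over replicates), per-clone fold deviations from the baseline,
    blank checks, the read error rate, and the verdict.
    """

    model: MockRunQC
    run_id: str
    community_id: str
    profiles: dict[str, CloneProfile]
    regressions: dict[str, RegressionResult | None]
    r2: float | None
    clone_run_means: dict[str, float]
    deviations: DeviationFlags | None
    baseline_n: int
    blanks: dict[str, BlankResult]
    error_rate: ErrorRateResult | None
    verdict: RunVerdict
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def status(self) -> str:
        return self.verdict.status

    def to_frame(self) -> pd.DataFrame:
        """Per-clone report table (percent scale) with folds and flags."""
        expected = self.model.expected.abundances
        baseline_means = None
        if self.baseline_available:
            baseline_means = self.model.baseline.baseline_means(exclude_run=self.run_id)
        rows = []
        for cid in self.model.definition.clone_ids:
            row: dict = {
                "clone_id": cid,
                "expected_pct": 100.0 * expected[cid],
            }
            for sid in self.model.mock_samples:
                row[f"observed_pct[{sid}]"] = 100.0 * self.profiles[sid].abundances[cid]
            row["observed_pct_mean"] = 100.0 * self.clone_run_means[cid]
            if baseline_means is not None:
                row["baseline_pct"] = 100.0 * baseline_means.get(cid, float("nan"))
            if self.deviations is not None:
                fold, direction = self.deviations.folds[cid]
                row["fold_change"] = fold
                row["direction"] = direction
                row["flag"] = (
                    "10fold"
                    if cid in self.deviations.offenders.get("single_10fold", [])
                    else "2fold"
                    if cid in self.deviations.offenders.get("multi_2fold", [])
                    else ""
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("clone_id")

    @property
    def baseline_available(self) -> bool:
        return self.model.baseline is not None and self.baseline_n >= 1

    def regression_points(self) -> pd.DataFrame:
        """(log10 expected, log10 observed) pairs per replicate and clone."""
        expected = self.model.expected.abundances
        rows = []
        for sid in self.model.mock_samples:
            for cid in self.model.definition.clone_ids:
                rows.append(
                    {
                        "sample_id": sid,
                        "clone_id": cid,
                        "log_expected": log_shift(expected[cid], self.pseudocount),
                        "log_observed": log_shift(
                            self.profiles[sid].abundances[cid], self.pseudocount
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable QC summary in the spirit of a model-fit report."""
        lines = [
            "Mock-community run QC".center(64),
            "=" * 64,
            f"run_id:        {self.run_id}",
            f"community:     {self.community_id} "
            f"({self.model.definition.kind}, {len(self.model.definition)} clones)",
            f"replicates:    {len(self.model.mock_samples)}",
        ]
        if self.r2 is not None:
            lines.append(
                f"R^2 (median):  {self.r2:.4f}   "
                f"(flag line {self.verdict.thresholds['r2_threshold']:.2f})"
            )
            per_rep = ", ".join(
                f"{sid}: {reg.r2:.4f}"
                for sid, reg in self.regressions.items()
                if reg is not None
            )
            lines.append(f"  per replicate: {per_rep}")
        else:
            lines.append("R^2:           n/a (even design has no expected variation)")
        if self.error_rate is not None:
            lines.append(
                f"error rate:    {self.error_rate.error_rate_percent:.4f}% "
                f"({self.error_rate.total_mismatches} mismatches / "
                f"{self.error_rate.total_query_bases} bases)"
            )
        if self.deviations is not None:
            lines.append(f"baseline runs: {self.baseline_n}")
            worst = sorted(
                self.deviations.folds.items(), key=lambda kv: -kv[1][0]
            )[:5]
            lines.append(
                "  largest folds: "
                + ", ".join(f"{c} {f:.1f}x {d}" for c, (f, d) in worst)
            )
        for b in self.blanks.values():
            lines.append(
                f"blank {b.sample_id}: {b.total_counts} reads "
                f"({'ok' if b.passed else 'FAIL'}; limit {b.max_allowed:.0f})"
            )
        lines.append("-" * 64)
        lines.append(f"status:        {self.status.upper()}")
        if self.verdict.reasons:
            lines.append(f"reasons:       {', '.join(self.verdict.reasons)}")
        return "\n".join(lines)

    def plot_regression(self, ax=None):
        """Scatter of log-shifted observed vs expected abundances."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        pts = self.regression_points()
        for sid, grp in pts.groupby("sample_id"):
            ax.scatter(grp["log_expected"], grp["log_observed"], label=sid, alpha=0.7)
        lo = min(pts["log_expected"].min(), pts["log_observed"].min()) - 0.2
        hi = max(pts["log_expected"].max(), pts["log_observed"].max()) + 0.2
        ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="identity")
        ax.set_xlabel("log10(expected + pc)")
        ax.set_ylabel("log10(observed + pc)")
        title = f"{self.run_id}: R^2"
        if self.r2 is not None:
            title += f" = {self.r2:.3f}"
        ax.set_title(title)
        ax.legend(fontsize=7)
        return ax

    def write_report(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the per-clone TSV, the JSON verdict and the scatter data."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "clone_table": out / "clone_report.tsv",
            "verdict": out / "runqc.json",
            "scatter": out / "regression_points.tsv",
        }
        self.to_frame().to_csv(paths["clone_table"], sep="\t")
        self.regression_points().to_csv(paths["scatter"], sep="\t", index=False)
        payload = {
            "run_id": self.run_id,
            "community_id": self.community_id,
            "status": self.status,
            "reasons": list(self.verdict.reasons),
            "r2": self.r2,
            "r2_per_replicate": {
                s: (None if r is None else r.r2) for s, r in self.regressions.items()
            },
            "clone_run_means": self.clone_run_means,
            "error_rate_percent": (
                None if self.error_rate is None else self.error_rate.error_rate_percent
            ),
            "baseline_runs_used": self.baseline_n,
            "blanks": {
                s: {"total_counts": b.total_counts, "passed": b.passed}
                for s, b in self.blanks.items()
            },
            "thresholds": self.verdict.thresholds,
        }
        with open(paths["verdict"], "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def evaluate_run(
    table: FeatureTable,
    definition: MockCommunityDef,
    baseline: BaselineStore | None,
    run_id: str,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    **kwargs,
) -> tuple[RunVerdict, MockRunQCResults]:
    """Convenience wrapper: build :class:`MockRunQC`, fit, return verdict+results.

    ``kwargs`` are split between the model constructor (``rep_seqs``,
    ``clone_map``, ``reads``, ``identity_threshold``) and ``fit``.
    """
    ctor_keys = {"rep_seqs", "clone_map", "reads", "identity_threshold"}
    ctor = {k: v for k, v in kwargs.items() if k in ctor_keys}
    fit_kw = {k: v for k, v in kwargs.items() if k not in ctor_keys}
    model = MockRunQC(table, definition, run_id, baseline=baseline, **ctor)
    results = model.fit(r2_threshold=r2_threshold, **fit_kw)
    return results.verdict, results


def update_baseline(
    baseline: BaselineStore, results: MockRunQCResults, force: bool = False
) -> BaselineStore:
    """Append an evaluated run to the baseline store.

    Flagged runs are never appended automatically — pass ``force=True`` to
    override after review.  Duplicate run_ids are refused.
    """
    if results.status == "flagged" and not force:
        raise ValueError(
            f"run {results.run_id!r} is flagged ({', '.join(results.verdict.reasons)}); "
            "not appending to baseline (use force=True to override)"
        )
    platform = None
    meta = results.model.table.metadata
    mocks = results.model.mock_samples
    if mocks:
        platform = str(meta.at[mocks[0], "platform"])
    baseline.add_run(
        results.run_id,
        results.clone_run_means,
        r2=results.r2,
        error_rate_percent=(
            None if results.error_rate is None else results.error_rate.error_rate_percent
        ),
        platform=platform,
    )
    return baseline


def write_report(results: MockRunQCResults, out_dir: str | Path) -> dict[str, Path]:
    """Module-level alias for :meth:`MockRunQCResults.write_report`."""
    return results.write_report(out_dir)
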