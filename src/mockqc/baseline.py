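"""The lab's running multi-run baseline of mock-community behaviour.

A lab accumulates, run after run, the per-clone mean observed abundances
of its mock community plus each run's R^2 and error rate.  A new run is
then judged against the average over the *other* runs — the run under
evaluation never contributes to its own baseline.  Persistence is a plain
JSON file; histories are append-only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = ["BaselineStore"]


@dataclass
class BaselineStore:
    """Per-run mock summaries for one mock community across runs."""

    community_id: str
    runs: dict[str, dict] = field(default_factory=dict)

    def add_run(
        self,
        run_id: str,
        clone_means: Mapping[str, float],
        r2: float | None = None,
        error_rate_percent: float | None = None,
        platform: str | None = None,
    ) -> None:
        """Append one run's per-clone mean abundances and summary stats."""
        if run_id in self.runs:
            raise ValueError(f"run {run_id!r} already in baseline (append-only store)")
        self.runs[run_id] = {
            "clone_means": dict(clone_means),
            "r2": r2,
            "error_rate_percent": error_rate_percent,
            "platform": platform,
        }

    def n_runs(self, exclude_run: str | None = None) -> int:
        return sum(1 for r in self.runs if r != exclude_run)

    def baseline_means(self, exclude_run: str | None = None) -> dict[str, float]:
        """Unweighted per-clone mean over runs, excluding the run under test."""
        # sorted run order + fsum so the mean is insertion-order independent
        contributing = sorted(r for r in self.runs if r != exclude_run)
        if not contributing:
            raise ValueError("baseline has no contributing runs")
        clones: set[str] = set()
        for r in contributing:
            clones.update(self.runs[r]["clone_means"])
        return {
            cid: math.fsum(
                self.runs[r]["clone_means"].get(cid, 0.0) for r in contributing
            )
            / len(contributing)
            for cid in sorted(clones)
        }

    def r2_history(self) -> dict[str, float | None]:
        return {r: self.runs[r]["r2"] for r in self.runs}

    def error_rate_history(self) -> dict[str, float | None]:
        return {r: self.runs[r]["error_rate_percent"] for r in self.runs}

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"community_id": self.community_id, "runs": self.runs},
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "BaselineStore":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(community_id=payload["community_id"], runs=payload["runs"])
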