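"""Data-driven calibration of the three inference parameters.

There is no ground truth for which joint visits are genuine
leading-following events, so parameters are selected by comparing the
distributions of L/F *time differences* across a parameter grid.  The
logic: if delaying the occupation cutoff from hour d1 to a later hour d2
leaves the time-difference distribution unchanged, the extra events picked
up between d1 and d2 are of the same nature as the earlier ones (no
swarming contamination yet) and the later cutoff is preferable because it
increases the sample size.  Swarming at an occupied roost, by contrast,
produces joint reads with systematically larger gaps, so a cutoff that is
too late shifts the distribution's upper tail — detected by a one-sided
rank-sum test.

Each pairwise comparison is a bootstrapped Wilcoxon rank-sum
(Mann-Whitney) test: both samples are resampled with replacement at their
original sizes, the asymptotic tie-corrected p-value is computed per
replicate, and the replicate p-values are averaged.  The plain
(unbootstrapped) p-values are reported alongside for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import InferenceParams, infer_events, time_differences
from .io import BoxMetadata, RecordingSet

__all__ = [
    "ParamGrid",
    "PairwiseTest",
    "CalibrationReport",
    "rank_sum_bootstrap",
    "calibration_table",
    "select_params",
]


@dataclass(frozen=True)
class ParamGrid:
    """Grid of candidate parameter values.

    Defaults mirror a typical calibration sweep: lf_delay in {3, 5} min,
    turnaround in {2, 3, 5, 7, 9} min, morning deadline in {2, 3, 5, 8}.
    """

    lf_delays: tuple[float, ...] = (3.0, 5.0)
    turnarounds: tuple[float, ...] = (2.0, 3.0, 5.0, 7.0, 9.0)
    deadlines: tuple[float, ...] = (2.0, 3.0, 5.0, 8.0)

    def __post_init__(self) -> None:
        if not (self.lf_delays and self.turnarounds and self.deadlines):
            raise ValueError("grid axes must be nonempty")
        for d in self.lf_delays:
            if d <= 0:
                raise ValueError("lf_delay values must be positive")
        for t in self.turnarounds:
            if t < 0:
                raise ValueError("turnaround values must be nonnegative")
        for h in self.deadlines:
            if not (0 <= h < 24):
                raise ValueError("deadline hours must be in [0, 24)")


@dataclass(frozen=True)
class PairwiseTest:
    """Bootstrapped rank-sum comparison of two deadline cells.

    ``p_two_sided`` tests distributional difference; ``p_one_sided`` tests
    whether the earlier-deadline sample is stochastically smaller than the
    later one (the signature of swarming entering at the later deadline).
    """

    lf_delay: float
    turnaround: float
    deadline_lo: float
    deadline_hi: float
    p_two_sided: float
    p_one_sided: float
    plain_p_two_sided: float
    plain_p_one_sided: float
    n_lo: int
    n_hi: int
    n_boot: int
    seed: int


class EmptyCellError(ValueError):
    """A deadline cell produced no events, so it cannot be compared."""


@dataclass
class CalibrationReport:
    grid: ParamGrid
    alpha_sig: float
    #: event counts keyed by (deadline, lf_delay, turnaround)
    counts: dict[tuple[float, float, float], int]
    tests: list[PairwiseTest]
    selected: InferenceParams | None = None
    selection_warning: bool = False

    def counts_frame(self) -> pd.DataFrame:
        """Event-count grid: rows = deadline, columns = (lf_delay, turnaround)."""
        rows = [
            {"deadline": d, "lf_delay": l, "turnaround": t, "n_events": n}
            for (d, l, t), n in sorted(self.counts.items())
        ]
        df = pd.DataFrame(rows)
        return df.pivot(index="deadline", columns=["lf_delay", "turnaround"], values="n_events")

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.tests])

    def to_dict(self) -> dict:
        """JSON-serializable view of the full report."""
        return {
            "alpha_sig": self.alpha_sig,
            "grid": {
                "lf_delays": list(self.grid.lf_delays),
                "turnarounds": list(self.grid.turnarounds),
                "deadlines": list(self.grid.deadlines),
            },
            "counts": [
                {"deadline": d, "lf_delay": l, "turnaround": t, "n_events": n}
                for (d, l, t), n in sorted(self.counts.items())
            ],
            "tests": [t.__dict__ for t in self.tests],
            "selected": None
            if self.selected is None
            else {
                "lf_delay": self.selected.lf_delay,
                "turnaround_time": self.selected.turnaround_time,
                "occupation_deadline": self.selected.occupation_deadline,
            },
            "selection_warning": self.selection_warning,
        }


def rank_sum_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrapped Wilcoxon rank-sum p-values for two samples of minutes.

    Each of ``n_boot`` replicates resamples ``x`` and ``y`` with
    replacement at their original sizes and computes the Mann-Whitney
    p-value (normal approximation with tie correction).  Returns the means
    of the replicate p-values: ``(p_two_sided, p_one_sided)`` where the
    one-sided alternative is that ``x`` is stochastically smaller than
    ``y``.  Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyCellError("both samples must be nonempty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    xs = rng.choice(x, size=(n_boot, x.size), replace=True)
    ys = rng.choice(y, size=(n_boot, y.size), replace=True)
    p2 = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic", axis=1).pvalue
    p1 = stats.mannwhitneyu(xs, ys, alternative="less", method="asymptotic", axis=1).pvalue
    return float(np.mean(p2)), float(np.mean(p1))


def plain_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Unbootstrapped Mann-Whitney p-values, same conventions as above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyCellError("both samples must be nonempty")
    p2 = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    p1 = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
    return float(p2), float(p1)


def _sub_seed(seed: int, index: int) -> int:
    return (seed * 100003 + index) % (2**31)


def calibration_table(
    rs: RecordingSet,
    boxes: Iterable[BoxMetadata],
    grid: ParamGrid | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha_sig: float = 0.05,
) -> CalibrationReport:
    """Run the full calibration sweep over a parameter grid.

    For every (lf_delay, turnaround) cell, events are inferred at each
    deadline and all deadline pairs (d1 < d2) are compared with
    :func:`rank_sum_bootstrap`.  Event counts are tabulated for every
    (deadline, lf_delay, turnaround) combination, and the selected
    parameters are filled in via :func:`select_params`.  Deadline cells
    with no events are skipped in pairwise testing (they carry no
    distributional information) but still appear in the count grid.
    """
    grid = grid or ParamGrid()
    boxes = list(boxes)
    counts: dict[tuple[float, float, float], int] = {}
    diffs: dict[tuple[float, float, float], np.ndarray] = {}
    for lf in grid.lf_delays:
        for tr in grid.turnarounds:
            for d in grid.deadlines:
                params = InferenceParams(
                    lf_delay=lf, turnaround_time=tr, occupation_deadline=d
                )
                events = infer_events(rs, params, boxes)
                counts[(d, lf, tr)] = len(events)
                diffs[(d, lf, tr)] = time_differences(events)

    tests: list[PairwiseTest] = []
    idx = 0
    deadlines = sorted(grid.deadlines)
    for lf in grid.lf_delays:
        for tr in grid.turnarounds:
            for i, d1 in enumerate(deadlines):
                for d2 in deadlines[i + 1 :]:
                    x, y = diffs[(d1, lf, tr)], diffs[(d2, lf, tr)]
                    sub = _sub_seed(seed, idx)
                    idx += 1
                    if x.size == 0 or y.size == 0:
                        continue
                    p2, p1 = rank_sum_bootstrap(x, y, n_boot=n_boot, seed=sub)
                    q2, q1 = plain_rank_sum(x, y)
                    tests.append(
                        PairwiseTest(
                            lf_delay=lf,
                            turnaround=tr,
                            deadline_lo=d1,
                            deadline_hi=d2,
                            p_two_sided=p2,
                            p_one_sided=p1,
                            plain_p_two_sided=q2,
                            plain_p_one_sided=q1,
                            n_lo=int(x.size),
                            n_hi=int(y.size),
                            n_boot=n_boot,
                            seed=sub,
                        )
                    )
    report = CalibrationReport(grid=grid, alpha_sig=alpha_sig, counts=counts, tests=tests)
    report.selected = select_params(report, alpha_sig)
    return report


def select_params(report: CalibrationReport, alpha_sig: float | None = None) -> InferenceParams:
    """Pick the parameter tuple maximizing events without distorting gaps.

    For each (lf_delay, turnaround) cell the admissible deadline is the
    latest one whose time-difference distribution is not significantly
    different (two-sided, at ``alpha_sig``) from *all* earlier deadlines;
    the earliest deadline is vacuously admissible.  Among the per-cell
    candidates, the tuple with the largest event count wins; ties go to
    the smaller lf_delay, then the smaller turnaround.  If every pairwise
    test in the report is significant, the earliest deadline is returned
    and ``report.selection_warning`` is set.
    """
    alpha = report.alpha_sig if alpha_sig is None else alpha_sig
    grid = report.grid
    deadlines = sorted(grid.deadlines)
    sig = {
        (t.lf_delay, t.turnaround, t.deadline_lo, t.deadline_hi): t.p_two_sided < alpha
        for t in report.tests
    }
    candidates: list[tuple[int, float, float, float]] = []  # (count, lf, tr, d)
    for lf in grid.lf_delays:
        for tr in grid.turnarounds:
            admissible = [
                d
                for i, d in enumerate(deadlines)
                if not any(
                    sig.get((lf, tr, d_lo, d), False) for d_lo in deadlines[:i]
                )
            ]
            best_d = max(admissible)  # earliest is always admissible
            candidates.append((report.counts[(best_d, lf, tr)], lf, tr, best_d))
    # max count; ties -> smaller lf_delay, then smaller turnaround
    count, lf, tr, d = max(candidates, key=lambda c: (c[0], -c[1], -c[2]))
    if report.tests and all(t.p_two_sided < alpha for t in report.tests):
        report.selection_warning = True
    return InferenceParams(lf_delay=lf, turnaround_time=tr, occupation_deadline=d)
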