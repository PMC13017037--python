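"""Derived trait scores for a multi-assay fish cohort.

Each assay produces raw durations, counts, or morphometric measurements;
this module turns them into the per-subject trait indices used throughout
the analysis:

* growth: percent change in body length between the two timepoints;
* basal metabolism: resting opercular ventilation rate normalized by body
  weight (bpm/g);
* stress metabolism: percent elevation of ventilation on entry into a novel
  environment over the basal rate;
* activity, thigmotaxis, scototaxis, sociability: open-field distance and
  zone-occupancy percentages;
* motor and visual lateralization: relative (signed) and absolute indices
  from clockwise/counterclockwise swimming times;
* spatial learning, cognitive flexibility, memory: days to a learning
  criterion in the T-maze and the derived phase-contrast indices.

The learning criterion is 10 correct choices out of 12 trials over any two
consecutive days (overlapping windows), so the minimum achievable value is
2 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "NETWORK_TRAITS_12",
    "MazePhaseResult",
    "percent_change",
    "zone_percentage",
    "lateralization_indices",
    "basal_per_gram",
    "days_to_criterion",
    "phase_index",
    "chance_level",
    "build_trait_table",
]

#: Canonical trait-column order of the subjects x traits table.
TRAITS = [
    "growth",
    "basal_metabolism",
    "stress_metabolism",
    "activity",
    "thigmotaxis",
    "scototaxis",
    "sociability",
    "motor_lat_rel",
    "motor_lat_abs",
    "visual_lat_rel",
    "visual_lat_abs",
    "spatial_learning",
    "flexibility",
    "memory",
]

#: Default network node set: the 12 traits entering the covariance network
#: (the signed relative lateralization indices are kept in the table but not
#: in the default network).
NETWORK_TRAITS_12 = [t for t in TRAITS if not t.endswith("_rel")]

MAZE_PHASES = ("learning", "reversal", "memory")


def percent_change(value: float, baseline: float) -> float:
    """Percent change of ``value`` relative to ``baseline``.

    Used for the growth index (final vs initial body length) and for stress
    metabolism (ventilation under stress vs basal ventilation).
    """
    if not baseline > 0:
        raise ValueError(f"baseline must be positive, got {baseline!r}")
    return (value - baseline) / baseline * 100.0


def zone_percentage(time_in: float, denominator: float) -> float:
    """Percentage of ``denominator`` seconds spent in a zone.

    Thigmotaxis passes (time in outer band, total time); scototaxis passes
    (time in dark half, total time); sociability passes
    (time near mirror, total time - time in the central sector).

    A non-positive denominator makes the score undefined: returns NaN with a
    warning so the cell propagates as missing.
    """
    if denominator <= 0:
        warnings.warn(
            f"zone_percentage undefined for denominator {denominator!r}; "
            "scoring as missing",
            stacklevel=2,
        )
        return float("nan")
    if time_in < 0 or time_in > denominator:
        raise ValueError(
            f"time_in must lie in [0, denominator], got {time_in!r} of {denominator!r}"
        )
    return time_in / denominator * 100.0


def lateralization_indices(time_cw: float, time_ccw: float) -> tuple[float, float]:
    """Relative and absolute lateralization indices from rotation times.

    relative = (cw - ccw) / (cw + ccw) * 100, in [-100, 100]; positive means
    a clockwise bias. absolute = |relative|, the strength of lateralization
    regardless of direction. Both times zero (the subject never swam along
    the edge) leaves the indices undefined -> (nan, nan) with a warning.
    """
    if time_cw < 0 or time_ccw < 0:
        raise ValueError("rotation times must be non-negative")
    total = time_cw + time_ccw
    if total == 0:
        warnings.warn(
            "lateralization undefined for zero edge-swimming time; scoring as missing",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    rel = (time_cw - time_ccw) / total * 100.0
    return rel, abs(rel)


def basal_per_gram(basal_bpm: float, weight_g: float) -> float:
    """Basal ventilation rate normalized by body weight (bpm/g)."""
    if not weight_g > 0:
        raise ValueError(f"weight must be positive, got {weight_g!r}")
    return basal_bpm / weight_g


def days_to_criterion(
    daily_correct: Sequence[int],
    threshold: int = 10,
    window_days: int = 2,
    trials_per_day: int = 6,
) -> Optional[int]:
    """First day (1-based) on which the learning criterion is met.

    The criterion scans *overlapping* windows of ``window_days`` consecutive
    days and is met on the first day ``d >= window_days`` whose trailing
    window accumulates at least ``threshold`` correct choices (default: 10
    of 12 over two days). Returns None if the criterion is never reached.

    Appending days after the criterion day cannot change the result.
    """
    counts = np.asarray(list(daily_correct), dtype=float)
    if counts.size and (np.nanmin(counts) < 0 or np.nanmax(counts) > trials_per_day):
        raise ValueError(
            f"daily correct counts must lie in [0, {trials_per_day}]"
        )
    if counts.size < window_days:
        return None
    window_sums = np.convolve(counts, np.ones(window_days), mode="valid")
    hits = np.nonzero(window_sums >= threshold)[0]
    if hits.size == 0:
        return None
    return int(hits[0]) + window_days


def phase_index(days_after: int, days_before: int) -> float:
    """Contrast index between two criterion-based maze phases.

    -(days_after - days_before) / days_before. Higher values mean the later
    phase was solved in fewer days relative to the earlier one: flexibility
    contrasts reversal vs initial learning, memory contrasts the memory
    phase vs reversal.
    """
    if days_before < 1:
        raise ValueError(f"days_before must be >= 1, got {days_before!r}")
    return -(days_after - days_before) / days_before


def chance_level(kind: str, side_cm: float = 40.0, band_cm: float = 4.5) -> float:
    """Chance-expectation percentage for a zone-occupancy score.

    For the square open-field arena the chance thigmotaxis level is the area
    of the outer band as a fraction of the arena: (L^2 - (L-2w)^2)/L^2 * 100
    (39.94% for the 40 cm arena with a 4.5 cm band, i.e. ~40%). Half-split
    apparatuses (scototaxis, sociability) have a chance level of 50%, and
    the relative lateralization index has a chance expectation of 0.
    """
    kind = kind.lower()
    if kind in ("open_field", "thigmotaxis", "square"):
        if side_cm <= 0 or band_cm < 0 or band_cm > side_cm / 2:
            raise ValueError(
                f"invalid geometry: side {side_cm!r} cm, band {band_cm!r} cm"
            )
        inner = (side_cm - 2 * band_cm) ** 2
        return (side_cm**2 - inner) / side_cm**2 * 100.0
    if kind in ("scototaxis", "sociability", "half"):
        return 50.0
    if kind == "lateralization":
        return 0.0
    raise ValueError(f"unknown chance-level kind {kind!r}")


@dataclass
class MazePhaseResult:
    """Criterion summary of one maze phase for one subject."""

    phase: str
    daily_correct_counts: list[int] = field(default_factory=list)
    days_to_criterion: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phase not in MAZE_PHASES:
            raise ValueError(f"unknown maze phase {self.phase!r}")


def score_maze_phase(
    phase: str,
    daily_choices: Sequence[Sequence[int]],
    threshold: int = 10,
    window_days: int = 2,
    trials_per_day: int = 6,
) -> MazePhaseResult:
    """Collapse per-trial binary choices into daily counts and criterion day."""
    counts = []
    for day in daily_choices:
        day = list(day)
        if len(day) != trials_per_day:
            raise ValueError(
                f"each day must hold exactly {trials_per_day} trials, got {len(day)}"
            )
        if any(c not in (0, 1) for c in day):
            raise ValueError("maze choices must be 0/1")
        counts.append(int(sum(day)))
    return MazePhaseResult(
        phase=phase,
        daily_correct_counts=counts,
        days_to_criterion=days_to_criterion(
            counts, threshold=threshold, window_days=window_days,
            trials_per_day=trials_per_day,
        ),
    )


def _mean_or_first(values: Sequence[float], first_trial_only: bool) -> float:
    vals = [v for v in values if not (isinstance(v, float) and np.isnan(v))]
    if not vals:
        return float("nan")
    if first_trial_only:
        return float(values[0])
    return float(np.nanmean(np.asarray(values, dtype=float)))


def build_trait_table(
    cohort,
    lateralization_trials: str = "mean",
    stress: str = "index",
    flexibility: str = "index",
    threshold: int = 10,
    window_days: int = 2,
) -> pd.DataFrame:
    """Assemble the subjects x 14 traits table from raw cohort records.

    Behavioral and lateralization scores are the mean of the two trials;
    ``lateralization_trials="first"`` switches the lateralization columns to
    the first trial only (the control-network setting). ``stress="raw"``
    keeps the raw stress-condition ventilation rate (bpm) instead of the
    percent-increase index, and ``flexibility="raw_days"`` keeps the raw
    days-to-criterion of the reversal phase instead of the flexibility
    index — together these reproduce the raw-variable control analysis.

    Missing assay blocks (no rows for a subject) propagate to missing cells;
    a missing learning (reversal) phase also leaves flexibility (flexibility
    and memory) undefined because the indices contrast consecutive phases.
    """
    if lateralization_trials not in ("mean", "first"):
        raise ValueError("lateralization_trials must be 'mean' or 'first'")
    if stress not in ("index", "raw"):
        raise ValueError("stress must be 'index' or 'raw'")
    if flexibility not in ("index", "raw_days"):
        raise ValueError("flexibility must be 'index' or 'raw_days'")

    subjects = list(cohort.subjects)
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids in cohort")
    table = pd.DataFrame(index=pd.Index(subjects, name="subject"),
                         columns=TRAITS, dtype=float)

    morpho = cohort.morphometrics.set_index(["subject", "timepoint"])
    vent = cohort.ventilation.set_index(["subject", "condition"])

    def _get(df, key, col):
        try:
            return float(df.loc[key, col])
        except KeyError:
            return float("nan")

    for s in subjects:
        li = _get(morpho, (s, "initial"), "length_cm")
        lf = _get(morpho, (s, "final"), "length_cm")
        wi = _get(morpho, (s, "initial"), "weight_g")
        if np.isfinite(li) and np.isfinite(lf) and li > 0:
            table.at[s, "growth"] = percent_change(lf, li)
        basal = _get(vent, (s, "basal"), "bpm")
        stress_bpm = _get(vent, (s, "stress"), "bpm")
        if np.isfinite(basal) and np.isfinite(wi) and wi > 0:
            table.at[s, "basal_metabolism"] = basal_per_gram(basal, wi)
        if np.isfinite(stress_bpm):
            if stress == "raw":
                table.at[s, "stress_metabolism"] = stress_bpm
            elif np.isfinite(basal) and basal > 0:
                table.at[s, "stress_metabolism"] = percent_change(stress_bpm, basal)

    first_only = lateralization_trials == "first"

    for s, grp in cohort.open_field.groupby("subject"):
        grp = grp.sort_values("trial")
        table.at[s, "activity"] = float(np.nanmean(grp["distance_cm"]))
        scores = [
            zone_percentage(r.time_outer_s, r.time_total_s)
            for r in grp.itertuples()
        ]
        table.at[s, "thigmotaxis"] = _mean_or_first(scores, False)

    for s, grp in cohort.scototaxis.groupby("subject"):
        grp = grp.sort_values("trial")
        scores = [
            zone_percentage(r.time_dark_s, r.time_total_s) for r in grp.itertuples()
        ]
        table.at[s, "scototaxis"] = _mean_or_first(scores, False)

    for s, grp in cohort.sociability.groupby("subject"):
        grp = grp.sort_values("trial")
        scores = [
            zone_percentage(r.time_near_mirror_s, r.time_total_s - r.time_center_s)
            for r in grp.itertuples()
        ]
        table.at[s, "sociability"] = _mean_or_first(scores, False)

    for (s, test), grp in cohort.lateralization.groupby(["subject", "test"]):
        grp = grp.sort_values("trial")
        rels, absolutes = [], []
        for r in grp.itertuples():
            rel, ab = lateralization_indices(r.time_cw_s, r.time_ccw_s)
            rels.append(rel)
            absolutes.append(ab)
        table.at[s, f"{test}_lat_rel"] = _mean_or_first(rels, first_only)
        table.at[s, f"{test}_lat_abs"] = _mean_or_first(absolutes, first_only)

    days: dict[tuple[str, object], Optional[int]] = {}
    if len(cohort.maze):
        for (s, phase), grp in cohort.maze.groupby(["subject", "phase"]):
            counts = (
                grp.sort_values(["day", "trial"]).groupby("day")["correct"].sum()
            )
            days[(phase, s)] = days_to_criterion(
                counts.to_numpy(), threshold=threshold, window_days=window_days,
                trials_per_day=int(grp.groupby("day").size().iloc[0]),
            )

    for s in subjects:
        learn = days.get(("learning", s))
        rev = days.get(("reversal", s))
        mem = days.get(("memory", s))
        if learn is not None:
            table.at[s, "spatial_learning"] = learn
        if flexibility == "raw_days":
            if rev is not None:
                table.at[s, "flexibility"] = rev
        elif rev is not None and learn is not None:
            table.at[s, "flexibility"] = phase_index(rev, learn)
        if mem is not None and rev is not None:
            table.at[s, "memory"] = phase_index(mem, rev)

    return table
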