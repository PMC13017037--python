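"""Synthetic raw-cohort generator with a known latent trait covariance.

The generator emulates the raw-record schema of a wild juvenile tench
(*Tinca tinca*) cohort assayed for life-history, physiological, behavioral
and cognitive traits: morphometrics at two timepoints, opercular
ventilation in stress and basal conditions, two trials each of open-field,
scototaxis, sociability and two lateralization tests, and daily 6-trial
binary choice sequences in a T-maze across learning, reversal and memory
phases.

Each subject draws one latent vector from a multivariate normal with a
configurable correlation matrix over the 14 trait dimensions. Latent
coordinates map *monotonically* to the raw observables (logistic squashing
for zone-time fractions, affine maps clipped at zero for rates and
distances), so rank-based statistics computed downstream recover the
planted latent correlation structure. Maze performance is generated by a
per-subject logistic learning curve whose slope is driven by the subject's
latent for that phase; daily Bernoulli choices are sampled and the sequence
is truncated on the day the learning criterion is met.

Missingness mimics the real study's dropout (whole assay blocks removed for
a few subjects, never the first-timepoint morphometrics) at a configurable
expected missing-cell rate of the derived trait table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .scoring import TRAITS, days_to_criterion

__all__ = [
    "CohortConfig",
    "RawCohort",
    "generate_cohort",
    "inject_missingness",
    "DEFAULT_TRAIT_MEANS",
    "DEFAULT_TRAIT_SDS",
]

# Plausible population location/spread for each trait dimension on its
# observable scale (percent, cm, bpm/g, days, index units). These seed the
# monotone latent->observable maps; maze-day entries act as nominal targets
# for the learning-curve calibration rather than direct affine parameters.
DEFAULT_TRAIT_MEANS = {
    "growth": 5.2,
    "basal_metabolism": 84.5,
    "stress_metabolism": 102.7,
    "activity": 4053.0,
    "thigmotaxis": 78.3,
    "scototaxis": 90.7,
    "sociability": 54.9,
    "motor_lat_rel": 0.0,
    "motor_lat_abs": 26.2,
    "visual_lat_rel": 0.0,
    "visual_lat_abs": 12.7,
    "spatial_learning": 4.8,
    "flexibility": -0.4,
    "memory": 0.4,
}
DEFAULT_TRAIT_SDS = {
    "growth": 4.0,
    "basal_metabolism": 25.1,
    "stress_metabolism": 88.5,
    "activity": 2160.0,
    "thigmotaxis": 18.3,
    "scototaxis": 7.8,
    "sociability": 21.5,
    "motor_lat_rel": 33.9,
    "motor_lat_abs": 21.1,
    "visual_lat_rel": 15.6,
    "visual_lat_abs": 8.7,
    "spatial_learning": 2.1,
    "flexibility": 1.0,
    "memory": 0.3,
}

TRIAL_SECONDS = 1800.0  # 30 min behavioral/lateralization trials

# Assay blocks eligible for dropout-style removal. First-timepoint
# morphometrics are never removed. Cell counts refer to the 14-column trait
# table: removing the reversal phase wipes both the flexibility and memory
# indices because they contrast consecutive phases.
_BLOCKS = (
    "morpho_final", "ventilation", "open_field", "scototaxis", "sociability",
    "motor_lat", "visual_lat", "learning", "reversal", "memory",
)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    latent_corr is a 14 x 14 correlation matrix over the trait dimensions in
    :data:`traitnet.scoring.TRAITS` order (identity if omitted). trial_icc
    is the latent-scale correlation between the two trials of the repeated
    assays (1.0 disables trial-level noise so scored traits are strictly
    monotone in their latents).
    """

    n_subjects: int = 24
    latent_corr: Optional[np.ndarray] = None
    trait_means: Optional[dict] = None
    trait_sds: Optional[dict] = None
    trials_per_day: int = 6
    max_days: int = 20
    n_behavior_trials: int = 2
    missing_rate: float = 6 / 336
    trial_icc: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if not (0.0 <= self.trial_icc <= 1.0):
            raise ValueError("trial_icc must lie in [0, 1]")
        if self.trials_per_day < 1 or self.max_days < 1:
            raise ValueError("trials_per_day and max_days must be positive")
        p = len(TRAITS)
        if self.latent_corr is None:
            self.latent_corr = np.eye(p)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        if self.latent_corr.shape != (p, p):
            raise ValueError(
                f"latent_corr must be {p}x{p} over the trait dimensions"
            )
        if not np.allclose(self.latent_corr, self.latent_corr.T, atol=1e-10):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0, atol=1e-10):
            raise ValueError("latent_corr must have a unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.latent_corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"latent_corr is not positive semidefinite "
                f"(smallest eigenvalue {eigmin:.3e})"
            )
        means = dict(DEFAULT_TRAIT_MEANS)
        sds = dict(DEFAULT_TRAIT_SDS)
        if self.trait_means is not None:
            if not isinstance(self.trait_means, dict):
                raise ValueError("trait_means must map trait names to values")
            unknown = set(self.trait_means) - set(TRAITS)
            if unknown:
                raise ValueError(f"trait_means keys must be traits, got {unknown}")
            means.update(self.trait_means)
        if self.trait_sds is not None:
            unknown = set(self.trait_sds) - set(TRAITS)
            if unknown:
                raise ValueError(f"trait_sds keys must be traits, got {unknown}")
            sds.update(self.trait_sds)
        if len(means) != p or len(sds) != p:
            raise ValueError(f"trait means/sds must cover the {p} traits")
        self.trait_means = means
        self.trait_sds = sds


@dataclass
class RawCohort:
    """Tidy per-assay tables of raw trial records for one cohort.

    Missing assay blocks are represented by absent rows. ``maze`` holds one
    row per (subject, phase, day, trial) with the binary choice outcome;
    each phase sequence ends on the criterion day (or at the day cap).
    """

    subjects: list
    morphometrics: pd.DataFrame
    ventilation: pd.DataFrame
    open_field: pd.DataFrame
    scototaxis: pd.DataFrame
    sociability: pd.DataFrame
    lateralization: pd.DataFrame
    maze: pd.DataFrame
    config: Optional[CohortConfig] = None

    _TABLES = (
        "morphometrics", "ventilation", "open_field", "scototaxis",
        "sociability", "lateralization", "maze",
    )

    def copy(self) -> "RawCohort":
        return RawCohort(
            subjects=list(self.subjects),
            config=self.config,
            **{t: getattr(self, t).copy() for t in self._TABLES},
        )

    def equals(self, other: "RawCohort") -> bool:
        return self.subjects == other.subjects and all(
            getattr(self, t).reset_index(drop=True).equals(
                getattr(other, t).reset_index(drop=True))
            for t in self._TABLES
        )

    def to_dir(self, path) -> None:
        """Write one delimited-text table per assay plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for t in self._TABLES:
            getattr(self, t).to_csv(path / f"{t}.csv", index=False)
        manifest = {"subjects": list(map(str, self.subjects)), "tables": list(self._TABLES)}
        if self.config is not None:
            cfg = {
                k: v for k, v in self.config.__dict__.items()
                if k != "latent_corr"
            }
            cfg["latent_corr"] = np.asarray(self.config.latent_corr).tolist()
            manifest["config"] = cfg
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, path) -> "RawCohort":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        tables = {}
        for t in cls._TABLES:
            tables[t] = pd.read_csv(path / f"{t}.csv")
        config = None
        if "config" in manifest:
            cfg = dict(manifest["config"])
            cfg["latent_corr"] = np.asarray(cfg["latent_corr"], dtype=float)
            config = CohortConfig(**cfg)
        return cls(subjects=manifest["subjects"], config=config, **tables)


def _trial_latents(z: np.ndarray, icc: float, n_trials: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-trial latent draws around the subject latent (marginal N(0,1))."""
    eps = rng.standard_normal((n_trials,) + z.shape)
    return np.sqrt(icc) * z[None] + np.sqrt(1.0 - icc) * eps


def _fraction_map(z: np.ndarray, mean_pct: float, sd_pct: float) -> np.ndarray:
    """Monotone logistic squash of a latent to a (0, 1) time fraction."""
    p0 = np.clip(mean_pct / 100.0, 1e-4, 1 - 1e-4)
    scale = (sd_pct / 100.0) / (p0 * (1 - p0))  # delta-method slope matching
    return expit(logit(p0) + scale * z)


def _simulate_phase(
    rng: np.random.Generator,
    z: np.ndarray,
    intercept: float,
    base_slope: float,
    slope_sensitivity: float,
    trials_per_day: int,
    max_days: int,
    threshold: int,
) -> list[list[np.ndarray]]:
    """Daily Bernoulli choice sequences truncated at the criterion day.

    P(correct) on day d is expit(intercept + s*d) with per-subject slope
    s = base_slope * exp(-slope_sensitivity * z): higher latent -> shallower
    curve -> more days to criterion, so the scored days column is monotone
    increasing in the latent (up to sampling noise).
    """
    slopes = base_slope * np.exp(-slope_sensitivity * z)
    out = []
    for s in slopes:
        days: list[np.ndarray] = []
        counts: list[int] = []
        for d in range(1, max_days + 1):
            p = expit(intercept + s * d)
            choices = (rng.random(trials_per_day) < p).astype(int)
            days.append(choices)
            counts.append(int(choices.sum()))
            if (
                len(counts) >= 2
                and counts[-1] + counts[-2] >= threshold
            ):
                break
        out.append(days)
    return out


def generate_cohort(config: CohortConfig) -> RawCohort:
    """Draw one fully reproducible synthetic cohort from ``config``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    p = len(TRAITS)
    means, sds = config.trait_means, config.trait_sds

    # latent draw: jittered Cholesky tolerates PSD-but-singular inputs
    corr = config.latent_corr + 1e-10 * np.eye(p)
    L = np.linalg.cholesky(corr)
    Z = rng.standard_normal((n, p)) @ L.T
    lat = {t: Z[:, i] for i, t in enumerate(TRAITS)}

    subjects = [f"S{i + 1:03d}" for i in range(n)]

    # --- morphometrics -----------------------------------------------------
    length0 = np.clip(rng.normal(5.82, 0.35, n), 3.0, None)
    growth = means["growth"] + sds["growth"] * lat["growth"]
    growth = np.clip(growth, -50.0, None)
    length1 = length0 * (1 + growth / 100.0)
    # weight tracks length allometrically with mild individual noise
    cond0 = np.exp(rng.normal(0.0, 0.08, n))
    weight0 = 0.0092 * length0**3 * cond0
    weight1 = 0.0092 * length1**3 * cond0 * np.exp(rng.normal(0.03, 0.03, n))
    morpho = pd.DataFrame({
        "subject": subjects * 2,
        "timepoint": ["initial"] * n + ["final"] * n,
        "length_cm": np.round(np.concatenate([length0, length1]), 2),
        "weight_g": np.round(np.concatenate([weight0, weight1]), 3),
    })

    # --- ventilation -------------------------------------------------------
    basal_per_g = np.clip(
        means["basal_metabolism"] + sds["basal_metabolism"] * lat["basal_metabolism"],
        5.0, None,
    )
    basal_bpm = basal_per_g * weight0
    stress_pct = np.clip(
        means["stress_metabolism"] + sds["stress_metabolism"] * lat["stress_metabolism"],
        -90.0, None,
    )
    stress_bpm = basal_bpm * (1 + stress_pct / 100.0)
    vent = pd.DataFrame({
        "subject": subjects * 2,
        "condition": ["stress"] * n + ["basal"] * n,
        "bpm": np.round(np.concatenate([stress_bpm, basal_bpm]), 1),
    })

    n_tr = config.n_behavior_trials
    icc = config.trial_icc

    # --- open field: activity + thigmotaxis --------------------------------
    z_act = _trial_latents(lat["activity"], icc, n_tr, rng)
    z_thig = _trial_latents(lat["thigmotaxis"], icc, n_tr, rng)
    dist = np.clip(means["activity"] + sds["activity"] * z_act, 0.0, None)
    outer = _fraction_map(z_thig, means["thigmotaxis"], sds["thigmotaxis"])
    open_field = pd.DataFrame({
        "subject": np.tile(subjects, n_tr),
        "trial": np.repeat(np.arange(1, n_tr + 1), n),
        "distance_cm": np.round(dist.ravel(), 1),
        "time_outer_s": np.round(outer.ravel() * TRIAL_SECONDS, 1),
        "time_total_s": TRIAL_SECONDS,
    })

    # --- scototaxis --------------------------------------------------------
    z_sco = _trial_latents(lat["scototaxis"], icc, n_tr, rng)
    dark = _fraction_map(z_sco, means["scototaxis"], sds["scototaxis"])
    scoto = pd.DataFrame({
        "subject": np.tile(subjects, n_tr),
        "trial": np.repeat(np.arange(1, n_tr + 1), n),
        "time_dark_s": np.round(dark.ravel() * TRIAL_SECONDS, 1),
        "time_total_s": TRIAL_SECONDS,
    })

    # --- sociability -------------------------------------------------------
    z_soc = _trial_latents(lat["sociability"], icc, n_tr, rng)
    near_frac = _fraction_map(z_soc, means["sociability"], sds["sociability"])
    center_frac = rng.uniform(0.15, 0.35, (n_tr, n))
    lateral = TRIAL_SECONDS * (1 - center_frac)
    social = pd.DataFrame({
        "subject": np.tile(subjects, n_tr),
        "trial": np.repeat(np.arange(1, n_tr + 1), n),
        "time_near_mirror_s": np.round((near_frac * lateral).ravel(), 1),
        "time_center_s": np.round((center_frac * TRIAL_SECONDS).ravel(), 1),
        "time_total_s": TRIAL_SECONDS,
    })

    # --- lateralization (motor, visual) ------------------------------------
    lat_rows = []
    for test in ("motor", "visual"):
        z_abs = _trial_latents(lat[f"{test}_lat_abs"], icc, n_tr, rng)
        z_rel = _trial_latents(lat[f"{test}_lat_rel"], icc, n_tr, rng)
        magnitude = _fraction_map(
            z_abs, means[f"{test}_lat_abs"], sds[f"{test}_lat_abs"]
        )
        direction = np.tanh(2.5 * z_rel)
        rel_frac = magnitude * direction
        center_frac = rng.uniform(0.1, 0.3, (n_tr, n))
        freeze_frac = rng.uniform(0.0, 0.1, (n_tr, n))
        edge = TRIAL_SECONDS * (1 - center_frac - freeze_frac)
        cw = edge * (1 + rel_frac) / 2
        ccw = edge * (1 - rel_frac) / 2
        for t in range(n_tr):
            for i, s in enumerate(subjects):
                lat_rows.append((
                    s, test, t + 1,
                    round(cw[t, i], 1), round(ccw[t, i], 1),
                    round(center_frac[t, i] * TRIAL_SECONDS, 1),
                    round(freeze_frac[t, i] * TRIAL_SECONDS, 1),
                ))
    lateralization = pd.DataFrame(
        lat_rows,
        columns=["subject", "test", "trial", "time_cw_s", "time_ccw_s",
                 "time_center_s", "time_freeze_s"],
    )

    # --- maze phases --------------------------------------------------------
    # threshold 10-of-12 scaled to the configured trials/day
    threshold = int(np.ceil(10 / 12 * 2 * config.trials_per_day))
    phase_params = {
        # (intercept, base slope, latent sensitivity); calibrated so the
        # default cohort lands near the nominal day targets in trait_means
        "learning": (-0.4, 0.55, 0.45, "spatial_learning"),
        "reversal": (-0.6, 0.50, 0.45, "flexibility"),
        "memory": (0.8, 0.55, 0.45, "memory"),
    }
    maze_rows = []
    for phase, (a, b, sens, trait) in phase_params.items():
        # memory/flexibility latents: higher latent = better performance =
        # fewer days, so flip their sign into the slope (days fall as the
        # latent rises, and the phase indices rise with the latent)
        z = lat[trait] if phase == "learning" else -lat[trait]
        seqs = _simulate_phase(
            rng, z, a, b, sens, config.trials_per_day, config.max_days, threshold
        )
        for s, days in zip(subjects, seqs):
            for d, choices in enumerate(days, start=1):
                for t, c in enumerate(choices, start=1):
                    maze_rows.append((s, phase, d, t, int(c)))
    maze = pd.DataFrame(
        maze_rows, columns=["subject", "phase", "day", "trial", "correct"]
    )

    cohort = RawCohort(
        subjects=subjects,
        morphometrics=morpho,
        ventilation=vent,
        open_field=open_field,
        scototaxis=scoto,
        sociability=social,
        lateralization=lateralization,
        maze=maze,
        config=config,
    )
    if config.missing_rate > 0:
        cohort = inject_missingness(
            cohort, config.missing_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return cohort


def _block_probability(rate: float) -> float:
    """Per-block removal probability with the index cascade accounted for.

    Removing the learning (reversal) phase also blanks the flexibility
    (flexibility and memory) index cells, so the expected missing-cell count
    of the 14-column trait table is 16q - 2q^2 per subject at block
    probability q. Solving 16q - 2q^2 = 14*rate keeps the expected missing
    fraction equal to ``rate`` (q=1 exactly at rate=1).
    """
    return (16.0 - np.sqrt(256.0 - 112.0 * rate)) / 4.0


def inject_missingness(cohort: RawCohort, rate: float, seed: int) -> RawCohort:
    """Remove whole assay blocks per subject, mimicking study dropout.

    Each eligible (subject, assay-block) pair is removed independently with
    a probability calibrated so the expected missing-cell fraction of the
    derived trait table equals ``rate``. First-timepoint morphometrics are
    never removed.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    out = cohort.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    q = _block_probability(rate)
    drop = rng.random((len(cohort.subjects), len(_BLOCKS))) < q
    for i, s in enumerate(cohort.subjects):
        gone = {b for j, b in enumerate(_BLOCKS) if drop[i, j]}
        if not gone:
            continue
        if "morpho_final" in gone:
            m = out.morphometrics
            out.morphometrics = m[
                ~((m.subject == s) & (m.timepoint == "final"))
            ]
        if "ventilation" in gone:
            v = out.ventilation
            out.ventilation = v[v.subject != s]
        for block, attr in (
            ("open_field", "open_field"), ("scototaxis", "scototaxis"),
            ("sociability", "sociability"),
        ):
            if block in gone:
                t = getattr(out, attr)
                setattr(out, attr, t[t.subject != s])
        for test in ("motor", "visual"):
            if f"{test}_lat" in gone:
                t = out.lateralization
                out.lateralization = t[~((t.subject == s) & (t.test == test))]
        for phase in ("learning", "reversal", "memory"):
            if phase in gone:
                t = out.maze
                out.maze = t[~((t.subject == s) & (t.phase == phase))]
    for t in RawCohort._TABLES:
        setattr(out, t, getattr(out, t).reset_index(drop=True))
    return out
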