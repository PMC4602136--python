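"""Synthetic stroke-recovery cohorts with known ground truth.

Emulates a longitudinal sensorimotor-stroke study: patients split into three
recovery subgroups — *fast* (linear trajectory of the z-scored hand-skill
test), *slow* (exponential trajectory converging to an asymptote within the
normal band, z >= -2.5) and *impaired* (exponential trajectory converging
below -2.5) — assessed on a monthly visit schedule against a healthy control
group that defines the z-transform.

Tests generated per visit:

* ``PSO`` — picking small objects, a timed dexterity task (seconds; longer is
  worse, so its z-score is sign-flipped).  This is the test whose trajectory
  defines the subgroup.
* ``HD`` — hand dynamometry grip force (kg).
* ``TOR`` — tactile object recognition (0-30 correct).
* ``NIH`` / ``mRS`` — ordinal clinical summaries correlated with subgroup.

Every public generator is deterministic given its integer seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TEST_KIND",
    "DEFAULT_CONTROL_CONFIG",
    "DEFAULT_SCHEDULE",
    "ControlStats",
    "CohortTable",
    "TrajectoryTruth",
    "generate_control_stats",
    "generate_trajectory",
    "generate_cohort",
    "z_transform",
    "invert_z",
    "NORMAL_BAND_Z",
]

#: Orientation of each test's z-score.  ``timed`` tests (durations) are
#: flipped so that worse performance is more negative: z = (mean - x) / sd.
#: ``score`` tests use z = (x - mean) / sd.
TEST_KIND: dict[str, str] = {"PSO": "timed", "HD": "score", "TOR": "score"}

#: Healthy-control population parameters (per-test mean, sd) used for the
#: z-transform.  PSO: 6 s +- 1 s (a severe patient at 44.9 s scores z ~ -38.9);
#: HD: 38 +- 13 kg; TOR: 28.5 +- 2.5 correct out of 30 (ceiling-near task).
DEFAULT_CONTROL_CONFIG: dict[str, tuple[float, float]] = {
    "PSO": (6.0, 1.0),
    "HD": (38.0, 13.0),
    "TOR": (28.5, 2.5),
}

#: Baseline (median day 5 post-stroke) plus monthly visits to month 9.
DEFAULT_SCHEDULE: tuple[int, ...] = (5, 30, 60, 90, 120, 150, 180, 210, 240, 270)

#: Half-width of the normal performance band in z units.
NORMAL_BAND_Z: float = 2.5

CLASSES = ("fast", "slow", "impaired")


@dataclass
class ControlStats:
    """Healthy-control population parameters plus a sampled control table."""

    means: dict[str, float]
    sds: dict[str, float]
    n_controls: int
    table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for test, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"control sd for {test} must be > 0, got {sd}")
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")


@dataclass
class TrajectoryTruth:
    """Ground-truth recovery model for one synthetic patient.

    ``params`` holds ``{"intercept", "slope"}`` for the linear family and
    ``{"asymptote", "amplitude", "tau"}`` for the exponential family, where
    z(t) = asymptote - amplitude * exp(-t / tau) and amplitude =
    asymptote - z(0).
    """

    patient_id: str
    true_class: str
    family: str
    params: dict[str, float]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.family not in ("linear", "exponential"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "exponential":
            if self.params["tau"] <= 0:
                raise ValueError("tau must be > 0")
            impaired = self.params["asymptote"] < -NORMAL_BAND_Z
            if impaired != (self.true_class == "impaired"):
                raise ValueError("impaired <=> exponential asymptote < -2.5")

    def curve(self, t: np.ndarray) -> np.ndarray:
        """Noiseless model curve evaluated at days ``t``."""
        t = np.asarray(t, dtype=float)
        if self.family == "linear":
            return self.params["intercept"] + self.params["slope"] * t
        a, amp, tau = (self.params[k] for k in ("asymptote", "amplitude", "tau"))
        return a - amp * np.exp(-t / tau)


@dataclass
class CohortTable:
    """Long-format longitudinal score table plus per-patient metadata.

    ``scores`` has one row per (patient, visit, test) with the raw value;
    ``meta`` one row per patient (age, gender, lesion side, etiology).
    """

    scores: pd.DataFrame
    meta: pd.DataFrame

    def pivot(self, test: str) -> pd.DataFrame:
        """Patients x visit-days matrix of raw values for one test."""
        sub = self.scores[self.scores["test"] == test]
        if sub.empty:
            raise KeyError(f"no rows for test {test!r}")
        wide = sub.pivot(index="id", columns="visit_day", values="value")
        return wide.reindex(self.meta["id"].tolist())

    def to_csv(self, scores_path, meta_path) -> None:
        self.scores.to_csv(scores_path, index=False)
        self.meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, scores_path, meta_path) -> "CohortTable":
        return cls(pd.read_csv(scores_path), pd.read_csv(meta_path))


def z_transform(values, stats: ControlStats, test: str):
    """z-score raw values against the control population of ``test``.

    Timed tests are flipped — z = (control mean - value) / sd — so that slow
    (bad) performance maps to negative z; score tests use
    z = (value - control mean) / sd.
    """
    kind = TEST_KIND.get(test)
    if kind is None:
        raise ValueError(f"unknown test {test!r}; known: {sorted(TEST_KIND)}")
    mean, sd = stats.means[test], stats.sds[test]
    values = np.asarray(values, dtype=float)
    return (mean - values) / sd if kind == "timed" else (values - mean) / sd


def invert_z(z, stats: ControlStats, test: str):
    """Raw score whose :func:`z_transform` equals ``z`` (exact inverse)."""
    kind = TEST_KIND.get(test)
    if kind is None:
        raise ValueError(f"unknown test {test!r}; known: {sorted(TEST_KIND)}")
    mean, sd = stats.means[test], stats.sds[test]
    z = np.asarray(z, dtype=float)
    return mean - z * sd if kind == "timed" else mean + z * sd


def generate_control_stats(
    config: dict[str, tuple[float, float]] | None = None,
    n: int = 22,
    seed: int = 0,
) -> ControlStats:
    """Control-group parameters plus a sampled table of ``n`` healthy subjects.

    The returned population mean/sd are exactly the configured values; the
    sampled table is illustrative (it is not used to re-estimate them).
    """
    config = dict(DEFAULT_CONTROL_CONFIG if config is None else config)
    for test, (_, sd) in config.items():
        if not sd > 0:
            raise ValueError(f"configured sd for {test} must be > 0, got {sd}")
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {test: rng.normal(mean, sd, size=n) for test, (mean, sd) in config.items()}
    )
    table.insert(0, "control_id", [f"c{i + 1:02d}" for i in range(n)])
    return ControlStats(
        means={t: float(m) for t, (m, _) in config.items()},
        sds={t: float(s) for t, (_, s) in config.items()},
        n_controls=n,
        table=table,
    )


def generate_trajectory(
    truth: TrajectoryTruth,
    visit_days,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """z-score series of one patient at the given visit days.

    With ``truth.noise_sd == 0`` the series lies exactly on the model curve.
    """
    visit_days = np.asarray(visit_days, dtype=float)
    if visit_days.size < 3:
        raise ValueError("need at least 3 visits")
    z = truth.curve(visit_days)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        z = z + rng.normal(0.0, truth.noise_sd, size=z.shape)
    return z


def _sample_truth(cls: str, pid: str, noise_sd: float, rng: np.random.Generator) -> TrajectoryTruth:
    if cls == "fast":
        params = {
            "intercept": float(rng.uniform(-2.0, 0.5)),
            "slope": float(rng.uniform(0.0, 0.004)),
        }
        return TrajectoryTruth(pid, cls, "linear", params, noise_sd)
    # Amplitudes reflect the deep baseline deficits of a cohort selected for
    # clinically significant hand impairment (baseline z down to ~ -40 for a
    # timed task a patient can barely perform).
    if cls == "slow":
        asym = float(rng.uniform(-2.0, 0.5))
        amp = float(rng.uniform(3.0, 20.0))
    else:  # impaired: converges clearly below the normal band
        asym = float(rng.uniform(-10.0, -3.0))
        amp = float(rng.uniform(3.0, 30.0))
    params = {
        "asymptote": asym,
        "amplitude": amp,
        "tau": float(rng.uniform(30.0, 90.0)),
    }
    return TrajectoryTruth(pid, cls, "exponential", params, noise_sd)


# Subgroup severity used for the ordinal clinical summaries (baseline NIHSS
# center, mRS baseline center) and the secondary tests.
_SEVERITY = {"fast": (3.5, 2.0), "slow": (5.0, 2.5), "impaired": (9.0, 4.0)}


def generate_cohort(
    n_per_class: tuple[int, int, int] = (8, 12, 8),
    schedule=DEFAULT_SCHEDULE,
    seed: int = 0,
    noise_sd: float = 0.5,
    missing_fraction: float = 10 / 280,
    control_config: dict[str, tuple[float, float]] | None = None,
) -> tuple[CohortTable, list[TrajectoryTruth], ControlStats]:
    """Generate a full synthetic cohort.

    Parameters
    ----------
    n_per_class:
        Patients in the (fast, slow, impaired) subgroups; default 8/12/8.
    schedule:
        Visit days post-stroke, strictly increasing, >= 3 visits.
    noise_sd:
        Measurement noise of the z-score series, in z units.
    missing_fraction:
        Fraction of behavioral cells deleted at random (default 10/280,
        i.e. ten missed visits out of 280 planned).

    Returns the raw-score table (z-scores are recovered downstream via
    :func:`z_transform` with the returned :class:`ControlStats`), the list of
    ground-truth trajectories and the control statistics.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size < 3:
        raise ValueError("visit schedule must have at least 3 visits")
    if not np.all(np.diff(schedule) > 0):
        raise ValueError("visit days must be strictly increasing")
    if any(n < 1 for n in n_per_class):
        raise ValueError("each class needs at least one patient")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing fraction must be in [0, 1)")

    root = np.random.SeedSequence(seed)
    rng_truth, rng_scores, rng_meta, rng_ctrl, rng_miss = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    stats = generate_control_stats(control_config, seed=rng_ctrl.integers(2**31))

    truths: list[TrajectoryTruth] = []
    for cls, n in zip(CLASSES, n_per_class):
        for _ in range(n):
            pid = f"s{len(truths) + 1:02d}"
            truths.append(_sample_truth(cls, pid, noise_sd, rng_truth))

    rows = []
    meta_rows = []
    for truth in truths:
        cls = truth.true_class
        sev_nih = _SEVERITY[cls][0]
        # -- main dexterity test (PSO): the classified trajectory
        z_pso = generate_trajectory(truth, schedule, rng_scores)
        z_pso = np.minimum(z_pso, 3.0)  # keep inverted times positive
        pso = invert_z(z_pso, stats, "PSO")
        # -- secondary tests: exponential return toward class-typical level
        tau2 = rng_scores.uniform(30.0, 90.0)
        z_asym_tor = {"fast": 0.3, "slow": 0.0, "impaired": -5.0}[cls]
        z_tor = z_asym_tor - 2.0 * np.exp(-schedule / tau2)
        z_tor = z_tor + rng_scores.normal(0, noise_sd, size=schedule.size)
        tor = np.clip(invert_z(np.clip(z_tor, -11.4, 0.6), stats, "TOR"), 0, 30)
        z_asym_hd = {"fast": 0.3, "slow": 0.1, "impaired": -1.5}[cls]
        z_hd = z_asym_hd - 2.0 * np.exp(-schedule / tau2)
        z_hd = z_hd + rng_scores.normal(0, noise_sd, size=schedule.size)
        hd = np.maximum(invert_z(z_hd, stats, "HD"), 0.0)
        # -- ordinal clinical summaries (not z-transformed downstream)
        decay = np.exp(-schedule / 120.0)
        nih = np.clip(np.round(sev_nih * decay + rng_scores.normal(0, 0.7, schedule.size)), 0, 42)
        mrs_base = {"fast": 2.0, "slow": 2.5, "impaired": 4.0}[cls]
        mrs = np.clip(np.round(mrs_base * decay + rng_scores.normal(0, 0.5, schedule.size)), 0, 6)
        for j, day in enumerate(schedule):
            rows += [
                {"id": truth.patient_id, "visit_day": day, "test": "PSO", "value": pso[j]},
                {"id": truth.patient_id, "visit_day": day, "test": "HD", "value": hd[j]},
                {"id": truth.patient_id, "visit_day": day, "test": "TOR", "value": tor[j]},
                {"id": truth.patient_id, "visit_day": day, "test": "NIH", "value": nih[j]},
                {"id": truth.patient_id, "visit_day": day, "test": "mRS", "value": mrs[j]},
            ]
        meta_rows.append(
            {
                "id": truth.patient_id,
                "age": int(rng_meta.integers(41, 83)),
                "gender": "F" if rng_meta.random() < 4 / 28 else "M",
                "side": "L" if rng_meta.random() < 13 / 28 else "R",
                "etiology": rng_meta.choice(["LAD", "CE", "UN", "OC"], p=[11 / 28, 10 / 28, 4 / 28, 3 / 28]),
            }
        )

    scores = pd.DataFrame(rows)
    if missing_fraction > 0:
        _delete_cells(scores, missing_fraction, rng_miss)
    return CohortTable(scores, pd.DataFrame(meta_rows)), truths, stats


def _delete_cells(scores: pd.DataFrame, fraction: float, rng: np.random.Generator) -> None:
    """Blank a random fraction of behavioral cells (NaN), keeping every visit
    column represented and >= 4 observations per patient-test for fitting."""
    behavioral = scores.index[scores["test"].isin(list(TEST_KIND))].to_numpy()
    n_delete = int(round(fraction * behavioral.size))
    candidates = rng.permutation(behavioral)
    deleted = 0
    for idx in candidates:
        if deleted >= n_delete:
            break
        row = scores.loc[idx]
        same = scores[(scores["test"] == row["test"]) & scores["value"].notna()]
        if (same["visit_day"] == row["visit_day"]).sum() <= 1:
            continue
        if (same["id"] == row["id"]).sum() <= 4:
            continue
        scores.loc[idx, "value"] = np.nan
        deleted += 1
    if deleted < n_delete:
        warnings.warn("could not delete the requested number of cells")
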