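"""Synthetic dimorphic cohorts calibrated to published reference statistics.

The real CT cohort behind this pipeline (276 adult Bulgarians, 136 males
and 140 females) is not publicly deposited, so testing and replication run
on synthetic cohorts built to carry the same statistical structure at two
levels:

* **measurement level** — per-bone vectors of the 33 named measurements
  drawn from a sex- and side-specific multivariate Gaussian whose means
  and SDs are the shipped reference preset, with a declared exchangeable
  cross-measurement correlation (the true covariance is unpublished);
  optional right-left offsets (preset = the published right-minus-left
  differences, split +d/2 / -d/2 around an individual latent value) and
  age-group offsets applied around a 45-year cutoff;

* **landmark level** — bones sampled from sex- and side-specific 34-point
  *templates* calibrated so their derived measurements match the preset
  means, deformed by a global scale factor ~ Normal(1, 0.03^2) and
  isotropic per-landmark shape jitter, with optional missing-landmark
  masks (default: 35 of 552 bones missing 1-3 landmarks) and repeated
  acquisitions with small landmark noise for reliability studies.

All generators are deterministic given their seed.  None of the
correlation or deformation choices are claims about the real cohort; they
are declared simulation assumptions (see the methods note).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist
from scipy.stats import truncnorm

from .landmarks import LANDMARK_NAMES, N_LANDMARKS, Cohort, LandmarkSet
from .measure import (
    FIRST_DATASET,
    FIRST_DATASET_NAMES,
    META_COLUMNS,
    evaluate_definitions,
)

__all__ = [
    "CohortConfig",
    "MeasurementGeneratorParams",
    "LandmarkGeneratorParams",
    "CalibrationError",
    "load_reference_means",
    "load_side_offsets",
    "load_age_offsets",
    "reference_targets",
    "calibrate_template",
    "template_for",
    "generate_measurement_cohort",
    "generate_landmark_cohort",
    "generate_repeat_study",
    "range_flags",
]

ANGLE_NAMES = tuple(m.name for m in FIRST_DATASET if m.kind == "angle")

#: Age model of the emulated cohort: mean, SD and truncation range (years).
AGE_MODEL = {"M": (56.5, 14.8, 19.0, 83.0), "F": (56.7, 13.8, 19.0, 88.0)}


class CalibrationError(RuntimeError):
    """Template calibration failed its residual tolerance."""


@dataclass
class CohortConfig:
    """Cohort composition; defaults emulate the reference study sample."""

    n_males: int = 136
    n_females: int = 140
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one individual per sex")


@dataclass
class MeasurementGeneratorParams:
    """Measurement-level generator settings.

    rho: exchangeable cross-measurement correlation within the
         linear/height block; pairs involving an angle use rho/2.
    side_correlation: correlation of the same measurement between the two
         sides of one individual (synthetic assumption; bilateral skeletal
         measurements are strongly correlated).
    laterality_offsets: apply the preset right-minus-left differences,
         split +/- d/2 around the individual's latent value.
    age_offsets: apply the preset age-group differences, split +/- d/2
         around the 45-year cutoff (older group larger where the preset
         is positive).
    """

    rho: float = 0.3
    side_correlation: float = 0.9
    laterality_offsets: bool = False
    age_offsets: bool = False
    age_cutoff: float = 45.0


@dataclass
class LandmarkGeneratorParams:
    """Landmark-level generator settings (mm)."""

    scale_sd: float = 0.03          # global size factor SD around 1
    sigma_shape: float = 1.5        # per-landmark isotropic shape jitter
    sigma_acq: float = 0.3          # acquisition (repeat) noise
    n_masked_bones: int = 35        # bones with missing landmarks
    max_masked_landmarks: int = 3   # 1..3 landmarks masked per such bone
    min_separation: float = 13.0    # template minimum pairwise distance


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("coxmorph.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@functools.lru_cache(maxsize=1)
def load_reference_means() -> pd.DataFrame:
    """Reference preset: mean/SD/min/max of the 33 measurements per sex
    and side, for an adult Bulgarian cohort of 136 males and 140 females."""
    df = _load_csv("reference_means.csv")
    assert set(df["measurement"]) == set(FIRST_DATASET_NAMES)
    return df


@functools.lru_cache(maxsize=1)
def load_side_offsets() -> pd.DataFrame:
    """Reference right-minus-left mean differences per sex."""
    return _load_csv("side_offsets.csv").set_index("measurement")


@functools.lru_cache(maxsize=1)
def load_age_offsets() -> pd.DataFrame:
    """Reference age-group differences (older minus younger) per sex/side."""
    return _load_csv("age_offsets.csv").set_index("measurement")


def _stat_vector(sex: str, side: str, stat: str) -> np.ndarray:
    df = load_reference_means()
    sub = df[(df["sex"] == sex) & (df["side"] == side)].set_index("measurement")
    return sub.loc[list(FIRST_DATASET_NAMES), stat].to_numpy(dtype=float)


def reference_targets(sex: str, side: str) -> np.ndarray:
    """The 33 preset means for one sex/side, in battery order."""
    return _stat_vector(sex, side, "mean")


# ---------------------------------------------------------------------------
# Template calibration
# ---------------------------------------------------------------------------

#: Hand-built anatomical starting configuration (mm), one right coxal bone
#: roughly at adult male scale.  Frame: x anterior, y lateral, z superior.
#: Only the topology matters: the calibration optimizer moves every
#: coordinate to match the measurement targets.
_START_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "mla":  (0.0, 60.0, 110.0),
    "iit":  (-15.0, 20.0, -90.0),
    "sps":  (75.0, 0.0, -25.0),
    "pss":  (-65.0, 25.0, 75.0),
    "ass":  (55.0, 40.0, 85.0),
    "ais":  (45.0, 35.0, 50.0),
    "pis":  (-60.0, 20.0, 40.0),
    "mli":  (10.0, 10.0, 40.0),
    "as":   (35.0, 25.0, 10.0),
    "asa":  (18.0, 35.0, 22.0),
    "ai":   (12.0, 30.0, -32.0),
    "ap":   (-12.0, 28.0, -15.0),
    "lss":  (25.0, 18.0, 5.0),
    "sfo":  (38.0, 22.0, -20.0),
    "ifo":  (32.0, 18.0, -75.0),
    "mfo":  (52.0, 15.0, -45.0),
    "lfo":  (20.0, 25.0, -45.0),
    "pirt": (-52.0, 12.0, 25.0),
    "is":   (-25.0, 5.0, -25.0),
    "ips":  (70.0, 0.0, -62.0),
    "iipr": (30.0, 10.0, -85.0),
    "lit":  (-28.0, 25.0, -60.0),
    "gsn":  (-45.0, 15.0, 5.0),
    "lsn":  (-28.0, 8.0, -35.0),
    "sij":  (-40.0, 5.0, 40.0),
    "pgl":  (-40.0, 45.0, 80.0),
    "pla":  (60.0, 8.0, -18.0),
    "plp":  (30.0, 14.0, 0.0),
    "mipr": (50.0, 5.0, -75.0),
    "lsi":  (18.0, 22.0, -25.0),
    "maps": (81.0, 2.0, -44.0),
    "mpps": (64.0, 3.0, -44.0),
    "ain":  (48.0, 36.0, 67.0),
    "pin":  (-58.0, 21.0, 57.0),
}


def _start_coords() -> np.ndarray:
    return np.array([_START_TEMPLATE[n] for n in LANDMARK_NAMES], dtype=float)


def calibrate_template(targets: np.ndarray,
                       start: np.ndarray | None = None,
                       *,
                       tol: float = 0.01,
                       min_separation: float = 13.0,
                       regularization: float = 1e-5,
                       ) -> np.ndarray:
    """Fit a 34x3 landmark configuration whose measurements hit ``targets``.

    Minimizes the sum of squared relative measurement residuals over the
    102 free coordinates with a soft hinge keeping every landmark pair at
    least ``min_separation`` mm apart (pairs pinned closer by a target are
    allowed to violate the hinge) and a weak pull toward the anatomical
    starting configuration.  Raises :class:`CalibrationError` if any
    measurement misses its target by more than ``tol`` (relative).

    The fit is a deterministic least-squares solve: same targets and
    start always give the same template.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (33,):
        raise ValueError("targets must be a 33-vector in battery order")
    if (targets <= 0).any():
        raise ValueError("targets must be positive")
    x0 = (_start_coords() if start is None else np.asarray(start, float)).ravel()

    sep_w = 0.5
    pair_i, pair_j = np.triu_indices(N_LANDMARKS, k=1)
    lm_idx = [tuple(LANDMARK_NAMES.index(n) for n in d.landmarks)
              for d in FIRST_DATASET]
    kinds = [d.kind for d in FIRST_DATASET]
    n_res = 33 + len(pair_i) + 3 * N_LANDMARKS

    def residuals(x: np.ndarray) -> np.ndarray:
        X = x.reshape(N_LANDMARKS, 3)
        m = evaluate_definitions(X)
        rel = (m - targets) / targets
        d = pdist(X)
        hinge = sep_w * np.maximum(0.0, (min_separation - d) / min_separation)
        reg = regularization * (x - x0)
        return np.concatenate([rel, hinge, reg])

    def jacobian(x: np.ndarray) -> np.ndarray:
        X = x.reshape(N_LANDMARKS, 3)
        J = np.zeros((n_res, 3 * N_LANDMARKS))

        def put(row: int, lm: int, grad: np.ndarray) -> None:
            J[row, 3 * lm:3 * lm + 3] += grad

        for r, (kind, idx) in enumerate(zip(kinds, lm_idx)):
            t = targets[r]
            if kind == "linear":
                a, b = idx
                diff = X[a] - X[b]
                u = diff / np.linalg.norm(diff)
                put(r, a, u / t)
                put(r, b, -u / t)
            elif kind == "height":
                a, b1, b2 = idx
                u = X[b2] - X[b1]
                w = X[a] - X[b1]
                lam = float(w @ u) / float(u @ u)
                perp = w - lam * u
                h = np.linalg.norm(perp)
                nhat = perp / h
                # envelope theorem: foot parameter lam treated as fixed
                put(r, a, nhat / t)
                put(r, b1, -(1 - lam) * nhat / t)
                put(r, b2, -lam * nhat / t)
            else:  # angle, in degrees
                a, v, b = idx
                u1 = X[a] - X[v]
                u2 = X[b] - X[v]
                n1 = np.linalg.norm(u1)
                n2 = np.linalg.norm(u2)
                c = np.clip(u1 @ u2 / (n1 * n2), -1.0, 1.0)
                s = np.sqrt(max(1.0 - c * c, 1e-12))
                scale = np.degrees(1.0) / (s * t)
                ga = -scale * (u2 / (n1 * n2) - c * u1 / n1 ** 2)
                gb = -scale * (u1 / (n1 * n2) - c * u2 / n2 ** 2)
                put(r, a, ga)
                put(r, v, -(ga + gb))
                put(r, b, gb)

        diff = X[pair_i] - X[pair_j]
        d = np.linalg.norm(diff, axis=1)
        active = d < min_separation
        g = -(sep_w / min_separation) * diff[active] / d[active, None]
        for row, lm_a, lm_b, grad in zip(33 + np.flatnonzero(active),
                                         pair_i[active], pair_j[active], g):
            put(int(row), int(lm_a), grad)
            put(int(row), int(lm_b), -grad)

        base = 33 + len(pair_i)
        J[base:, :] = regularization * np.eye(3 * N_LANDMARKS)
        return J

    sol = least_squares(residuals, x0, jac=jacobian, method="trf",
                        ftol=1e-14, xtol=1e-12, gtol=1e-14, max_nfev=3000)
    X = sol.x.reshape(N_LANDMARKS, 3)
    achieved = evaluate_definitions(X)
    rel = np.abs(achieved - targets) / targets
    if rel.max() > tol:
        worst = np.argsort(rel)[::-1][:5]
        report = "; ".join(
            f"{FIRST_DATASET_NAMES[i]}: target {targets[i]:.2f} "
            f"got {achieved[i]:.2f} ({100 * rel[i]:.2f}%)" for i in worst
        )
        raise CalibrationError(f"calibration residual exceeds {tol:.0%}: {report}")
    return X


@functools.lru_cache(maxsize=8)
def template_for(sex: str, side: str, min_separation: float = 13.0) -> np.ndarray:
    """Calibrated template for one sex/side (cached)."""
    T = calibrate_template(reference_targets(sex, side),
                           min_separation=min_separation)
    T.setflags(write=False)
    return T


# ---------------------------------------------------------------------------
# Measurement-level generator
# ---------------------------------------------------------------------------

def _correlation_cholesky(rho: float) -> np.ndarray:
    """Exchangeable correlation over the 33 measurements; angle pairs at
    rho/2.  Shrinks rho toward 0 if the matrix is not positive definite."""
    is_angle = np.array([n in ANGLE_NAMES for n in FIRST_DATASET_NAMES])
    for shrink in (1.0, 0.5, 0.25, 0.0):
        r = rho * shrink
        C = np.full((33, 33), r)
        half = np.logical_or.outer(is_angle, is_angle)
        C[half] = r / 2.0
        np.fill_diagonal(C, 1.0)
        try:
            return np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            continue
    raise ValueError(f"correlation matrix not positive definite for rho={rho}")


def _sample_ages(sex: str, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sd, lo, hi = AGE_MODEL[sex]
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def generate_measurement_cohort(config: CohortConfig | None = None,
                                params: MeasurementGeneratorParams | None = None,
                                sides: tuple[str, ...] = ("right",),
                                ) -> pd.DataFrame:
    """Draw a measurement table directly from the reference preset.

    One row per bone (individual x side).  Per-side marginals have the
    preset means and SDs; the two sides of one individual share a latent
    bone vector with correlation ``side_correlation``.  With
    ``laterality_offsets`` the per-measurement side means are rebuilt as
    (side average) +/- (preset right-left difference)/2, so the population
    right-minus-left difference equals the preset exactly.
    """
    config = config or CohortConfig()
    params = params or MeasurementGeneratorParams()
    for s in sides:
        if s not in ("right", "left"):
            raise ValueError(f"unknown side {s!r}")

    rng = np.random.default_rng(config.seed)
    L = _correlation_cholesky(params.rho)
    side_off = load_side_offsets()
    age_off = load_age_offsets()
    r = params.side_correlation

    frames = []
    for sex, n in (("M", config.n_males), ("F", config.n_females)):
        ages = _sample_ages(sex, n, rng)
        z = rng.standard_normal((n, 33)) @ L.T  # shared latent per individual
        mu = {s: _stat_vector(sex, s, "mean") for s in ("right", "left")}
        sd = {s: _stat_vector(sex, s, "sd") for s in ("right", "left")}
        if params.laterality_offsets:
            base = 0.5 * (mu["right"] + mu["left"])
            d = side_off.loc[list(FIRST_DATASET_NAMES), sex].to_numpy(float)
            mu = {"right": base + d / 2.0, "left": base - d / 2.0}
        for side in sides:
            e = rng.standard_normal((n, 33)) @ L.T  # side-specific residual
            values = mu[side] + sd[side] * (np.sqrt(r) * z + np.sqrt(1 - r) * e)
            if params.age_offsets:
                d_age = age_off.loc[
                    list(FIRST_DATASET_NAMES), f"{sex}_{side}"].to_numpy(float)
                old = (ages > params.age_cutoff)[:, None]
                values = values + np.where(old, d_age / 2.0, -d_age / 2.0)
            frames.append(pd.DataFrame(values, columns=list(FIRST_DATASET_NAMES))
                          .assign(individual_id=[f"{sex}{i + 1:04d}" for i in range(n)],
                                  side=side, sex=sex, age=ages))
    table = pd.concat(frames, ignore_index=True)
    return table[META_COLUMNS + list(FIRST_DATASET_NAMES)]


def range_flags(table: pd.DataFrame, margin: float = 0.2) -> pd.DataFrame:
    """Flag (never truncate) values outside the preset min/max by more
    than ``margin`` (relative); returns the offending rows/columns."""
    ref = load_reference_means().set_index(["measurement", "sex", "side"])
    rows = []
    for _, row in table.iterrows():
        for m in FIRST_DATASET_NAMES:
            lo, hi = ref.loc[(m, row["sex"], row["side"]), ["min", "max"]]
            if row[m] < lo * (1 - margin) or row[m] > hi * (1 + margin):
                rows.append({"individual_id": row["individual_id"],
                             "side": row["side"], "measurement": m,
                             "value": row[m], "min": lo, "max": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Landmark-level generator
# ---------------------------------------------------------------------------

def _deformed_bone(template: np.ndarray, scale: float, sigma_shape: float,
                   rng: np.random.Generator) -> np.ndarray:
    centroid = template.mean(axis=0)
    coords = centroid + scale * (template - centroid)
    if sigma_shape > 0:
        coords = coords + rng.normal(0.0, sigma_shape, size=coords.shape)
    return coords


def generate_landmark_cohort(config: CohortConfig | None = None,
                             params: LandmarkGeneratorParams | None = None,
                             sides: tuple[str, ...] = ("right", "left"),
                             ) -> Cohort:
    """Sample a landmark-level cohort from the calibrated templates.

    Each individual gets a global scale factor ~ Normal(1, scale_sd^2)
    shared across sides, and independent per-landmark isotropic jitter per
    bone.  ``n_masked_bones`` bones are then masked at 1 to
    ``max_masked_landmarks`` random landmarks each (whole landmarks, all
    three coordinates).
    """
    config = config or CohortConfig()
    params = params or LandmarkGeneratorParams()
    rng = np.random.default_rng(config.seed)

    templates = {(sex, side): template_for(sex, side, params.min_separation)
                 for sex in ("M", "F") for side in sides}
    records: list[LandmarkSet] = []
    for sex, n in (("M", config.n_males), ("F", config.n_females)):
        ages = _sample_ages(sex, n, rng)
        scales = rng.normal(1.0, params.scale_sd, size=n)
        for i in range(n):
            for side in sides:
                coords = _deformed_bone(templates[(sex, side)], scales[i],
                                        params.sigma_shape, rng)
                records.append(LandmarkSet(f"{sex}{i + 1:04d}", side, sex,
                                           float(ages[i]), coords))

    n_masked = min(params.n_masked_bones, len(records))
    if n_masked > 0:
        for k in rng.choice(len(records), size=n_masked, replace=False):
            n_miss = rng.integers(1, params.max_masked_landmarks + 1)
            lm = rng.choice(N_LANDMARKS, size=n_miss, replace=False)
            records[k].coords[lm] = np.nan
    return Cohort(records, provenance=f"synthetic landmark cohort seed={config.seed}")


def generate_repeat_study(n_subjects: int = 30, n_repeats: int = 3,
                          params: LandmarkGeneratorParams | None = None,
                          seed: int = 0,
                          sides: tuple[str, ...] = ("right", "left"),
                          ) -> list[Cohort]:
    """Repeated acquisitions for a reliability study.

    ``n_subjects`` individuals (half male, rounded up) contribute both
    sides; each bone is acquired ``n_repeats`` times with isotropic
    Gaussian landmark noise of SD ``sigma_acq``.  Returns one cohort per
    acquisition, matched by (individual_id, side).
    """
    params = params or LandmarkGeneratorParams()
    if n_repeats < 2:
        raise ValueError("a repeat study needs at least 2 acquisitions")
    rng = np.random.default_rng(seed)

    n_m = (n_subjects + 1) // 2
    true_bones: list[tuple[str, str, str, float, np.ndarray]] = []
    for sex, n in (("M", n_m), ("F", n_subjects - n_m)):
        ages = _sample_ages(sex, n, rng)
        scales = rng.normal(1.0, params.scale_sd, size=n)
        for i in range(n):
            for side in sides:
                T = template_for(sex, side, params.min_separation)
                coords = _deformed_bone(T, scales[i], params.sigma_shape, rng)
                true_bones.append((f"{sex}{i + 1:04d}", side, sex,
                                   float(ages[i]), coords))

    cohorts = []
    for rep in range(n_repeats):
        recs = [
            LandmarkSet(ind, side, sex, age,
                        coords + rng.normal(0.0, params.sigma_acq,
                                            size=coords.shape))
            for ind, side, sex, age, coords in true_bones
        ]
        cohorts.append(Cohort(recs, provenance=f"repeat acquisition {rep + 1}"))
    return cohorts
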