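"""Landmark schema, containers and I/O for coxal-bone landmark data.

The analysis rests on 34 named anatomical landmarks placed on one coxal
(hip) bone.  This module fixes their names and order (the column order of
every coordinate matrix in the package), holds per-bone landmark records
with their identity metadata, and reads/writes the two interchange formats:
a long-format CSV (canonical) and MeshLab PickedPoints XML (input-only
convenience, the native export of a common landmarking tool).

Coordinates are millimetres in an arbitrary scanner frame.  No
registration, alignment or mirroring is performed: every downstream
measurement (distances, unsigned angles, point-to-line heights) is
invariant to rigid motion and reflection, so none is needed.

Missingness is landmark-wise: a landmark is either fully observed (x, y, z)
or fully missing.  Records missing more than three landmarks fall outside
the imputation regime this pipeline supports and are flagged by
:func:`validate`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "LANDMARK_NAMES",
    "LANDMARK_INDEX",
    "N_LANDMARKS",
    "LandmarkSet",
    "Cohort",
    "SchemaError",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_picked_points",
    "validate",
    "MAX_IMPUTABLE_MISSING",
]

#: Ordered landmark abbreviations.  This order is the column order of all
#: 34x3 coordinate matrices and of the flattened 102-column matrices used
#: by the imputation module.
LANDMARK_NAMES: tuple[str, ...] = (
    "mla",   # most lateral point of the iliac ala
    "iit",   # most inferior point of the ischial tuberosity
    "sps",   # superior point of the pubic symphysis
    "pss",   # posterior superior iliac spine
    "ass",   # anterior superior iliac spine
    "ais",   # anterior inferior iliac spine
    "pis",   # posterior inferior iliac spine
    "mli",   # most lateral point of the pelvic inlet
    "as",    # superior point of the acetabulum at the pubic-iliac junction
    "asa",   # superior point of the acetabular margin at the base of the iliac ala
    "ai",    # inferior point of the acetabular margin
    "ap",    # posterior point of the acetabular margin
    "lss",   # most medial point of the superior portion of the lunate surface
    "sfo",   # most superior point of the obturator foramen margin
    "ifo",   # most inferior point of the obturator foramen margin
    "mfo",   # most medial point of the obturator foramen
    "lfo",   # most lateral point of the obturator foramen
    "pirt",  # piriform tubercle
    "is",    # ischial spine
    "ips",   # inferior point of the pubic symphysis
    "iipr",  # inferior point of the ischiopubic ramus
    "lit",   # most lateral point of the ischial tuberosity
    "gsn",   # deepest point of the greater sciatic notch
    "lsn",   # deepest point of the lesser sciatic notch
    "sij",   # most anterior point of the sacroiliac joint on the pelvic inlet
    "pgl",   # crossing of the iliac crest and the posterior gluteal line
    "pla",   # anterior end of the pectineal line
    "plp",   # posterior end of the pectineal line
    "mipr",  # mid-point of the ischiopubic ramus
    "lsi",   # most medial point of the inferior portion of the lunate surface
    "maps",  # mid-anterior point of the pubic symphysis
    "mpps",  # mid-posterior point of the pubic symphysis
    "ain",   # deepest point of the anterior interspinous notch
    "pin",   # deepest point of the posterior interspinous notch
)

N_LANDMARKS = len(LANDMARK_NAMES)
assert N_LANDMARKS == 34

#: name -> row index in the coordinate matrix
LANDMARK_INDEX: dict[str, int] = {n: i for i, n in enumerate(LANDMARK_NAMES)}

SIDES = ("right", "left")
SEXES = ("M", "F", "unknown")

#: Records missing more than this many landmarks are outside the
#: supported imputation regime.
MAX_IMPUTABLE_MISSING = 3


class SchemaError(ValueError):
    """Raised when input data violates the landmark schema."""


@dataclass
class LandmarkSet:
    """One bone: 34 named 3D points plus identity metadata.

    ``coords`` is a (34, 3) float array in millimetres; a missing landmark
    is a row of NaNs (never a partial NaN row).
    """

    individual_id: str
    side: str
    sex: str
    age: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 3):
            raise SchemaError(
                f"coords must be ({N_LANDMARKS}, 3), got {self.coords.shape}"
            )
        if self.side not in SIDES:
            raise SchemaError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 0:
            raise SchemaError(f"age must be nonnegative, got {self.age}")
        # enforce landmark-wise missingness
        nan_mask = np.isnan(self.coords)
        partial = nan_mask.any(axis=1) & ~nan_mask.all(axis=1)
        if partial.any():
            bad = [LANDMARK_NAMES[i] for i in np.flatnonzero(partial)]
            raise SchemaError(f"partially missing landmarks (per-axis NaN): {bad}")

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (34,) mask of missing landmarks."""
        return np.isnan(self.coords).all(axis=1)

    @property
    def missing_landmarks(self) -> list[str]:
        return [LANDMARK_NAMES[i] for i in np.flatnonzero(self.missing_mask)]

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            self.individual_id, self.side, self.sex, float(self.age), self.coords.copy()
        )


@dataclass
class Cohort:
    """A collection of bones; the unit every pipeline stage consumes."""

    records: list[LandmarkSet] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[LandmarkSet]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.records],
                "side": [r.side for r in self.records],
                "sex": [r.sex for r in self.records],
                "age": [r.age for r in self.records],
            }
        )

    def coords_matrix(self) -> np.ndarray:
        """Stack all records into an (n_bones, 34, 3) array."""
        return np.stack([r.coords for r in self.records])

    def subset(self, mask: Iterable[bool]) -> "Cohort":
        recs = [r for r, m in zip(self.records, mask) if m]
        return Cohort(recs, provenance=self.provenance)

    def config_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.provenance.encode())
        for r in self.records:
            h.update(f"{r.individual_id}|{r.side}|{r.sex}|{r.age}".encode())
            h.update(np.ascontiguousarray(r.coords).tobytes())
        return h.hexdigest()[:16]


_CSV_COLUMNS = ["individual_id", "side", "sex", "age", "landmark", "x", "y", "z"]


def read_landmark_csv(path) -> Cohort:
    """Read a long-format landmark CSV into a :class:`Cohort`.

    One row per observed landmark; columns ``individual_id, side, sex, age,
    landmark, x, y, z``.  Landmarks absent for a bone are recorded as
    missing.  Unknown landmark tokens and duplicate landmarks for one bone
    raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"individual_id": str},
                     float_precision="round_trip")
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"landmark CSV missing columns: {missing_cols}")

    unknown = sorted(set(df["landmark"]) - set(LANDMARK_NAMES))
    if unknown:
        raise SchemaError(f"unknown landmark abbreviation(s): {unknown}")

    records: list[LandmarkSet] = []
    for (ind, side), grp in df.groupby(["individual_id", "side"], sort=True):
        dup = grp["landmark"][grp["landmark"].duplicated()]
        if len(dup):
            raise SchemaError(
                f"duplicate landmark(s) {sorted(set(dup))} for bone ({ind}, {side})"
            )
        coords = np.full((N_LANDMARKS, 3), np.nan)
        idx = [LANDMARK_INDEX[n] for n in grp["landmark"]]
        coords[idx] = grp[["x", "y", "z"]].to_numpy(dtype=float)
        records.append(
            LandmarkSet(
                individual_id=str(ind),
                side=str(side),
                sex=str(grp["sex"].iloc[0]),
                age=float(grp["age"].iloc[0]),
                coords=coords,
            )
        )
    return Cohort(records, provenance=f"read_landmark_csv({path})")


def write_landmark_csv(cohort: Cohort, path) -> None:
    """Write a cohort to the long-format CSV (missing landmarks omitted).

    Values are written in shortest round-trip float repr and parsed back
    with a round-trip parser, so coordinates survive bit-identically.
    """
    rows = []
    for r in cohort:
        obs = ~r.missing_mask
        for i in np.flatnonzero(obs):
            x, y, z = r.coords[i]
            rows.append(
                (r.individual_id, r.side, r.sex, r.age, LANDMARK_NAMES[i], x, y, z)
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_picked_points(path, *, individual_id: str, side: str,
                       sex: str = "unknown", age: float = 0.0) -> LandmarkSet:
    """Read a MeshLab PickedPoints (``.pp``) XML file into a LandmarkSet.

    Point ``name`` attributes are matched case-insensitively against the
    registry; repeated names raise :class:`SchemaError`; absent landmarks
    are recorded as missing.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"malformed PickedPoints XML: {exc}") from exc

    coords = np.full((N_LANDMARKS, 3), np.nan)
    seen: set[str] = set()
    for point in tree.getroot().iter("point"):
        name = (point.get("name") or "").strip().lower()
        if name not in LANDMARK_INDEX:
            raise SchemaError(f"unknown landmark abbreviation: {name!r}")
        if name in seen:
            raise SchemaError(f"repeated landmark name: {name!r}")
        seen.add(name)
        try:
            xyz = [float(point.get(ax)) for ax in ("x", "y", "z")]
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric coordinates for {name!r}") from exc
        coords[LANDMARK_INDEX[name]] = xyz
    return LandmarkSet(individual_id, side, sex, age, coords)


def validate(cohort: Cohort) -> list[str]:
    """Report schema and consistency findings without modifying the data.

    Flags records missing more than three landmarks (outside the supported
    imputation regime), non-finite observed coordinates, duplicate
    (individual, side) pairs, and sex/age disagreements between the two
    sides of one individual.
    """
    findings: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    by_individual: dict[str, list[LandmarkSet]] = {}
    for r in cohort:
        key = (r.individual_id, r.side)
        if key in seen:
            findings.append(f"duplicate (individual_id, side): {key}")
        seen[key] = seen.get(key, 0) + 1
        by_individual.setdefault(r.individual_id, []).append(r)

        if r.n_missing > MAX_IMPUTABLE_MISSING:
            findings.append(
                f"bone ({r.individual_id}, {r.side}) exceeds imputable missingness: "
                f"{r.n_missing} missing landmarks (supported: <= {MAX_IMPUTABLE_MISSING})"
            )
        obs = r.coords[~r.missing_mask]
        if obs.size and not np.isfinite(obs).all():
            findings.append(
                f"bone ({r.individual_id}, {r.side}) has non-finite coordinates"
            )

    for ind, recs in by_individual.items():
        if len({r.sex for r in recs}) > 1:
            findings.append(f"individual {ind}: sex differs between sides")
        if len({float(r.age) for r in recs}) > 1:
            findings.append(f"individual {ind}: age differs between sides")
    return findings
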