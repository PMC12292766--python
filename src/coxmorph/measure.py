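"""Measurement engine: named coxal-bone measurements and interlandmark distances.

Two measurement batteries are derived from the 34-landmark configuration:

* the *first dataset* — 33 mostly standard coxal-bone measurements
  (27 linear distances, 3 angles, 3 point-to-line heights), each defined
  over named landmarks;
* the *ILD dataset* — all C(34, 2) = 561 interlandmark Euclidean
  distances, enumerated in canonical registry order and named ``"a-b"``
  with ``a`` before ``b`` in the registry.

Linear and height measurements are millimetres; angles are degrees in
[0, 180].  All measurements are invariant to rigid motion and reflection
and (except angles) equivariant under uniform scaling, so bones are
measured in their native scanner frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .landmarks import LANDMARK_INDEX, LANDMARK_NAMES, Cohort

__all__ = [
    "MeasurementDefinition",
    "FIRST_DATASET",
    "FIRST_DATASET_NAMES",
    "ILD_PAIRS",
    "ILD_NAMES",
    "META_COLUMNS",
    "euclidean_distance",
    "vertex_angle",
    "point_line_height",
    "compute_first_dataset",
    "compute_ild_dataset",
    "measurement_columns",
    "IncompleteRecordError",
    "DegenerateGeometryError",
]

META_COLUMNS = ["individual_id", "side", "sex", "age"]


class IncompleteRecordError(ValueError):
    """Raised when measuring a bone with missing landmarks."""


class DegenerateGeometryError(ValueError):
    """Raised for zero-length angle arms or coincident baseline points."""


@dataclass(frozen=True)
class MeasurementDefinition:
    """A typed geometric recipe over named landmarks.

    kind='linear'  -> landmarks = (a, b): Euclidean distance a-b.
    kind='angle'   -> landmarks = (a, v, b): angle at vertex v between
                      arms v->a and v->b.
    kind='height'  -> landmarks = (apex, b1, b2): orthogonal distance from
                      apex to the infinite line through b1 and b2.
    """

    name: str
    kind: str
    landmarks: tuple[str, ...]

    def __post_init__(self) -> None:
        arity = {"linear": 2, "angle": 3, "height": 3}
        if self.kind not in arity:
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        if len(self.landmarks) != arity[self.kind]:
            raise ValueError(
                f"{self.name}: kind {self.kind!r} needs {arity[self.kind]} "
                f"landmarks, got {len(self.landmarks)}"
            )
        unknown = [n for n in self.landmarks if n not in LANDMARK_INDEX]
        if unknown:
            raise ValueError(f"{self.name}: unknown landmark(s) {unknown}")


def _d(name: str, a: str, b: str) -> MeasurementDefinition:
    return MeasurementDefinition(name, "linear", (a, b))


def _ang(name: str, a: str, v: str, b: str) -> MeasurementDefinition:
    return MeasurementDefinition(name, "angle", (a, v, b))


def _h(name: str, apex: str, b1: str, b2: str) -> MeasurementDefinition:
    return MeasurementDefinition(name, "height", (apex, b1, b2))


#: The 33 first-dataset measurements, in reporting order:
#: 27 linear, then 3 heights, then 3 angles.
FIRST_DATASET: tuple[MeasurementDefinition, ...] = (
    _d("coxal_bone_height", "mla", "iit"),
    _d("coxal_bone_breadth", "sps", "pss"),
    _d("ala_breadth_superior_iliac_spines", "ass", "pss"),
    _d("ala_breadth_inferior_iliac_spines", "ais", "pis"),
    _d("ala_height", "mla", "mli"),
    _d("pubic_length", "sps", "as"),
    _d("vertical_acetabular_diameter", "asa", "ai"),
    _d("transversal_acetabular_diameter", "ap", "lss"),
    _d("vertical_diameter_obturator_foramen", "sfo", "ifo"),
    _d("transversal_diameter_obturator_foramen", "mfo", "lfo"),
    _d("greater_sciatic_notch_breadth", "pirt", "is"),
    _d("ischiopubic_ramus_length", "ips", "iipr"),
    _d("ischial_tuberosity_length", "lit", "iipr"),
    _d("intersciatic_distance", "gsn", "lsn"),
    _d("anterior_interspinal_distance", "ass", "ais"),
    _d("posterior_interspinal_distance", "pss", "pis"),
    _d("spino_sciatic_distance", "ais", "gsn"),
    _d("anterior_spino_auricular_distance", "ais", "sij"),
    _d("posterior_spino_auricular_distance", "pis", "sij"),
    _d("post_acetabular_ischium_distance", "ap", "iipr"),
    _d("gluteo_sciatic_distance", "pgl", "gsn"),
    _d("pectineal_line_length", "pla", "plp"),
    _d("lunate_ramus_distance", "mipr", "lsi"),
    _d("greater_sciatic_acetabular_distance", "gsn", "ap"),
    _d("lesser_sciatic_acetabular_distance", "lsn", "ai"),
    _d("pubic_symphysis_height", "sps", "ips"),
    _d("pubic_symphysis_width", "maps", "mpps"),
    _h("greater_sciatic_notch_height", "gsn", "pirt", "is"),
    _h("anterior_interspinal_height", "ain", "ass", "ais"),
    _h("posterior_interspinal_height", "pin", "pss", "pis"),
    _ang("greater_sciatic_notch_angle", "pirt", "gsn", "is"),
    _ang("ischiopubic_angle", "sps", "ips", "iipr"),
    _ang("ischial_angle", "mipr", "iit", "lit"),
)

FIRST_DATASET_NAMES: tuple[str, ...] = tuple(m.name for m in FIRST_DATASET)
assert len(FIRST_DATASET) == 33
assert sum(m.kind == "linear" for m in FIRST_DATASET) == 27
assert sum(m.kind == "angle" for m in FIRST_DATASET) == 3
assert sum(m.kind == "height" for m in FIRST_DATASET) == 3

#: Canonical enumeration of all 561 unordered landmark pairs.
ILD_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(LANDMARK_NAMES, 2))
ILD_NAMES: tuple[str, ...] = tuple(f"{a}-{b}" for a, b in ILD_PAIRS)
assert len(ILD_PAIRS) == 561


def euclidean_distance(p, q) -> float:
    """Euclidean distance between two 3D points (mm)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("non-finite input point")
    return float(np.linalg.norm(p - q))


def vertex_angle(a, v, b) -> float:
    """Angle in degrees at vertex ``v`` between arms v->a and v->b.

    The normalized dot product is clamped to [-1, 1] before arccos so
    exactly collinear configurations return 0 or 180 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    b = np.asarray(b, dtype=float)
    u1 = a - v
    u2 = b - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("zero-length angle arm (point equals vertex)")
    c = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def point_line_height(apex, base1, base2) -> float:
    """Orthogonal distance (mm) from ``apex`` to the infinite line
    through ``base1`` and ``base2``."""
    apex = np.asarray(apex, dtype=float)
    b1 = np.asarray(base1, dtype=float)
    b2 = np.asarray(base2, dtype=float)
    d = b2 - b1
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise DegenerateGeometryError("coincident baseline points")
    return float(np.linalg.norm(np.cross(apex - b1, d)) / nd)


def _require_complete(cohort: Cohort, module_hint: str) -> np.ndarray:
    incomplete = [
        (r.individual_id, r.side) for r in cohort if not r.is_complete
    ]
    if incomplete:
        raise IncompleteRecordError(
            f"{len(incomplete)} bone(s) have missing landmarks "
            f"(first: {incomplete[0]}); impute the cohort first ({module_hint})"
        )
    return cohort.coords_matrix()


def _evaluate(defn: MeasurementDefinition, X: np.ndarray) -> np.ndarray:
    """Vectorized evaluation of one definition over (n, 34, 3) coords."""
    idx = [LANDMARK_INDEX[n] for n in defn.landmarks]
    if defn.kind == "linear":
        p, q = X[:, idx[0]], X[:, idx[1]]
        return np.linalg.norm(p - q, axis=1)
    if defn.kind == "angle":
        a, v, b = X[:, idx[0]], X[:, idx[1]], X[:, idx[2]]
        u1 = a - v
        u2 = b - v
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        if (n1 == 0).any() or (n2 == 0).any():
            raise DegenerateGeometryError(f"{defn.name}: zero-length angle arm")
        c = np.clip(np.einsum("ij,ij->i", u1, u2) / (n1 * n2), -1.0, 1.0)
        return np.degrees(np.arccos(c))
    # height
    apex, b1, b2 = X[:, idx[0]], X[:, idx[1]], X[:, idx[2]]
    d = b2 - b1
    nd = np.linalg.norm(d, axis=1)
    if (nd == 0).any():
        raise DegenerateGeometryError(f"{defn.name}: coincident baseline points")
    return np.linalg.norm(np.cross(apex - b1, d), axis=1) / nd


def evaluate_definitions(coords: np.ndarray,
                         definitions: Sequence[MeasurementDefinition] = FIRST_DATASET,
                         ) -> np.ndarray:
    """Evaluate a battery of definitions on a single (34, 3) configuration."""
    X = np.asarray(coords, dtype=float)[None]
    return np.array([_evaluate(m, X)[0] for m in definitions])


def compute_first_dataset(cohort: Cohort) -> pd.DataFrame:
    """Compute the 33-measurement battery for every bone.

    Returns a table with the metadata columns followed by the 33
    measurement columns in registry order.  Requires complete records.
    """
    X = _require_complete(cohort, "coxmorph.impute")
    data = {m.name: _evaluate(m, X) for m in FIRST_DATASET}
    return pd.concat([cohort.metadata, pd.DataFrame(data)], axis=1)


def compute_ild_dataset(cohort: Cohort) -> pd.DataFrame:
    """Compute all 561 interlandmark distances for every bone."""
    X = _require_complete(cohort, "coxmorph.impute")
    i = np.array([LANDMARK_INDEX[a] for a, _ in ILD_PAIRS])
    j = np.array([LANDMARK_INDEX[b] for _, b in ILD_PAIRS])
    dist = np.linalg.norm(X[:, i] - X[:, j], axis=2)  # (n, 561)
    table = pd.DataFrame(dist, columns=list(ILD_NAMES))
    return pd.concat([cohort.metadata, table], axis=1)


def measurement_columns(table: pd.DataFrame) -> list[str]:
    """The non-metadata (measurement) columns of a measurement table."""
    return [c for c in table.columns if c not in META_COLUMNS]
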