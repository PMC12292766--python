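"""Intraobserver reliability via the technical error of measurement (TEM).

Repeated landmark acquisitions of the same bones quantify how precisely an
observer can replace the landmarks.  For each measurement the multi-repeat
TEM is

    TEM = sqrt( sum_i [ sum_j x_ij^2 - (sum_j x_ij)^2 / k ] / (N (k - 1)) )

over N subjects with k repeats each — i.e. the square root of the pooled
within-subject variance of the repeats.  The relative TEM expresses it as
a percentage of the grand mean of all N*k values:

    rTEM = 100 * TEM / grand_mean

Reliability is assessed on the full interlandmark-distance battery (561
distances per side, 1122 entries over both sides): the named measurements
are either themselves interlandmark distances or are derived (angles,
heights) from the same landmarks, so the ILD battery bounds the
landmark-placement error that propagates into every measurement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .landmarks import Cohort
from .measure import ILD_NAMES, compute_ild_dataset

__all__ = ["tem", "rtem", "reliability_study"]


def tem(values) -> float:
    """Technical error of measurement over an (N subjects, k repeats) matrix."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be an (N, k) matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("at least 2 repeats per subject are required")
    if n < 1 or not np.isfinite(x).all():
        raise ValueError("values must be finite with at least one subject")
    # algebraically sum(x^2) - (sum x)^2/k per subject; computed as squared
    # deviations from the subject mean, which is exact for identical repeats
    within = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return float(np.sqrt(within.sum() / (n * (k - 1))))


def rtem(tem_value: float, grand_mean: float) -> float:
    """Relative TEM (%): 100 * TEM / grand mean of all N*k values."""
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive")
    return 100.0 * tem_value / grand_mean


def _tem_columns(x: np.ndarray) -> np.ndarray:
    """TEM per column of an (N, k, m) repeated-measurement stack."""
    n, k, _ = x.shape
    within = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt(within.sum(axis=0) / (n * (k - 1)))


def reliability_study(repeats: Sequence[Cohort]) -> pd.DataFrame:
    """TEM/rTEM for all interlandmark distances over repeated acquisitions.

    ``repeats`` is a sequence of k >= 2 cohorts, each holding one
    acquisition of the same set of bones (matched by (individual_id,
    side)).  Returns a report with one row per (side, landmark pair):
    columns ``side, pair, mean, tem, rtem`` — 1122 rows for a two-sided
    study.
    """
    if len(repeats) < 2:
        raise ValueError("at least 2 repeated acquisitions are required")

    tables = [compute_ild_dataset(c) for c in repeats]
    key_sets = [set(zip(t["individual_id"], t["side"])) for t in tables]
    if any(ks != key_sets[0] for ks in key_sets[1:]):
        raise ValueError("repeats cover inconsistent (individual_id, side) sets")

    tables = [
        t.sort_values(["side", "individual_id"], kind="mergesort").reset_index(drop=True)
        for t in tables
    ]
    ild = list(ILD_NAMES)
    rows = []
    sides = sorted(tables[0]["side"].unique())
    for side in sides:
        # (N, k, 561) stack of the side's ILD values
        per_rep = [t.loc[t["side"] == side, ild].to_numpy() for t in tables]
        x = np.stack(per_rep, axis=1)
        tems = _tem_columns(x)
        means = x.mean(axis=(0, 1))
        rows.append(
            pd.DataFrame(
                {
                    "side": side,
                    "pair": ild,
                    "mean": means,
                    "tem": tems,
                    "rtem": 100.0 * tems / means,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
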