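"""Normality-gated group comparisons for measurement tables.

Each measurement is compared between two groups with a test chosen by a
Shapiro-Wilk normality gate: if both groups (for paired designs: the
per-individual differences) are consistent with normality at the gate
level, the parametric test is used (Welch's t for independent groups,
paired t for sides); otherwise the rank-based alternative (Mann-Whitney U,
Wilcoxon signed-rank).  Tests are two-sided at alpha = 0.05 with no
multiple-testing correction; per-measurement p-values are reported as-is.

Three factors are supported:

* ``sex``  — males vs females, run separately per side;
* ``side`` — right vs left, paired within individual, run per sex;
* ``age_group`` — at/below vs above a cutoff (default 45 years, the
  onset of menopause), run per sex per side.

Signed differences follow the reporting conventions male-female,
right-left and young-old.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measure import META_COLUMNS, measurement_columns

__all__ = [
    "ComparisonSpec",
    "choose_test",
    "compare",
    "significant_fraction",
]

_PARAMETRIC = {False: "welch_t", True: "paired_t"}
_RANK = {False: "mann_whitney_u", True: "wilcoxon_signed_rank"}


@dataclass
class ComparisonSpec:
    factor: str  # {"sex", "side", "age_group"}
    age_cutoff: float = 45.0
    alpha: float = 0.05
    gate_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.factor not in ("sex", "side", "age_group"):
            raise ValueError(f"unknown factor {self.factor!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def paired(self) -> bool:
        return self.factor == "side"


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    # Shapiro-Wilk is undefined for constant samples; a constant sample
    # carries no evidence against normality for gating purposes.
    if np.ptp(x) == 0:
        return True
    return sps.shapiro(x).pvalue >= alpha


def choose_test(group_a, group_b, paired: bool = False,
                gate_alpha: float = 0.05) -> str:
    """Select the test by the Shapiro-Wilk normality gate.

    Unpaired: parametric iff both groups pass the gate.  Paired:
    parametric iff the per-individual differences pass.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired groups must have equal length")
        if len(a) < 3:
            raise ValueError("paired comparison needs n >= 3")
        normal = _shapiro_normal(a - b, gate_alpha)
    else:
        if len(a) < 3 or len(b) < 3:
            raise ValueError("each group needs n >= 3")
        normal = _shapiro_normal(a, gate_alpha) and _shapiro_normal(b, gate_alpha)
    return _PARAMETRIC[paired] if normal else _RANK[paired]


def _run_test(test: str, a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if test == "welch_t":
        r = sps.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney_u":
        r = sps.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "paired_t":
        r = sps.ttest_rel(a, b)
    elif test == "wilcoxon_signed_rank":
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        r = sps.wilcoxon(a, b)
    else:  # pragma: no cover
        raise ValueError(test)
    return float(r.statistic), float(r.pvalue)


def _descriptives(x: np.ndarray, label: str) -> dict:
    return {
        f"{label}_n": len(x),
        f"{label}_mean": float(np.mean(x)),
        f"{label}_sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
        f"{label}_min": float(np.min(x)),
        f"{label}_max": float(np.max(x)),
    }


def _compare_measurements(sub_a: pd.DataFrame, sub_b: pd.DataFrame,
                          columns: list[str], spec: ComparisonSpec,
                          stratum: dict, labels: tuple[str, str]) -> list[dict]:
    rows = []
    for col in columns:
        a = sub_a[col].to_numpy(dtype=float)
        b = sub_b[col].to_numpy(dtype=float)
        test = choose_test(a, b, paired=spec.paired, gate_alpha=spec.gate_alpha)
        stat, p = _run_test(test, a, b)
        row = {"measurement": col, **stratum,
               "group_a": labels[0], "group_b": labels[1]}
        row.update(_descriptives(a, "a"))
        row.update(_descriptives(b, "b"))
        row.update(
            {
                "difference": float(np.mean(a) - np.mean(b)),
                "test": test,
                "statistic": stat,
                "p_value": p,
                "significant": p < spec.alpha,
            }
        )
        rows.append(row)
    return rows


def compare(table: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Per-measurement group comparisons on a measurement table.

    Returns one row per measurement per stratum with group descriptives,
    the gated test name, its statistic and two-sided p-value, and the
    signed mean difference (group_a - group_b).
    """
    for c in META_COLUMNS:
        if c not in table.columns:
            raise ValueError(f"measurement table lacks metadata column {c!r}")
    columns = measurement_columns(table)
    rows: list[dict] = []

    if spec.factor == "sex":
        for side, sub in table.groupby("side", sort=True):
            rows += _compare_measurements(
                sub[sub["sex"] == "M"], sub[sub["sex"] == "F"], columns, spec,
                {"stratum": f"side={side}"}, ("M", "F"))
    elif spec.factor == "age_group":
        young = table["age"] <= spec.age_cutoff
        for (sex, side), sub in table.groupby(["sex", "side"], sort=True):
            rows += _compare_measurements(
                sub[young.loc[sub.index]], sub[~young.loc[sub.index]],
                columns, spec, {"stratum": f"sex={sex},side={side}"},
                (f"age<={spec.age_cutoff:g}", f"age>{spec.age_cutoff:g}"))
    else:  # side, paired within individual
        for sex, sub in table.groupby("sex", sort=True):
            right = sub[sub["side"] == "right"].set_index("individual_id")
            left = sub[sub["side"] == "left"].set_index("individual_id")
            orphans = sorted(set(right.index) ^ set(left.index))
            if orphans:
                raise ValueError(
                    f"unpairable individuals for side comparison (sex={sex}): "
                    f"{orphans[:10]}"
                )
            left = left.loc[right.index]
            rows += _compare_measurements(
                right, left, columns, spec, {"stratum": f"sex={sex}"},
                ("right", "left"))
    return pd.DataFrame(rows)


def significant_fraction(comparison: pd.DataFrame) -> float:
    """Share of comparison rows with p below the significance level."""
    if len(comparison) == 0:
        return 0.0
    return float(comparison["significant"].mean())
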