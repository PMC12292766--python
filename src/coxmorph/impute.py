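"""Missing-landmark imputation by iterative conditional regression.

Each bone contributes a row of 102 coordinate scalars (34 landmarks x 3
axes).  Missing landmarks are filled by cycling over the incomplete
coordinate columns and regressing each on all other coordinates with a
Bayesian ridge model — a linear model with L2-type shrinkage whose
strength is estimated from the data — until the round-to-round change
falls below a relative tolerance.  Observed entries are never modified.

Imputation is fitted per side on the pooled male+female sample: the
coordinate correlations exploited by the regressions are side-specific
(bones are in native frames), while pooling sexes maximizes the number of
complete rows available to fit on.  Pooling before any train/test split
means imputed test bones borrow information from training bones; the
per-bone effect is small (at most 3 of 34 landmarks) but callers doing
strict generalization studies should impute per split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .landmarks import MAX_IMPUTABLE_MISSING, N_LANDMARKS, Cohort

__all__ = ["ImputationConfig", "ImputationError", "impute_cohort"]

N_COORDS = 3 * N_LANDMARKS  # 102


class ImputationError(ValueError):
    pass


@dataclass
class ImputationConfig:
    """Settings for the iterative imputer.

    max_iterations and tolerance govern the outer cycling loop (stop when
    the relative change of the imputed values drops below ``tolerance``);
    columns are visited in descending missing count, and the initial fill
    is the column mean.
    """

    max_iterations: int = 10
    tolerance: float = 1e-3
    random_seed: int = 0
    allow_excess_missing: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ImputationDiagnostics:
    n_imputed_bones: int = 0
    n_imputed_landmarks: int = 0
    iterations_per_side: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_imputed_bones": self.n_imputed_bones,
            "n_imputed_landmarks": self.n_imputed_landmarks,
            "iterations_per_side": self.iterations_per_side,
        }


def _impute_side(X: np.ndarray, config: ImputationConfig) -> tuple[np.ndarray, int]:
    """Impute one side's (n_bones, 102) matrix. Returns (filled, n_iter)."""
    missing = np.isnan(X)
    if not missing.any():
        return X, 0
    if missing.all(axis=0).any():
        raise ImputationError("a coordinate column is entirely missing")

    n_complete = int((~missing.any(axis=1)).sum())
    if n_complete < N_COORDS:
        warnings.warn(
            f"only {n_complete} complete bones to fit {N_COORDS}-predictor "
            f"regressions; imputation may be unstable",
            stacklevel=3,
        )

    imputer = IterativeImputer(
        estimator=BayesianRidge(),
        max_iter=config.max_iterations,
        tol=config.tolerance,
        initial_strategy="mean",
        imputation_order="descending",  # most missing values first
        sample_posterior=False,
        random_state=config.random_seed,
        keep_empty_features=False,
    )
    filled = imputer.fit_transform(X)
    # keep observed entries bit-exact regardless of implementation detail
    filled[~missing] = X[~missing]
    return filled, int(imputer.n_iter_)


def impute_cohort(cohort: Cohort, config: ImputationConfig | None = None
                  ) -> tuple[Cohort, ImputationDiagnostics]:
    """Fill missing landmark coordinates for every bone in the cohort.

    Returns a new cohort (observed coordinates unchanged bit-exactly) and
    diagnostics with the iteration counts.  Bones missing more than three
    landmarks are outside the supported regime and raise
    :class:`ImputationError` unless ``config.allow_excess_missing``.
    """
    config = config or ImputationConfig()

    excess = [
        (r.individual_id, r.side, r.n_missing)
        for r in cohort
        if r.n_missing > MAX_IMPUTABLE_MISSING
    ]
    if excess and not config.allow_excess_missing:
        raise ImputationError(
            f"{len(excess)} bone(s) missing more than {MAX_IMPUTABLE_MISSING} "
            f"landmarks (first: {excess[0]}); set allow_excess_missing to override"
        )

    diagnostics = ImputationDiagnostics(
        n_imputed_bones=sum(1 for r in cohort if r.n_missing > 0),
        n_imputed_landmarks=sum(r.n_missing for r in cohort),
    )

    out = [r.copy() for r in cohort]
    for side in sorted({r.side for r in out}):
        idx = [k for k, r in enumerate(out) if r.side == side]
        X = np.stack([out[k].coords.reshape(-1) for k in idx])
        filled, n_iter = _impute_side(X, config)
        diagnostics.iterations_per_side[side] = n_iter
        for row, k in enumerate(idx):
            out[k].coords = filled[row].reshape(N_LANDMARKS, 3)

    completed = Cohort(out, provenance=cohort.provenance + "|imputed")
    return completed, diagnostics
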