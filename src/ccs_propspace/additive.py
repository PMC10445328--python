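"""Atomic-additive (group-contribution) polarizability model.

The model predicts the mean dipole polarizability of a molecule as a linear
combination of its atom-type counts,

    alpha_pred = m + sum_i C_i * n_i,

with an intercept ``m`` and one coefficient ``C_i`` per element.  Because it
sees only the composition, every set of structural isomers maps to a single
predicted value — a diagnostic for that degeneracy is included.  Built-in
parameter sets cover the classic experimentally fitted coefficients of Bosque
and Sales and a re-fit on quantum-chemical reference data for small organics
(all values in Bohr³).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import ELEMENTS, PropertyDataset, VocabularyError


class SingularityError(ValueError):
    """Design matrix is rank-deficient (an element column carries no information)."""


@dataclass(frozen=True)
class AdditiveModelParams:
    """Intercept and per-element coefficients of the additive model (a.u.)."""

    intercept: float
    coeffs: Mapping[str, float]
    label: str = "custom"

    def __post_init__(self):
        missing = set(ELEMENTS) - set(self.coeffs)
        extra = set(self.coeffs) - set(ELEMENTS)
        if missing or extra:
            raise VocabularyError(
                f"coefficients must cover exactly {ELEMENTS}; "
                f"missing {sorted(missing)}, extra {sorted(extra)}"
            )
        vals = [self.intercept, *self.coeffs.values()]
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite model parameter")
        object.__setattr__(self, "coeffs", dict(self.coeffs))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "intercept": self.intercept,
            "coeffs": dict(self.coeffs),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AdditiveModelParams":
        return cls(
            intercept=float(d["intercept"]),
            coeffs={k: float(v) for k, v in d["coeffs"].items()},
            label=str(d.get("label", "custom")),
        )


#: Published / re-fitted coefficient tables, Bohr^3, element order C Cl H N O S.
_BUILTIN: dict[str, tuple[float, tuple[float, ...]]] = {
    "bosque": (2.14, (10.20, 14.60, 1.17, 6.95, 3.85, 20.20)),
    "refit": (1.71, (10.10, 12.70, 0.87, 7.88, 4.00, 19.10)),
    "no_intercept": (0.00, (10.37, 13.00, 0.88, 8.11, 4.24, 19.37)),
}


def builtin_params(name: str) -> AdditiveModelParams:
    """Built-in parameter set: ``bosque``, ``refit`` or ``no_intercept``."""
    try:
        intercept, coeffs = _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {sorted(_BUILTIN)}"
        ) from None
    return AdditiveModelParams(intercept, dict(zip(ELEMENTS, coeffs)), label=name)


def predict(params: AdditiveModelParams, counts: Mapping[str, int]) -> float:
    """Predicted polarizability (a.u.) for one composition."""
    total = params.intercept
    for sym, n in counts.items():
        if n == 0:
            continue
        try:
            total += params.coeffs[sym] * n
        except KeyError:
            raise VocabularyError(f"no coefficient for element {sym!r}") from None
    return total


def predict_dataset(params: AdditiveModelParams, ds: PropertyDataset) -> np.ndarray:
    """Vector of predictions over a dataset (record order preserved)."""
    coeff = np.array([params.coeffs[s] for s in ELEMENTS])
    X = np.array([[r.count(s) for s in ELEMENTS] for r in ds], dtype=float)
    if len(ds) == 0:
        return np.empty(0)
    return params.intercept + X @ coeff


def metrics(pred: Sequence[float], ref: Sequence[float]) -> tuple[float, float, float]:
    """Regression diagnostics ``(r2, mape, mae)``.

    r2 is the coefficient of determination 1 - SS_res/SS_tot, MAPE the mean
    absolute percentage error (percent, reference in the denominator), MAE the
    mean absolute error (a.u.).  References must be strictly positive.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(r <= 0):
        raise ValueError("MAPE undefined: reference values must be > 0")
    resid = p - r
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    mape = 100.0 * float(np.mean(np.abs(resid) / r))
    mae = float(np.mean(np.abs(resid)))
    return r2, mape, mae


@dataclass
class FitReport:
    """Fitted parameters plus in-sample diagnostics."""

    params: AdditiveModelParams
    r2: float
    mape: float
    mae: float
    n: int
    residuals: np.ndarray = field(repr=False)


def fit(ds: PropertyDataset, with_intercept: bool = True) -> FitReport:
    """Ordinary least squares of reference polarizability on element counts.

    Every record must carry ``alpha``.  The solve uses an orthogonal
    (SVD-based) decomposition; metrics are computed in-sample.  Raises
    :class:`SingularityError` when an element count is constant across the
    dataset (its coefficient would be unidentifiable).
    """
    missing = [r.id for r in ds if r.alpha is None]
    if missing:
        raise ValueError(f"records without alpha: {missing[:5]}")
    n = len(ds)
    X = np.array([[r.count(s) for r in ds] for s in ELEMENTS], dtype=float).T
    y = np.array([r.alpha for r in ds], dtype=float)
    p = len(ELEMENTS) + (1 if with_intercept else 0)
    if n <= p:
        raise ValueError(f"need more than {p} records, got {n}")
    # identifiability: a constant column (always together with an intercept,
    # or an all-zero column without one) makes the system rank-deficient
    for j, s in enumerate(ELEMENTS):
        col = X[:, j]
        if (with_intercept and np.ptp(col) == 0) or (not with_intercept and not col.any()):
            raise SingularityError(f"element {s!r} is constant across the dataset")
    design = np.column_stack([np.ones(n), X]) if with_intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularityError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    if with_intercept:
        intercept, coeffs = float(beta[0]), beta[1:]
    else:
        intercept, coeffs = 0.0, beta
    params = AdditiveModelParams(
        intercept,
        dict(zip(ELEMENTS, map(float, coeffs))),
        label="refit" if with_intercept else "no_intercept",
    )
    pred = design @ beta
    r2, mape, mae = metrics(pred, y)
    return FitReport(params=params, r2=r2, mape=mape, mae=mae, n=n, residuals=pred - y)


def isomer_degeneracy(ds: PropertyDataset, params: AdditiveModelParams) -> pd.DataFrame:
    """Per-formula degeneracy table of the additive model.

    Groups records by exact composition; each group shares one predicted
    value, while the reference polarizabilities may spread.  Columns:
    ``formula, n_isomers, predicted, ref_min, ref_max, ref_range``.
    """
    groups: dict[tuple, list] = {}
    for r in ds:
        if r.alpha is None:
            raise ValueError(f"record {r.id!r} has no reference alpha")
        groups.setdefault(r.composition_key, []).append(r)
    rows = []
    for key, members in groups.items():
        refs = [m.alpha for m in members]
        rows.append(
            {
                "formula": members[0].formula,
                "n_isomers": len(members),
                "predicted": predict(params, members[0].element_counts),
                "ref_min": min(refs),
                "ref_max": max(refs),
                "ref_range": max(refs) - min(refs),
            }
        )
    return pd.DataFrame(rows).sort_values("formula", ignore_index=True)
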