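"""Work-function design screen for organic photodetector candidates.

Pipeline: restrict a candidate set to a supported element vocabulary,
predict each molecule's polarizability with the additive model, keep the
molecules inside a HOMO–LUMO gap window (a target optical detection band),
pick four quartile representatives of the predicted-polarizability
distribution, and evaluate the Topping work-function change for each
representative with an enhanced adsorbed-state polarizability
``alpha' = enhancement_factor * alpha_pred``.  Because the work-function
shift decreases with the adsorbate polarizability, the spread of the
resulting values measures how freely the work function can be tuned at a
fixed optical gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .additive import AdditiveModelParams, builtin_params, predict
from .physical import ToppingParams, topping_delta_phi
from .records import ELEMENTS, MoleculeRecord, PropertyDataset


class InsufficientDataError(ValueError):
    """Too few window members to pick quartile representatives."""


@dataclass
class ScreenConfig:
    """Configuration of the design screen."""

    gap_center: float
    gap_halfwidth: float = 0.1
    allowed_elements: frozenset[str] = frozenset(ELEMENTS)
    params: AdditiveModelParams = field(default_factory=lambda: builtin_params("refit"))
    topping: ToppingParams = ToppingParams(mu0=4.0, d=1.5, theta=1.0, alpha_eff=0.0)
    enhancement_factor: float = 10.0

    def __post_init__(self):
        if not self.gap_halfwidth > 0:
            raise ValueError("gap_halfwidth must be > 0")
        if not self.enhancement_factor > 0:
            raise ValueError("enhancement_factor must be > 0")
        self.allowed_elements = frozenset(self.allowed_elements)


@dataclass
class ScreenResult:
    """Outcome of one screen run."""

    n_candidates: int
    window_members: PropertyDataset
    quartile_reps: list[tuple[MoleculeRecord, float]]
    alpha_range: Optional[tuple[float, float]]
    phi_range: Optional[tuple[float, float]]


def filter_by_elements(ds: PropertyDataset, allowed: Sequence[str]) -> PropertyDataset:
    """Keep records whose every present element lies in ``allowed``."""
    allowed = set(allowed)
    kept = [
        r for r in ds
        if all(s in allowed for s, n in r.element_counts.items() if n > 0)
    ]
    return ds.subset(kept)


def gap_window(ds: PropertyDataset, center: float, halfwidth: float) -> PropertyDataset:
    """Keep records with ``|gap - center| <= halfwidth`` (closed interval).

    The boundary test tolerates float representation error, so a gap stored
    as exactly ``center + halfwidth`` in decimal is kept.
    """
    tol = 1e-12 * max(abs(center), abs(halfwidth), 1.0)
    kept = [
        r for r in ds
        if r.gap is not None and abs(r.gap - center) <= halfwidth + tol
    ]
    if not kept:
        warnings.warn(
            f"gap window {center} +- {halfwidth} eV is empty", stacklevel=2
        )
    return ds.subset(kept)


def quartile_representatives(
    window: PropertyDataset, params: AdditiveModelParams
) -> list[tuple[MoleculeRecord, float]]:
    """Four molecules representing the quartiles of predicted polarizability.

    The quartile targets are the 12.5th, 37.5th, 62.5th and 87.5th
    percentiles of the predicted-alpha distribution (the mid-points of the
    four quartile bins).  For each target the member with the smallest
    |alpha - target| is chosen; ties break toward lower alpha, then
    lexicographically smaller id.  Representatives are kept distinct when the
    window allows it.  Returned sorted by ascending alpha.
    """
    if len(window) < 4:
        raise InsufficientDataError(
            f"need >= 4 window members for quartile representatives, got {len(window)}"
        )
    preds = [(r, predict(params, r.element_counts)) for r in window]
    alphas = np.array([a for _, a in preds])
    chosen: list[tuple[MoleculeRecord, float]] = []
    chosen_ids: set[str] = set()
    for pct in (12.5, 37.5, 62.5, 87.5):
        target = float(np.percentile(alphas, pct))
        ranked = sorted(preds, key=lambda ra: (abs(ra[1] - target), ra[1], ra[0].id))
        pick = next((ra for ra in ranked if ra[0].id not in chosen_ids), ranked[0])
        chosen.append(pick)
        chosen_ids.add(pick[0].id)
    return sorted(chosen, key=lambda ra: (ra[1], ra[0].id))


def run_screen(ds: PropertyDataset, cfg: ScreenConfig) -> ScreenResult:
    """Run the full screen; deterministic for identical input and config."""
    if len(ds) == 0:
        raise ValueError("screen stage filter_by_elements: empty input dataset")
    candidates = filter_by_elements(ds, cfg.allowed_elements)
    window = gap_window(candidates, cfg.gap_center, cfg.gap_halfwidth)
    if len(window) == 0:
        return ScreenResult(
            n_candidates=len(candidates),
            window_members=window,
            quartile_reps=[],
            alpha_range=None,
            phi_range=None,
        )
    window_alphas = [predict(cfg.params, r.element_counts) for r in window]
    try:
        reps = quartile_representatives(window, cfg.params)
    except InsufficientDataError as exc:
        raise InsufficientDataError(f"screen stage quartile_representatives: {exc}")
    phis = [
        topping_delta_phi(replace(cfg.topping, alpha_eff=cfg.enhancement_factor * a))
        for _, a in reps
    ]
    return ScreenResult(
        n_candidates=len(candidates),
        window_members=window,
        quartile_reps=reps,
        alpha_range=(min(window_alphas), max(window_alphas)),
        phi_range=(min(phis), max(phis)),
    )
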