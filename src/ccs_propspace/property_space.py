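"""Statistics of the (HOMO–LUMO gap, polarizability) property space.

For a labelled dataset this module quantifies how strongly each property
axis clusters by functional-group class: the two-sample Kolmogorov–Smirnov
statistic is used as a plain distribution distance (no p-values), and the
class-level clustering strength is summarised as the unweighted mean of the
KS distance over all unordered class pairs.  A gap axis that clusters by
chromophore gives a high average; a polarizability axis driven by atomic
composition rather than functionality gives a low one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import MoleculeRecord, PropertyDataset


class InsufficientDataError(ValueError):
    """A class (or axis) has too few usable records."""


def _axis_value(record: MoleculeRecord, axis: str) -> Optional[float]:
    if axis == "gap":
        return record.gap
    if axis == "alpha":
        return record.alpha
    raise ValueError(f"unknown axis {axis!r} (expected 'gap' or 'alpha')")


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample Kolmogorov–Smirnov statistic in [0, 1].

    The exact supremum over the merged sample points of the absolute
    difference of the two empirical CDFs.  Used as a distribution distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


@dataclass
class ClusterReport:
    """Pairwise KS distances between class-conditional distributions."""

    property_axis: str
    classes: list[str]
    pairwise_ks: np.ndarray
    average_ks: float
    per_class_summary: pd.DataFrame


def cluster_report(
    ds: PropertyDataset,
    axis: str,
    classes: Optional[Iterable[str]] = None,
) -> ClusterReport:
    """Class-clustering analysis of one property axis.

    Parameters
    ----------
    ds
        Dataset; records without a class label or without the axis value are
        ignored.  Upstream filtering should already have removed molecules
        carrying more than one functional group.
    axis
        ``"gap"`` or ``"alpha"``.
    classes
        Class labels to compare (default: all labels present, sorted).  Each
        must have at least 2 usable records.

    The headline number, ``average_ks``, is the unweighted mean of the KS
    statistic over all unordered class pairs (an interpretation choice; see
    the methods note).
    """
    by_class: dict[str, list[float]] = {}
    for r in ds:
        v = _axis_value(r, axis)
        if r.fg_class is None or v is None:
            continue
        by_class.setdefault(r.fg_class, []).append(v)
    labels = sorted(by_class) if classes is None else list(classes)
    for lab in labels:
        n = len(by_class.get(lab, []))
        if n < 2:
            raise InsufficientDataError(
                f"class {lab!r} has {n} usable record(s) on axis {axis!r}; need >= 2"
            )
    k = len(labels)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = ks_two_sample(by_class[labels[i]], by_class[labels[j]])
            mat[i, j] = mat[j, i] = d
    iu = np.triu_indices(k, 1)
    average = float(mat[iu].mean()) if iu[0].size else 0.0
    summary = pd.DataFrame(
        [
            {
                "class": lab,
                "n": len(by_class[lab]),
                "mean": float(np.mean(by_class[lab])),
                "sd": float(np.std(by_class[lab], ddof=1)),
                "min": float(np.min(by_class[lab])),
                "max": float(np.max(by_class[lab])),
            }
            for lab in labels
        ]
    ).set_index("class")
    return ClusterReport(
        property_axis=axis,
        classes=labels,
        pairwise_ks=mat,
        average_ks=average,
        per_class_summary=summary,
    )


def global_correlation(ds: PropertyDataset) -> tuple[float, float, int]:
    """Pearson correlation of (gap, alpha) pairs: ``(r, r_squared, n)``."""
    pairs = [(r.gap, r.alpha) for r in ds if r.gap is not None and r.alpha is not None]
    if len(pairs) < 3:
        raise InsufficientDataError("need >= 3 records with both gap and alpha")
    gap, alpha = map(np.asarray, zip(*pairs))
    if np.ptp(gap) == 0 or np.ptp(alpha) == 0:
        raise ValueError("degenerate correlation: zero variance on an axis")
    r = float(stats.pearsonr(gap, alpha).statistic)
    return r, r * r, len(pairs)


def _summarize(values: list[float]) -> dict:
    if not values:
        return {"n": 0, "mean": None, "sd": None, "min": None, "max": None}
    return {
        "n": len(values),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else None,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def composition_slices(
    ds: PropertyDataset,
    formulas: Iterable[Mapping[str, int]],
) -> dict[str, dict[str, dict]]:
    """Gap and alpha summaries for fixed atomic compositions.

    ``formulas`` is an iterable of element-count maps (e.g. ``{"C": 4,
    "H": 8, "O": 1}``).  Returns, per canonical formula string, summaries of
    both axes over the records with exactly that composition.  A formula with
    no records yields an empty summary and a warning.
    """
    wanted: dict[tuple[int, ...], str] = {}
    for f in formulas:
        probe = MoleculeRecord(id="_probe", element_counts=dict(f))
        wanted[probe.composition_key] = probe.formula
    groups: dict[str, dict[str, list[float]]] = {
        name: {"gap": [], "alpha": []} for name in wanted.values()
    }
    for r in ds:
        name = wanted.get(r.composition_key)
        if name is None:
            continue
        if r.gap is not None:
            groups[name]["gap"].append(r.gap)
        if r.alpha is not None:
            groups[name]["alpha"].append(r.alpha)
    out = {}
    for name, axes in groups.items():
        if not axes["gap"] and not axes["alpha"]:
            warnings.warn(f"no records with composition {name}", stacklevel=2)
        out[name] = {axis: _summarize(vals) for axis, vals in axes.items()}
    return out
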