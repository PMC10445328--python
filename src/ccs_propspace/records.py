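"""Canonical molecule-record data model.

A :class:`MoleculeRecord` carries everything the analysis consumes for one
molecule: its atomic composition over the supported element vocabulary
(C, Cl, H, N, O, S — the elements of QM7-X-like small organics), an optional
functional-group class label, the HOMO–LUMO gap in eV, and the dipole
polarizability in atomic units (Bohr³), as a scalar mean and/or a symmetric
3×3 tensor.  A :class:`PropertyDataset` is an ordered collection of records
with unique ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: Supported element vocabulary, in canonical column order.
ELEMENTS: tuple[str, ...] = ("C", "Cl", "H", "N", "O", "S")

#: Default cap on non-hydrogen atoms per molecule (QM7-X-like chemical space).
DEFAULT_MAX_HEAVY = 7

#: Symmetric-storage tensor component order.
TENSOR_COMPONENTS: tuple[str, ...] = ("axx", "axy", "axz", "ayy", "ayz", "azz")


class InvariantError(ValueError):
    """A record or dataset violates a structural invariant."""


class VocabularyError(ValueError):
    """An element symbol outside the supported vocabulary was encountered."""


def _tensor_from_components(c: Sequence[float]) -> np.ndarray:
    axx, axy, axz, ayy, ayz, azz = c
    return np.array([[axx, axy, axz], [axy, ayy, ayz], [axz, ayz, azz]], dtype=float)


def tensor_components(tensor: np.ndarray) -> tuple[float, ...]:
    """Six independent components of a symmetric tensor, in canonical order."""
    t = np.asarray(tensor, dtype=float)
    return (t[0, 0], t[0, 1], t[0, 2], t[1, 1], t[1, 2], t[2, 2])


@dataclass
class MoleculeRecord:
    """One molecule: composition plus optional properties.

    Parameters
    ----------
    id
        Opaque unique identifier.
    element_counts
        Map element symbol -> non-negative atom count.  Symbols are
        case-sensitive and must come from :data:`ELEMENTS`.
    fg_class
        Optional functional-group class label.
    gap
        HOMO–LUMO gap in eV (> 0 when present).
    alpha
        Scalar mean polarizability in atomic units (> 0 when present).
    alpha_tensor
        Symmetric 3×3 polarizability tensor, atomic units.
    """

    id: str
    element_counts: dict[str, int]
    fg_class: Optional[str] = None
    gap: Optional[float] = None
    alpha: Optional[float] = None
    alpha_tensor: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        counts = {}
        for sym, n in dict(self.element_counts).items():
            if sym not in ELEMENTS:
                raise VocabularyError(
                    f"record {self.id!r}: unsupported element symbol {sym!r}; "
                    f"supported: {', '.join(ELEMENTS)}"
                )
            counts[sym] = int(n)
        self.element_counts = counts
        if self.alpha_tensor is not None:
            self.alpha_tensor = np.asarray(self.alpha_tensor, dtype=float)

    # -- derived quantities -------------------------------------------------

    def count(self, symbol: str) -> int:
        return self.element_counts.get(symbol, 0)

    @property
    def heavy_atoms(self) -> int:
        """Number of non-hydrogen atoms."""
        return sum(n for s, n in self.element_counts.items() if s != "H")

    @property
    def n_atoms(self) -> int:
        return sum(self.element_counts.values())

    @property
    def formula(self) -> str:
        """Canonical formula string, e.g. ``C6H8O`` (element order of ELEMENTS)."""
        parts = []
        for s in ELEMENTS:
            n = self.count(s)
            if n == 1:
                parts.append(s)
            elif n > 1:
                parts.append(f"{s}{n}")
        return "".join(parts)

    @property
    def composition_key(self) -> tuple[int, ...]:
        """Hashable exact-composition key (counts in canonical element order)."""
        return tuple(self.count(s) for s in ELEMENTS)

    # -- validation ---------------------------------------------------------

    def validate(self, max_heavy: int = DEFAULT_MAX_HEAVY) -> "MoleculeRecord":
        """Check all record invariants; return self (for chaining).

        Raises :class:`InvariantError` on violation.
        """
        if any(n < 0 for n in self.element_counts.values()):
            raise InvariantError(f"record {self.id!r}: negative element count")
        if self.n_atoms == 0:
            raise InvariantError(f"record {self.id!r}: no atoms")
        if self.heavy_atoms > max_heavy:
            raise InvariantError(
                f"record {self.id!r}: {self.heavy_atoms} heavy atoms exceeds "
                f"maximum {max_heavy}"
            )
        if self.gap is not None and not self.gap > 0:
            raise InvariantError(f"record {self.id!r}: gap must be > 0")
        if self.alpha is not None and not self.alpha > 0:
            raise InvariantError(f"record {self.id!r}: alpha must be > 0")
        if self.alpha_tensor is not None:
            t = self.alpha_tensor
            if t.shape != (3, 3):
                raise InvariantError(f"record {self.id!r}: tensor must be 3x3")
            if not np.allclose(t, t.T, rtol=1e-8, atol=1e-12):
                raise InvariantError(f"record {self.id!r}: tensor not symmetric")
            if self.alpha is not None:
                trace_third = float(np.trace(t)) / 3.0
                if not np.isclose(self.alpha, trace_third, rtol=1e-8):
                    raise InvariantError(
                        f"record {self.id!r}: alpha {self.alpha} inconsistent with "
                        f"tensor trace/3 = {trace_third}"
                    )
        return self

    def copy(self, **changes) -> "MoleculeRecord":
        return replace(self, **changes)


@dataclass
class PropertyDataset:
    """Ordered sequence of molecule records with unique ids."""

    records: list[MoleculeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise InvariantError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def validate(self, max_heavy: int = DEFAULT_MAX_HEAVY) -> "PropertyDataset":
        for r in self.records:
            r.validate(max_heavy=max_heavy)
        return self

    def subset(self, keep: Iterable[MoleculeRecord], provenance: str | None = None
               ) -> "PropertyDataset":
        return PropertyDataset(list(keep), provenance=provenance or self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in canonical column order (absent values as NaN/None)."""
        rows = []
        any_tensor = any(r.alpha_tensor is not None for r in self.records)
        for r in self.records:
            row: dict = {"id": r.id}
            for s in ELEMENTS:
                row[s] = r.count(s)
            row["fg_class"] = r.fg_class
            row["gap"] = r.gap
            row["alpha"] = r.alpha
            if any_tensor:
                comps = (
                    tensor_components(r.alpha_tensor)
                    if r.alpha_tensor is not None
                    else (None,) * 6
                )
                for name, val in zip(TENSOR_COMPONENTS, comps):
                    row[name] = val
            rows.append(row)
        cols = ["id", *ELEMENTS, "fg_class", "gap", "alpha"]
        if any_tensor:
            cols += list(TENSOR_COMPONENTS)
        return pd.DataFrame(rows, columns=cols)
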