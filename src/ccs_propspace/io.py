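"""Readers and writers for molecule property tables (CSV / JSON) and XYZ files.

Canonical on-disk format is a CSV with fixed column order
``id, C, Cl, H, N, O, S, fg_class, gap, alpha`` followed, when tensors are
stored, by the six independent components ``axx, axy, axz, ayy, ayz, azz``.
Absent optional values are encoded as empty cells, never 0.  The JSON format
stores one object per record with the same field names.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from .records import (
    ELEMENTS,
    TENSOR_COMPONENTS,
    InvariantError,
    MoleculeRecord,
    PropertyDataset,
    VocabularyError,
    _tensor_from_components,
    tensor_components,
)

#: Canonical header (tensor block optional, appended when present).
CANONICAL_COLUMNS: tuple[str, ...] = ("id", *ELEMENTS, "fg_class", "gap", "alpha")


class ParseError(ValueError):
    """Malformed row or file structure."""


class FormatError(ValueError):
    """File-level structural error (e.g. XYZ atom-count mismatch)."""


def _is_absent(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def _record_from_mapping(row: Mapping, index, max_heavy: int) -> MoleculeRecord:
    rid = row.get("id")
    if _is_absent(rid):
        raise ParseError(f"row {index}: missing id")
    counts: dict[str, int] = {}
    for key, val in row.items():
        if key in ("id", "fg_class", "gap", "alpha") or key in TENSOR_COMPONENTS:
            continue
        if key not in ELEMENTS:
            raise VocabularyError(
                f"unsupported element column {key!r}; supported: {', '.join(ELEMENTS)}"
            )
        if _is_absent(val):
            continue
        try:
            n = int(float(val))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {index}: bad count for {key}: {val!r}") from exc
        if n != float(val):
            raise ParseError(f"row {index}: non-integer count for {key}: {val!r}")
        if n:
            counts[key] = n
    fg = row.get("fg_class")
    gap = row.get("gap")
    alpha = row.get("alpha")

    def _as_float(v, name):
        if _is_absent(v):
            return None
        try:
            return float(v)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {index}: bad {name}: {v!r}") from exc

    tensor = None
    comps = [row.get(c) for c in TENSOR_COMPONENTS]
    if any(not _is_absent(c) for c in comps):
        if any(_is_absent(c) for c in comps):
            raise ParseError(f"row {index}: partial tensor components")
        tensor = _tensor_from_components([float(c) for c in comps])
    try:
        rec = MoleculeRecord(
            id=str(rid),
            element_counts=counts,
            fg_class=None if _is_absent(fg) else str(fg),
            gap=_as_float(gap, "gap"),
            alpha=_as_float(alpha, "alpha"),
            alpha_tensor=tensor,
        )
        rec.validate(max_heavy=max_heavy)
    except (InvariantError, VocabularyError) as exc:
        raise type(exc)(f"row {index}: {exc}") from exc
    return rec


def read_dataset(path, format: str | None = None, max_heavy: int = 7) -> PropertyDataset:
    """Read a property table into a :class:`PropertyDataset`.

    Parameters
    ----------
    path
        File to read.
    format
        ``"csv"`` or ``"json"``; inferred from the suffix when omitted.
    max_heavy
        Heavy-atom cap used for record validation.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"id": str, "fg_class": str})
        if "id" not in df.columns:
            raise ParseError(f"{path}: header lacks required 'id' column")
        if not any(c in ELEMENTS for c in df.columns):
            raise ParseError(f"{path}: header lacks element-count columns")
        rows = (row for _, row in df.iterrows())
        records = [
            _record_from_mapping(row.to_dict(), i, max_heavy)
            for i, row in enumerate(rows)
        ]
    elif fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            provenance = payload.get("provenance", "")
            items = payload["records"]
        else:
            provenance = ""
            items = payload
        records = [_record_from_mapping(obj, i, max_heavy) for i, obj in enumerate(items)]
        return PropertyDataset(records, provenance=provenance or str(path))
    else:
        raise ValueError(f"unknown format {fmt!r} (expected csv or json)")
    return PropertyDataset(records, provenance=str(path))


def _fmt(v) -> str:
    return "" if v is None else f"{v:.12g}"


def write_dataset(ds: PropertyDataset, path, format: str | None = None) -> None:
    """Write a dataset; ``read_dataset`` round-trips it field-for-field
    (floats to 12 significant digits)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    any_tensor = any(r.alpha_tensor is not None for r in ds)
    if fmt == "csv":
        cols = list(CANONICAL_COLUMNS) + (list(TENSOR_COMPONENTS) if any_tensor else [])
        lines = [",".join(cols)]
        for r in ds:
            row = [r.id]
            row += [str(r.count(s)) for s in ELEMENTS]
            row += [r.fg_class or "", _fmt(r.gap), _fmt(r.alpha)]
            if any_tensor:
                comps = (
                    tensor_components(r.alpha_tensor)
                    if r.alpha_tensor is not None
                    else (None,) * 6
                )
                row += [_fmt(c) for c in comps]
            lines.append(",".join(row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        items = []
        for r in ds:
            obj: dict = {"id": r.id}
            obj.update({s: r.count(s) for s in ELEMENTS if r.count(s)})
            if r.fg_class is not None:
                obj["fg_class"] = r.fg_class
            if r.gap is not None:
                obj["gap"] = float(f"{r.gap:.12g}")
            if r.alpha is not None:
                obj["alpha"] = float(f"{r.alpha:.12g}")
            if r.alpha_tensor is not None:
                for name, c in zip(TENSOR_COMPONENTS, tensor_components(r.alpha_tensor)):
                    obj[name] = float(f"{c:.12g}")
            items.append(obj)
        with open(path, "w") as fh:
            json.dump({"provenance": ds.provenance, "records": items}, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected csv or json)")


def composition_from_xyz(path) -> dict[str, int]:
    """Element counts from a standard XYZ file (coordinates discarded).

    The first line holds the atom count, the second is a comment, then one
    ``element x y z`` line per atom.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        declared = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: first line is not an atom count") from exc
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) != declared:
        raise FormatError(
            f"{path}: declares {declared} atoms but lists {len(atom_lines)}"
        )
    counts: dict[str, int] = {}
    for ln in atom_lines:
        fields = ln.split()
        if len(fields) < 4:
            raise FormatError(f"{path}: malformed atom line {ln!r}")
        sym = fields[0]
        if sym not in ELEMENTS:
            raise VocabularyError(
                f"{path}: element {sym!r} outside supported set {', '.join(ELEMENTS)}"
            )
        counts[sym] = counts.get(sym, 0) + 1
    return counts
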