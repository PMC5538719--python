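"""Brain atlas data model and I/O.

A brain atlas is an ordered list of regions — each with a short unique label,
a free-text name, and (x, y, z) coordinates in atlas space. The region order
fixes node identity for every connectivity matrix built from the atlas:
node index = position in the region list, labels in all user-facing output.

Three on-disk dialects are supported and round-trip exactly:

* ``txt`` — one region per line, tab- or comma-separated:
  ``label, name, x, y, z``; lines starting with ``#`` are comments.
* ``xlsx`` — a worksheet with a header row ``label, name, x, y, z``.
* ``xml`` — ``<atlas><region label=".." name=".." x=".." y=".." z=".."/></atlas>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

from .exceptions import ParseError, ValidationError

__all__ = ["RegionDef", "BrainAtlas", "load_atlas", "save_atlas"]

_COLUMNS = ("label", "name", "x", "y", "z")


@dataclass(frozen=True)
class RegionDef:
    """One brain region: short unique ``label``, descriptive ``name``, coordinates."""

    label: str
    name: str
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("region label must be non-empty")
        if len(self.coord) != 3 or not all(math.isfinite(c) for c in self.coord):
            raise ValidationError(
                f"region {self.label!r}: coordinates must be 3 finite numbers, got {self.coord!r}"
            )


@dataclass(frozen=True)
class BrainAtlas:
    """Ordered, immutable collection of :class:`RegionDef`.

    The order defines node indices for all matrices in an analysis.
    """

    regions: tuple[RegionDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) < 2:
            raise ValidationError("an atlas needs at least 2 regions")
        labels = [r.label for r in self.regions]
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise ValidationError(f"duplicate region label {lab!r} in atlas")
            seen.add(lab)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterable[RegionDef]:
        return iter(self.regions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.regions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    @property
    def coords(self) -> np.ndarray:
        """(R, 3) array of region coordinates, in atlas order."""
        return np.array([r.coord for r in self.regions], dtype=float)

    def index(self, label: str) -> int:
        for i, r in enumerate(self.regions):
            if r.label == label:
                return i
        raise KeyError(f"label {label!r} not in atlas")


def _parse_row(fields: Sequence[str], where: str) -> RegionDef:
    if len(fields) != 5:
        raise ParseError(f"{where}: expected 5 fields (label,name,x,y,z), got {len(fields)}")
    label, name = fields[0].strip(), fields[1].strip()
    try:
        coord = tuple(float(v) for v in fields[2:5])
    except ValueError as exc:
        raise ParseError(f"{where}: non-numeric coordinate ({exc})") from None
    return RegionDef(label=label, name=name, coord=coord)  # type: ignore[arg-type]


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".txt", ".csv", ".tsv"):
        return "txt"
    if suffix in (".xls", ".xlsx"):
        return "xlsx"
    if suffix == ".xml":
        return "xml"
    raise ValidationError(f"cannot infer atlas dialect from suffix {suffix!r}; pass dialect=")


def load_atlas(path: str | Path, dialect: str | None = None) -> BrainAtlas:
    """Load an atlas from ``path`` in the named dialect (txt | xlsx | xml).

    Regions keep file order; duplicate labels raise :class:`ValidationError`
    and malformed rows raise :class:`ParseError` naming the line or element.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "txt":
        regions = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            regions.append(_parse_row(line.split(sep), f"{path.name}:{lineno}"))
        return BrainAtlas(regions)
    if dialect in ("xls", "xlsx"):
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True)
        ws = wb.active
        rows = ws.iter_rows(values_only=True)
        header = next(rows, None)
        if header is None or tuple(str(h).strip().lower() for h in header[:5]) != _COLUMNS:
            raise ParseError(f"{path.name}: first row must be the header {','.join(_COLUMNS)}")
        regions = []
        for i, row in enumerate(rows, start=2):
            if row is None or all(v is None for v in row):
                continue
            regions.append(_parse_row([str(v) for v in row[:5]], f"{path.name}:row {i}"))
        wb.close()
        return BrainAtlas(regions)
    if dialect == "xml":
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"{path.name}: {exc}") from None
        root = tree.getroot()
        if root.tag != "atlas":
            raise ParseError(f"{path.name}: root element must be <atlas>, got <{root.tag}>")
        regions = []
        for i, el in enumerate(root.iter("region"), start=1):
            fields = [el.get(k) for k in _COLUMNS]
            if any(v is None for v in fields):
                missing = [k for k, v in zip(_COLUMNS, fields) if v is None]
                raise ParseError(f"{path.name}: <region> #{i} missing attributes {missing}")
            regions.append(_parse_row(fields, f"{path.name}: <region> #{i}"))
        return BrainAtlas(regions)
    raise ValidationError(f"unknown atlas dialect {dialect!r}")


def save_atlas(atlas: BrainAtlas, path: str | Path, dialect: str | None = None) -> Path:
    """Write ``atlas`` to ``path``; the same dialect loads it back identically."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "txt":
        lines = ["# label\tname\tx\ty\tz"]
        for r in atlas:
            lines.append(f"{r.label}\t{r.name}\t{r.coord[0]!r}\t{r.coord[1]!r}\t{r.coord[2]!r}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect in ("xls", "xlsx"):
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append(list(_COLUMNS))
        for r in atlas:
            ws.append([r.label, r.name, *r.coord])
        wb.save(path)
    elif dialect == "xml":
        root = etree.Element("atlas")
        for r in atlas:
            etree.SubElement(
                root,
                "region",
                label=r.label,
                name=r.name,
                x=repr(r.coord[0]),
                y=repr(r.coord[1]),
                z=repr(r.coord[2]),
            )
        etree.ElementTree(root).write(str(path), pretty_print=True, encoding="utf-8")
    else:
        raise ValidationError(f"unknown atlas dialect {dialect!r}")
    return path
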