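"""Indicator grading: map raw indicator values to the five sensitivity grades.

The grade system scores every indicator on the discrete index set
``{1, 3, 5, 7, 9}`` corresponding to the classes *insensitive*, *slightly*,
*moderately*, *highly* and *extremely sensitive*.  Numeric indicators carry
five ordered intervals (open-ended bins use infinite edges); categorical
indicators carry an explicit category-to-grade map.

Boundary convention: a raw value that falls on a shared interval edge is
assigned to the bin of *higher* sensitivity by default (``tie="higher"``),
a conservative choice for a protection-oriented assessment.  The direction
field (``benefit``: larger raw values mean more sensitive; ``cost``: larger
raw values mean less sensitive) is explicit metadata, never inferred from
bin order, because published grade tables are not always monotone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ContractError, GradingError, SchemaError

logger = logging.getLogger(__name__)

GRADE_INDICES: tuple[int, ...] = (1, 3, 5, 7, 9)
GRADE_LABELS: tuple[str, ...] = (
    "insensitive",
    "slightly sensitive",
    "moderately sensitive",
    "highly sensitive",
    "extremely sensitive",
)
LABEL_BY_INDEX: dict[int, str] = dict(zip(GRADE_INDICES, GRADE_LABELS))


@dataclass(frozen=True)
class IndicatorSpec:
    """One graded indicator: its position in the hierarchy and its bins.

    Parameters
    ----------
    id : str
        Unique short name, used as the column id of raw tables.
    layer : tuple of str
        Path of ancestor group ids (B-layer, then optional C-layer).
    kind : {"numeric", "categorical"}
    direction : {"benefit", "cost"} or None
        Whether larger raw values mean more (*benefit*) or less (*cost*)
        sensitive.  ``None`` is allowed for categorical indicators.
    intervals : tuple of (lo, hi) pairs, grade-aligned
        For numeric indicators: five intervals, one per grade in the order
        1, 3, 5, 7, 9.  Edges may be ``±inf``.
    categories : mapping of category -> grade index
    units : str
    flags : tuple of str
        Provenance/quality flags (e.g. transcription defects of a published
        table).  Flagged indicators are exempt from strict bin validation.
    """

    id: str
    layer: tuple[str, ...] = ()
    kind: str = "numeric"
    direction: str | None = None
    intervals: tuple[tuple[float, float], ...] = ()
    categories: Mapping[str, int] | None = None
    units: str = ""
    flags: tuple[str, ...] = ()

    def validate(self, strict: bool = True) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"indicator {self.id!r}: unknown kind {self.kind!r}")
        if self.direction not in ("benefit", "cost", None):
            raise SchemaError(f"indicator {self.id!r}: bad direction {self.direction!r}")
        if self.kind == "numeric":
            if self.direction is None:
                raise SchemaError(f"indicator {self.id!r}: numeric indicator needs a direction")
            if len(self.intervals) != 5:
                raise SchemaError(
                    f"indicator {self.id!r}: expected 5 grade bins, got {len(self.intervals)}"
                )
            for lo, hi in self.intervals:
                if not lo < hi:
                    raise SchemaError(
                        f"indicator {self.id!r}: degenerate interval ({lo}, {hi})"
                    )
            if strict and not self.flags:
                self._check_tiling()
        else:
            if not self.categories:
                raise SchemaError(f"indicator {self.id!r}: categorical map is empty")
            for cat, g in self.categories.items():
                if g not in GRADE_INDICES:
                    raise SchemaError(
                        f"indicator {self.id!r}: category {cat!r} mapped to invalid grade {g}"
                    )

    def _check_tiling(self) -> None:
        """Strict mode: the five intervals must tile the domain edge-to-edge."""
        ivals = self.intervals
        ascending = ivals[0][0] <= ivals[-1][0]
        ordered = ivals if ascending else tuple(reversed(ivals))
        for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
            if not math.isclose(hi1, lo2, rel_tol=0, abs_tol=0) and hi1 != lo2:
                kind = "gapped" if hi1 < lo2 else "overlapping"
                raise SchemaError(
                    f"indicator {self.id!r}: {kind} numeric intervals "
                    f"({lo1}, {hi1}) / ({lo2}, {hi2})"
                )

    # -- grading ---------------------------------------------------------

    def grade(self, raw, tie: str = "higher") -> int:
        """Return the grade index in {1,3,5,7,9} for one raw value."""
        if tie not in ("higher", "lower"):
            raise ContractError(f"tie must be 'higher' or 'lower', got {tie!r}")
        if self.kind == "categorical":
            try:
                return int(self.categories[raw])  # type: ignore[index]
            except (KeyError, TypeError):
                raise GradingError(
                    f"indicator {self.id!r}: unknown category {raw!r}"
                ) from None
        try:
            x = float(raw)
        except (TypeError, ValueError):
            raise GradingError(
                f"indicator {self.id!r}: non-numeric raw value {raw!r}"
            ) from None
        if math.isnan(x):
            raise GradingError(f"indicator {self.id!r}: NaN raw value")
        hits = [
            g for g, (lo, hi) in zip(GRADE_INDICES, self.intervals) if lo <= x <= hi
        ]
        if not hits:
            # A value inside the domain hull but between bins can only occur
            # for as-printed rows with gapped intervals; snap to the nearest
            # bin.  Values outside the hull are out of domain.
            hull_lo = min(lo for lo, _ in self.intervals)
            hull_hi = max(hi for _, hi in self.intervals)
            if not hull_lo <= x <= hull_hi:
                raise GradingError(
                    f"indicator {self.id!r}: value {x} outside the declared domain"
                )
            dists = [
                (max(lo - x, x - hi, 0.0), g)
                for g, (lo, hi) in zip(GRADE_INDICES, self.intervals)
            ]
            dmin = min(d for d, _ in dists)
            hits = [g for d, g in dists if d <= dmin + 1e-12]
        return max(hits) if tie == "higher" else min(hits)

    def domain_contains(self, raw) -> bool:
        if self.kind == "categorical":
            return raw in (self.categories or {})
        try:
            x = float(raw)
        except (TypeError, ValueError):
            return False
        return any(lo <= x <= hi for lo, hi in self.intervals)


@dataclass
class GradingScheme:
    """An ordered collection of :class:`IndicatorSpec` plus the grade indices."""

    indicators: tuple[IndicatorSpec, ...]
    grade_indices: tuple[int, ...] = GRADE_INDICES
    name: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.indicators = tuple(self.indicators)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.indicators)

    def __getitem__(self, indicator_id: str) -> IndicatorSpec:
        for s in self.indicators:
            if s.id == indicator_id:
                return s
        raise KeyError(indicator_id)

    def __len__(self) -> int:
        return len(self.indicators)

    def validate(self, strict: bool = True) -> None:
        if tuple(self.grade_indices) != GRADE_INDICES:
            raise SchemaError(
                f"grade_indices must be {GRADE_INDICES}, got {self.grade_indices}"
            )
        ids = self.ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate indicator ids: {dupes}")
        for spec in self.indicators:
            spec.validate(strict=strict)

    def groups(self, level: int = 0) -> dict[str, tuple[str, ...]]:
        """Indicator ids grouped by their ancestor at ``level`` in the layer path."""
        out: dict[str, list[str]] = {}
        for s in self.indicators:
            key = s.layer[level] if len(s.layer) > level else s.id
            out.setdefault(key, []).append(s.id)
        return {k: tuple(v) for k, v in out.items()}

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GradingScheme":
        specs = []
        for item in doc.get("indicators", []):
            intervals = tuple(
                (float(lo), float(hi)) for lo, hi in item.get("intervals", [])
            )
            specs.append(
                IndicatorSpec(
                    id=str(item["id"]),
                    layer=tuple(item.get("layer", [])),
                    kind=item.get("kind", "numeric"),
                    direction=item.get("direction"),
                    intervals=intervals,
                    categories=dict(item["categories"]) if item.get("categories") else None,
                    units=item.get("units", ""),
                    flags=tuple(item.get("flags", [])),
                )
            )
        return cls(
            indicators=tuple(specs),
            grade_indices=tuple(doc.get("grade_indices", GRADE_INDICES)),
            name=doc.get("name", ""),
            flags=tuple(doc.get("flags", [])),
        )

    def to_dict(self) -> dict:
        items = []
        for s in self.indicators:
            d: dict = {"id": s.id, "kind": s.kind}
            if s.layer:
                d["layer"] = list(s.layer)
            if s.direction:
                d["direction"] = s.direction
            if s.kind == "numeric":
                d["intervals"] = [[lo, hi] for lo, hi in s.intervals]
            else:
                d["categories"] = dict(s.categories or {})
            if s.units:
                d["units"] = s.units
            if s.flags:
                d["flags"] = list(s.flags)
            items.append(d)
        return {
            "name": self.name,
            "grade_indices": list(self.grade_indices),
            "indicators": items,
            "flags": list(self.flags),
        }


def load_scheme(path, strict: bool = True) -> GradingScheme:
    """Load and validate a grading scheme from a YAML/JSON config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: scheme config must be a mapping")
    scheme = GradingScheme.from_dict(doc)
    scheme.validate(strict=strict)
    return scheme


def grade_value(spec: IndicatorSpec, raw, tie: str = "higher") -> int:
    """Grade one raw value against one indicator. See :meth:`IndicatorSpec.grade`."""
    return spec.grade(raw, tie=tie)


def grade_table(
    scheme: GradingScheme,
    raw_table: pd.DataFrame,
    tie: str = "higher",
    missing: str = "propagate",
) -> pd.DataFrame:
    """Grade a units x indicators raw-value table.

    The table's columns (after setting aside a ``unit_id`` column, if present,
    as the index) must exactly match the scheme's indicator ids.  Missing raw
    values propagate as missing (NaN) with a logged count; downstream
    synthesis decides whether they are errors.
    """
    df = raw_table
    if "unit_id" in df.columns:
        df = df.set_index("unit_id")
    extra = [c for c in df.columns if c not in scheme.ids]
    absent = [c for c in scheme.ids if c not in df.columns]
    if extra or absent:
        raise ContractError(
            f"raw table columns do not match scheme indicators "
            f"(unknown: {extra}, missing: {absent})"
        )
    out = pd.DataFrame(index=df.index, columns=list(scheme.ids), dtype=float)
    n_missing = 0
    for spec in scheme.indicators:
        col = df[spec.id]
        graded = []
        for v in col:
            if v is None or (isinstance(v, float) and math.isnan(v)):
                n_missing += 1
                graded.append(float("nan"))
            else:
                graded.append(float(spec.grade(v, tie=tie)))
        out[spec.id] = graded
    if n_missing:
        if missing == "error":
            raise GradingError(f"{n_missing} missing raw values with missing='error'")
        logger.info("grade_table: %d missing raw values propagated", n_missing)
    return out
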