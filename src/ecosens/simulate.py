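"""Synthetic evaluation units: gridded polygons with controllable raw values.

The generator emulates the data shape the evaluation assumes — polygonal
units with one raw value per leaf indicator — without recreating any real
study area.  Units are squares on a regular grid (exact analytic areas make
overlay arithmetic assertable).  Each unit is assigned a target sensitivity
class per B-layer (drawn from a configurable mixture); every leaf indicator
then receives a raw value drawn uniformly inside the bin of that class,
optionally perturbed by Gaussian noise of ``sigma`` bin-widths and leaked
one bin away with probability ``eps``.  With ``sigma = eps = 0`` grading
recovers the assigned class for every indicator by construction.

Open-ended bins (``≥ x`` / ``≤ x``) get a finite sampling surrogate edge:
the boundary extended by the width of the nearest finite bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import ContractError
from .grading import GRADE_INDICES, GradingScheme, IndicatorSpec
from .overlay import FactorLayer


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shape parameters for the unit generator.

    rows, cols : grid layout; ``rows * cols`` units are generated.
    cell_size : square edge in meters (default 1000 m, i.e. 100 hm² units).
    mixture : proportions over the five classes (insensitive .. extremely),
        shared by all B-layers (one class draw per unit), or a mapping of
        B-layer id -> mixture for independent per-layer draws.
    sigma : within-bin Gaussian noise, as a fraction of the bin width.
    eps : probability that a value lands one bin away from its target.
    seed : RNG seed; a fixed seed yields byte-identical artifacts.
    """

    rows: int = 10
    cols: int = 10
    cell_size: float = 1000.0
    mixture: Sequence[float] | Mapping[str, Sequence[float]] = (0.2, 0.2, 0.2, 0.2, 0.2)
    sigma: float = 0.0
    eps: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ContractError("grid must have at least one cell")
        if self.cell_size <= 0:
            raise ContractError("cell_size must be positive")
        if self.sigma < 0:
            raise ContractError("sigma must be >= 0")
        if not 0 <= self.eps < 0.5:
            raise ContractError("eps must lie in [0, 0.5)")
        mixes = (
            self.mixture.values() if isinstance(self.mixture, Mapping) else [self.mixture]
        )
        for m in mixes:
            if len(m) != 5:
                raise ContractError("mixture needs 5 class proportions")
            if any(p < 0 for p in m) or abs(sum(m) - 1.0) > 1e-9:
                raise ContractError("mixture proportions must be nonnegative and sum to 1")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


@dataclass
class SimulatedData:
    layer: FactorLayer
    raw: pd.DataFrame
    assignments: pd.DataFrame
    config: SimulationConfig


def _finite_interval(spec: IndicatorSpec, grade: int) -> tuple[float, float]:
    """The sampling interval for a grade, with surrogate edges for ±inf."""
    pos = GRADE_INDICES.index(grade)
    lo, hi = spec.intervals[pos]
    if math.isinf(lo) and math.isinf(hi):
        return (0.0, 1.0)
    finite_widths = [
        h - l for l, h in spec.intervals if not math.isinf(l) and not math.isinf(h)
    ]
    surrogate = finite_widths[0] if finite_widths else 1.0
    # prefer the width of the axis-adjacent finite bin
    if math.isinf(lo):
        adjacent = [(l, h) for l, h in spec.intervals if not math.isinf(l) and l >= hi - 1e-12]
        if adjacent:
            l, h = min(adjacent)
            if not math.isinf(h):
                surrogate = h - l
        lo = hi - surrogate
    elif math.isinf(hi):
        adjacent = [(l, h) for l, h in spec.intervals if not math.isinf(h) and h <= lo + 1e-12]
        if adjacent:
            l, h = max(adjacent)
            if not math.isinf(l):
                surrogate = h - l
        hi = lo + surrogate
    return (float(lo), float(hi))


def _domain_hull(spec: IndicatorSpec) -> tuple[float, float]:
    los = [min(_finite_interval(spec, g)) for g in GRADE_INDICES]
    his = [max(_finite_interval(spec, g)) for g in GRADE_INDICES]
    return (min(los), max(his))


def _leak(pos: int, eps: float, rng: np.random.Generator) -> int:
    if eps > 0 and rng.random() < eps:
        step = 1 if rng.random() < 0.5 else -1
        if pos == 0:
            step = 1
        elif pos == 4:
            step = -1
        return pos + step
    return pos


def _sample_value(spec: IndicatorSpec, grade: int, cfg: SimulationConfig, rng) -> object:
    pos = _leak(GRADE_INDICES.index(grade), cfg.eps, rng)
    g = GRADE_INDICES[pos]
    if spec.kind == "categorical":
        cats = sorted(c for c, gi in (spec.categories or {}).items() if gi == g)
        if not cats:
            # garbled source rows may lack a category for some grade; use nearest
            by_dist = sorted(
                (spec.categories or {}).items(), key=lambda kv: (abs(kv[1] - g), kv[0])
            )
            cats = [by_dist[0][0]]
        return cats[int(rng.integers(len(cats)))]
    lo, hi = _finite_interval(spec, g)
    v = rng.uniform(lo, hi)
    # as-printed rows may have bins overlapping a more sensitive class, where
    # the tie rule would re-grade part of the bin; rejection-sample so the
    # noise-free draw always grades back to its target
    for _ in range(50):
        if spec.grade(v) == g:
            break
        v = rng.uniform(lo, hi)
    if cfg.sigma > 0:
        v += rng.normal(0.0, cfg.sigma * (hi - lo))
        dlo, dhi = _domain_hull(spec)
        v = min(max(v, dlo), dhi)
    return float(v)


def generate_units(config: SimulationConfig, scheme: GradingScheme) -> SimulatedData:
    """Generate grid polygons plus a raw indicator table under ``config``.

    Returns the polygon layer (meter units; cell areas are exact), the
    units x indicators raw table, and the per-unit class assignments
    (one column per B-layer, plus ``unit_class`` when a single shared
    mixture is used).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    ids = [f"u{i + 1:05d}" for i in range(n)]

    geoms = []
    for r in range(config.rows):
        for c in range(config.cols):
            x0, y0 = c * config.cell_size, r * config.cell_size
            geoms.append(box(x0, y0, x0 + config.cell_size, y0 + config.cell_size))

    blayers = sorted(scheme.groups(level=0))
    classes = np.asarray(GRADE_INDICES)
    assign = pd.DataFrame(index=pd.Index(ids, name="unit_id"))
    if isinstance(config.mixture, Mapping):
        unknown = set(config.mixture) - set(blayers)
        if unknown:
            raise ContractError(f"mixture names unknown B-layers: {sorted(unknown)}")
        for b in blayers:
            mix = config.mixture.get(b, (0.2, 0.2, 0.2, 0.2, 0.2))
            assign[b] = rng.choice(classes, size=n, p=np.asarray(mix, dtype=float))
    else:
        shared = rng.choice(classes, size=n, p=np.asarray(config.mixture, dtype=float))
        assign["unit_class"] = shared
        for b in blayers:
            assign[b] = shared

    raw = pd.DataFrame(index=assign.index, columns=list(scheme.ids), dtype=object)
    for spec in scheme.indicators:
        b = spec.layer[0] if spec.layer else spec.id
        targets = assign[b] if b in assign.columns else assign.iloc[:, 0]
        raw[spec.id] = [
            _sample_value(spec, int(t), config, rng) for t in targets
        ]

    layer = FactorLayer(
        frame=pd.DataFrame({"unit_id": ids, "geometry": geoms}),
        name="units",
        crs="local-m",
        crs_units="m",
    )
    return SimulatedData(layer=layer, raw=raw, assignments=assign, config=config)


def buffer_rings(
    geometry, distances: Sequence[float], crs: str = "local-m"
) -> FactorLayer:
    """Disjoint distance rings (0, d1], (d1, d2], ... around a geometry.

    ``geometry`` may be a shapely geometry or a :class:`FactorLayer` (its
    features are unioned first).  Distances are strictly increasing meters.
    """
    if list(distances) != sorted(set(distances)) or any(d <= 0 for d in distances):
        raise ContractError("distances must be strictly increasing and positive")
    if isinstance(geometry, FactorLayer):
        from shapely.ops import unary_union

        geometry = unary_union(list(geometry.geometries)) if len(geometry.frame) else None
    if geometry is None or geometry.is_empty:
        return FactorLayer(
            frame=pd.DataFrame({"ring": [], "distance_m": [], "geometry": []}),
            name="rings",
            crs=crs,
            crs_units="m",
        )
    rows = []
    prev = geometry
    lo = 0.0
    for k, d in enumerate(distances):
        outer = geometry.buffer(d)
        ring = outer.difference(prev)
        rows.append({"ring": k, "distance_m": float(d), "label": f"{lo:g}-{d:g}m", "geometry": ring})
        prev = outer
        lo = float(d)
    return FactorLayer(frame=pd.DataFrame(rows), name="rings", crs=crs, crs_units="m")
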