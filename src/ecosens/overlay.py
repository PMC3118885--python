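"""Vector overlay on evaluation units: intersect, dissolve, measure.

Factor layers are polygon coverages carrying one grade attribute per
evaluation unit.  Overlay intersects two or more layers pairwise so every
output polygon carries the grade of each contributing layer (plus the
provenance of the contributing unit ids); dissolve merges touching polygons
of equal class, conserving per-class area; areas are planar, reported in
hectares (1 hm² = 10⁴ m²), and therefore require a projected CRS with
linear units — geographic (degree) layers are rejected rather than
silently measured in square degrees.

I/O is GeoJSON (read and written as plain JSON, geometries via shapely).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ContractError, CRSError

logger = logging.getLogger(__name__)

_GEOGRAPHIC_CRS = {"EPSG:4326", "WGS84", "CRS84", "OGC:CRS84", "urn:ogc:def:crs:OGC:1.3:CRS84"}


@dataclass
class FactorLayer:
    """A polygon layer: a frame with a shapely ``geometry`` column plus CRS metadata.

    ``crs`` is a free descriptor (e.g. "EPSG:32649" or "local-m");
    ``crs_units`` declares the linear unit ("m") or "degree" for geographic.
    """

    frame: pd.DataFrame
    name: str = "layer"
    crs: str = "local-m"
    crs_units: str = "m"

    def __post_init__(self) -> None:
        if "geometry" not in self.frame.columns:
            raise ContractError(f"layer {self.name!r}: no geometry column")

    @property
    def geometries(self) -> pd.Series:
        return self.frame["geometry"]

    def total_area(self) -> float:
        return float(sum(g.area for g in self.geometries))

    def repaired(self) -> "FactorLayer":
        """Zero-width-buffer repair; unrepairable features dropped and logged."""
        rows = []
        dropped = []
        for i, row in self.frame.iterrows():
            g = row["geometry"]
            if not g.is_valid:
                g = g.buffer(0)
            if g.is_empty or not g.is_valid:
                dropped.append(i)
                continue
            r = dict(row)
            r["geometry"] = g
            rows.append(r)
        if dropped:
            logger.warning("layer %s: dropped unrepairable features %s", self.name, dropped)
        return FactorLayer(
            frame=pd.DataFrame(rows), name=self.name, crs=self.crs, crs_units=self.crs_units
        )

    # -- GeoJSON ---------------------------------------------------------

    @classmethod
    def from_geojson(cls, path, name: str | None = None) -> "FactorLayer":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise ContractError(f"{path}: expected a GeoJSON FeatureCollection")
        rows = []
        for feat in doc.get("features", []):
            props = dict(feat.get("properties") or {})
            props["geometry"] = shape(feat["geometry"])
            rows.append(props)
        meta = doc.get("metadata", {})
        return cls(
            frame=pd.DataFrame(rows),
            name=name or meta.get("name", "layer"),
            crs=meta.get("crs", "local-m"),
            crs_units=meta.get("crs_units", "m"),
        )

    def to_geojson(self, path) -> None:
        feats = []
        for _, row in self.frame.iterrows():
            props = {k: v for k, v in row.items() if k != "geometry"}
            feats.append(
                {"type": "Feature", "properties": props, "geometry": mapping(row["geometry"])}
            )
        doc = {
            "type": "FeatureCollection",
            "metadata": {"name": self.name, "crs": self.crs, "crs_units": self.crs_units},
            "features": feats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _polygonal(geom: BaseGeometry) -> BaseGeometry | None:
    """Keep only the polygonal part of an intersection result."""
    if geom.is_empty:
        return None
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if not polys:
            return None
        return unary_union(polys)
    return None


def _pairwise(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    from shapely.strtree import STRtree

    geoms_b = list(b["geometry"])
    tree = STRtree(geoms_b)
    rows = []
    for _, ra in a.iterrows():
        ga = ra["geometry"]
        for j in tree.query(ga):
            gb = geoms_b[int(j)]
            inter = _polygonal(ga.intersection(gb))
            if inter is None or inter.area == 0:
                continue
            rb = b.iloc[int(j)]
            merged = {k: v for k, v in ra.items() if k != "geometry"}
            merged.update({k: v for k, v in rb.items() if k != "geometry"})
            merged["geometry"] = inter
            rows.append(merged)
    return pd.DataFrame(rows)


def overlay_layers(
    layers: list[FactorLayer],
    sliver_frac: float = 1e-4,
    repair: bool = True,
) -> FactorLayer:
    """Intersect two or more factor layers into a single attributed coverage.

    Every output polygon carries, for each input layer *L*, the attributes
    of the contributing feature prefixed ``L:`` (so its grade and unit id
    travel along).  Slivers smaller than ``sliver_frac`` times the mean
    input polygon area are merged into their largest neighbor.
    """
    if len(layers) < 2:
        raise ContractError("overlay needs at least 2 layers")
    units = {l.crs_units for l in layers}
    crss = {l.crs for l in layers}
    if "degree" in units:
        raise CRSError("overlay requires planar layers; reproject degree-unit layers first")
    if len(crss) > 1:
        raise CRSError(f"layers use mixed CRS {sorted(crss)}; reproject to a common CRS first")

    prepared = []
    mean_area = 0.0
    n_feats = 0
    for l in layers:
        if repair:
            l = l.repaired()
        df = l.frame.rename(
            columns={c: f"{l.name}:{c}" for c in l.frame.columns if c != "geometry"}
        )
        prepared.append(df)
        n_feats += len(df)
        mean_area += sum(g.area for g in df["geometry"])
    mean_area = mean_area / max(n_feats, 1)

    result = prepared[0]
    for nxt in prepared[1:]:
        result = _pairwise(result, nxt)
        if result.empty:
            logger.warning("overlay: empty intersection")
            break

    out = FactorLayer(
        frame=result if not result.empty else pd.DataFrame({"geometry": []}),
        name="+".join(l.name for l in layers),
        crs=layers[0].crs,
        crs_units=layers[0].crs_units,
    )
    if not result.empty and sliver_frac > 0:
        out = _merge_slivers(out, sliver_frac * mean_area)
    return out


def _merge_slivers(layer: FactorLayer, threshold: float) -> FactorLayer:
    df = layer.frame.reset_index(drop=True)
    small = [i for i in df.index if df.at[i, "geometry"].area < threshold]
    if not small:
        return layer
    keep = [i for i in df.index if i not in set(small)]
    merged_into: dict[int, list] = {i: [] for i in keep}
    orphans = []
    for i in small:
        g = df.at[i, "geometry"]
        # largest neighbor by shared boundary length, falling back to area
        best, best_score = None, (-1.0, -1.0)
        for j in keep:
            gj = df.at[j, "geometry"]
            if g.touches(gj) or g.intersects(gj):
                shared = g.boundary.intersection(gj.boundary).length
                score = (shared, gj.area)
                if best is None or score > best_score:
                    best, best_score = j, score
        if best is None:
            orphans.append(i)
        else:
            merged_into[best].append(g)
    rows = []
    for j in keep:
        r = dict(df.loc[j])
        if merged_into[j]:
            r["geometry"] = unary_union([r["geometry"], *merged_into[j]])
        rows.append(r)
    for i in orphans:  # isolated slivers are kept rather than deleted
        rows.append(dict(df.loc[i]))
    return FactorLayer(
        frame=pd.DataFrame(rows), name=layer.name, crs=layer.crs, crs_units=layer.crs_units
    )


def dissolve_by_class(layer: FactorLayer, by: str = "class_index") -> FactorLayer:
    """Merge touching polygons of equal class; per-class area is conserved.

    Disjoint same-class polygons become a single multipart feature.
    """
    if by not in layer.frame.columns:
        raise ContractError(f"dissolve: attribute {by!r} not present")
    rows = []
    for value, group in layer.frame.groupby(by, sort=True):
        rows.append({by: value, "geometry": unary_union(list(group["geometry"]))})
    return FactorLayer(
        frame=pd.DataFrame(rows),
        name=f"{layer.name}|dissolved",
        crs=layer.crs,
        crs_units=layer.crs_units,
    )


def compute_areas(layer: FactorLayer, unit: str = "hm2") -> pd.Series:
    """Planar per-feature areas; ``hm2`` (default) or ``m2``."""
    if layer.crs_units == "degree" or layer.crs.upper() in _GEOGRAPHIC_CRS:
        raise CRSError(
            f"layer {layer.name!r} is in a geographic CRS ({layer.crs}); "
            "reproject to a planar CRS with meter units before measuring areas"
        )
    if layer.crs_units != "m":
        raise CRSError(f"unsupported linear unit {layer.crs_units!r}")
    m2 = pd.Series([g.area for g in layer.geometries], index=layer.frame.index, name="area")
    if unit == "m2":
        return m2
    if unit == "hm2":
        return m2 / 1e4
    raise ContractError(f"unit must be 'hm2' or 'm2', got {unit!r}")


def area_by_attribute(layer: FactorLayer, columns: list[str]) -> pd.DataFrame:
    """Total area (hm²) per combination of attribute values (sorted, canonical)."""
    df = layer.frame.copy()
    df["__area"] = compute_areas(layer)
    out = df.groupby(columns, sort=True)["__area"].sum().reset_index()
    return out.rename(columns={"__area": "area_hm2"})
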