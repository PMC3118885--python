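import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import ecosens as es
from ecosens.errors import ContractError, CRSError


def _layer(features, name, **kw):
    return es.FactorLayer(frame=pd.DataFrame(features), name=name, **kw)


def _square_layer(name, grade, x0=0, y0=0, size=1000):
    return _layer(
        [{"unit_id": f"{name}-1", "grade": grade, "geometry": box(x0, y0, x0 + size, y0 + size)}],
        name,
    )


class TestOverlay:
    def test_identity_overlay_carries_both_grades(self):
        out = es.overlay_layers([_square_layer("A", 3), _square_layer("B", 5)])
        assert len(out.frame) == 1
        row = out.frame.iloc[0]
        assert row["A:grade"] == 3 and row["B:grade"] == 5
        assert row["geometry"].area == pytest.approx(1000 * 1000)

    def test_half_overlap_intersection_area(self):
        a = _square_layer("A", 3)
        b = _square_layer("B", 5, x0=500)
        out = es.overlay_layers([a, b])
        assert out.total_area() == pytest.approx(0.5 * 1000 * 1000)

    def test_commutativity_of_area_by_attribute(self, rng):
        layers = _checkerboard_layers(rng, n_layers=2, n=4)
        ab = es.overlay_layers([layers[0], layers[1]])
        ba = es.overlay_layers([layers[1], layers[0]])
        cols = ["L0:grade", "L1:grade"]
        t1 = es.area_by_attribute(ab, cols).sort_values(cols).reset_index(drop=True)
        t2 = es.area_by_attribute(ba, cols).sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)

    def test_checkerboard_matches_bruteforce_all_pairs(self, rng):
        """Oracle: quadratic all-pairs intersection, no spatial index."""
        layers = _checkerboard_layers(rng, n_layers=4, n=3)
        out = es.overlay_layers(layers, sliver_frac=0.0)
        cols = [f"L{k}:grade" for k in range(4)]
        got = es.area_by_attribute(out, cols).set_index(cols)["area_hm2"]

        acc = {}
        frames = [l.frame for l in layers]
        for rows in itertools.product(*(f.iterrows() for f in frames)):
            geoms = [r[1]["geometry"] for r in rows]
            inter = geoms[0]
            for g in geoms[1:]:
                inter = inter.intersection(g)
            if inter.is_empty or inter.area == 0:
                continue
            key = tuple(r[1]["grade"] for r in rows)
            acc[key] = acc.get(key, 0.0) + inter.area / 1e4
        assert set(got.index) == set(acc)
        for key, area in acc.items():
            assert got[key] == pytest.approx(area, rel=1e-9)

    def test_mixed_crs_rejected(self):
        a = _square_layer("A", 1)
        b = _square_layer("B", 1)
        b.crs = "EPSG:32650"
        with pytest.raises(CRSError):
            es.overlay_layers([a, b])

    def test_empty_intersection_yields_empty_result(self):
        a = _square_layer("A", 1)
        b = _square_layer("B", 1, x0=10_000)
        out = es.overlay_layers([a, b])
        assert len(out.frame) == 0

    def test_single_layer_rejected(self):
        with pytest.raises(ContractError):
            es.overlay_layers([_square_layer("A", 1)])

    def test_no_overlapping_output_polygons(self, rng):
        layers = _checkerboard_layers(rng, n_layers=2, n=3)
        out = es.overlay_layers([layers[0], layers[1]])
        geoms = list(out.frame["geometry"])
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert geoms[i].intersection(geoms[j]).area == pytest.approx(0.0, abs=1e-6)


class TestDissolve:
    def test_adjacent_same_class_merge_to_one_polygon(self):
        lay = _layer(
            [
                {"class_index": 5, "geometry": box(0, 0, 1000, 1000)},
                {"class_index": 5, "geometry": box(1000, 0, 2000, 1000)},
            ],
            "m",
        )
        out = es.dissolve_by_class(lay)
        assert len(out.frame) == 1
        g = out.frame["geometry"].iloc[0]
        assert g.geom_type == "Polygon"
        assert g.area == pytest.approx(2_000_000)

    def test_disjoint_same_class_become_multipart(self):
        lay = _layer(
            [
                {"class_index": 7, "geometry": box(0, 0, 10, 10)},
                {"class_index": 7, "geometry": box(100, 0, 110, 10)},
            ],
            "m",
        )
        out = es.dissolve_by_class(lay)
        g = out.frame["geometry"].iloc[0]
        assert g.geom_type == "MultiPolygon"
        assert g.area == pytest.approx(200)

    def test_per_class_area_conserved_on_random_map(self, rng):
        layers = _checkerboard_layers(rng, n_layers=2, n=4)
        ov = es.overlay_layers([layers[0], layers[1]])
        ov.frame["class_index"] = ov.frame["L0:grade"]
        before = ov.frame.groupby("class_index")["geometry"].apply(
            lambda gs: sum(g.area for g in gs)
        )
        after = es.dissolve_by_class(ov)
        got = after.frame.set_index("class_index")["geometry"].apply(lambda g: g.area)
        for k in before.index:
            assert got[k] == pytest.approx(before[k], rel=1e-6)


class TestAreas:
    def test_hundred_meter_square_is_one_hectare(self):
        lay = _layer([{"geometry": box(0, 0, 100, 100)}], "sq")
        assert es.compute_areas(lay).iloc[0] == pytest.approx(1.0)

    def test_kilometer_square_is_hundred_hectares(self):
        lay = _layer([{"geometry": box(0, 0, 1000, 1000)}], "sq")
        assert es.compute_areas(lay).iloc[0] == pytest.approx(100.0)

    def test_geographic_crs_rejected_with_reprojection_hint(self):
        lay = _layer([{"geometry": box(0, 0, 1, 1)}], "geo", crs="EPSG:4326", crs_units="degree")
        with pytest.raises(CRSError, match="[Rr]eproject"):
            es.compute_areas(lay)

    def test_study_area_total_in_hectares(self):
        meta = es.load_fixture("study_area")
        assert meta["total_area_km2"] * 100 == meta["total_area_hm2"] == 204500


class TestGeoJSONRoundtrip:
    def test_roundtrip_preserves_attributes_and_area(self, tmp_path):
        lay = _layer(
            [{"unit_id": "u1", "grade": 7, "geometry": box(0, 0, 300, 200)}], "rt"
        )
        p = tmp_path / "layer.geojson"
        lay.to_geojson(p)
        back = es.FactorLayer.from_geojson(p)
        assert back.name == "rt" and back.crs_units == "m"
        assert back.frame["grade"].iloc[0] == 7
        assert back.frame["geometry"].iloc[0].area == pytest.approx(60_000)


def _checkerboard_layers(rng, n_layers=2, n=4, cell=500.0):
    """Layers of n x n cells with random grades; cells offset per layer so
    overlay produces genuine intersections."""
    layers = []
    for k in range(n_layers):
        off = k * cell / (n_layers + 1)
        feats = []
        for r in range(n):
            for c in range(n):
                feats.append(
                    {
                        "unit_id": f"L{k}-{r}-{c}",
                        "grade": int(rng.choice([1, 3, 5, 7, 9])),
                        "geometry": box(
                            c * cell + off, r * cell + off,
                            (c + 1) * cell + off, (r + 1) * cell + off,
                        ),
                    }
                )
        layers.append(_layer(feats, f"L{k}"))
    return layers
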