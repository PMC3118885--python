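"""Packaged fixtures: the published grade system, weight hierarchy and
area tables of the Yicheng City case study, transcribed as printed.

Transcription defects in the source (misaligned weight rows, non-monotone
bins, groups not summing to 1) are preserved and flagged, never silently
repaired; see each fixture's ``flags`` / ``conflicts`` metadata.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .grading import GradingScheme
from .weights import WeightTree

_TABLES = ("table2", "table3", "table4", "table6")


def _data_path(name: str):
    return resources.files("ecosens.data").joinpath(name)


def load_table1_scheme(strict: bool = False) -> GradingScheme:
    """The 40-indicator grade system (4 B-layer groups).

    Loaded with ``strict=False`` by default: several printed rows are
    gapped, overlapping or non-monotone and are flagged as such.
    """
    with _data_path("table1_scheme.yaml").open() as fh:
        scheme = GradingScheme.from_dict(yaml.safe_load(fh))
    scheme.validate(strict=strict)
    return scheme


def load_table5_tree() -> WeightTree:
    """The expert weight hierarchy, as printed (non-normalized groups flagged)."""
    with _data_path("table5_weights.yaml").open() as fh:
        tree = WeightTree.from_dict(yaml.safe_load(fh))
    tree.validate(strict=True)  # flagged nodes are reported, not raised
    return tree


def load_printed_areas(table: str) -> pd.DataFrame:
    """Per-class printed areas (hm²) and proportions for one results table."""
    if table not in _TABLES:
        raise KeyError(f"unknown area table {table!r}; known: {_TABLES}")
    with _data_path("printed_areas.csv").open() as fh:
        df = pd.read_csv(fh)
    out = df[df["table"] == table].drop(columns=["table"]).reset_index(drop=True)
    return out


def load_study_area() -> dict:
    with _data_path("study_area.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_fixture(name: str):
    """Uniform lookup over all shipped fixtures.

    Known names: ``table1`` (grading scheme), ``table5`` (weight tree),
    ``table5_Blayer`` (B-layer weight dict), ``table2``/``table3``/
    ``table4``/``table6`` (area tables), ``study_area`` (metadata dict).
    """
    if name == "table1":
        return load_table1_scheme()
    if name == "table5":
        return load_table5_tree()
    if name == "table5_Blayer":
        tree = load_table5_tree()
        return {c.id: c.weight for c in tree.root.children}
    if name in _TABLES:
        return load_printed_areas(name)
    if name == "study_area":
        return load_study_area()
    raise KeyError(
        f"unknown fixture {name!r}; known: table1, table5, table5_Blayer, "
        f"{', '.join(_TABLES)}, study_area"
    )
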