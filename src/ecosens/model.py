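"""Model/Results facade over the evaluation pipeline.

:class:`SensitivityModel` is built from a raw units x indicators table plus
a grading scheme; :meth:`SensitivityModel.fit` grades the table, resolves
the weight hierarchy (fixed from config, or entropy-derived from the graded
data), aggregates the composite sensitivity index up the hierarchy,
classifies every unit into the five sensitivity classes, and scores each
unit's fuzzy matter-element approach degree toward the ideal (most
sensitive) reference.  The returned :class:`SensitivityResults` carries the
estimates and exposes ``summary()``, ``rank()`` and ``area_summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import fme
from .errors import ContractError
from .grading import GradingScheme, grade_table
from .synthesis import DEFAULT_CLASSES, area_summary, classify, composite_index
from .weights import WeightTree, build_weight_tree


def _topology_from_scheme(scheme: GradingScheme, root_id: str = "eco_sensitivity") -> dict:
    """Nested node config mirroring the scheme's B/C layer paths."""
    root: dict = {"id": root_id, "children": []}

    def ensure_child(node: dict, cid: str) -> dict:
        for c in node["children"]:
            if c["id"] == cid:
                return c
        c = {"id": cid, "children": []}
        node["children"].append(c)
        return c

    for spec in scheme.indicators:
        node = root
        for part in spec.layer:
            node = ensure_child(node, part)
            node["derive"] = node.get("derive", "entropy")
        leaf = ensure_child(node, spec.id)
        leaf.pop("children", None)
    root["derive"] = "entropy"

    def mark(node: dict) -> None:
        if node.get("children"):
            node["derive"] = "entropy"
            for c in node["children"]:
                mark(c)
        else:
            node.pop("derive", None)

    mark(root)
    return root


class SensitivityModel:
    """Eco-environmental sensitivity evaluation of polygonal units.

    Parameters
    ----------
    raw : DataFrame
        Units x indicators raw values (a ``unit_id`` column, if present,
        becomes the index).
    scheme : GradingScheme
        The indicator grade system (bins per indicator).
    tree : WeightTree, optional
        Fixed weight hierarchy.  Groups are renormalized before use.
        Omit to derive weights from the data by the entropy method.
    areas : Series, optional
        Per-unit areas in hm² for area tabulation.
    """

    def __init__(
        self,
        raw: pd.DataFrame,
        scheme: GradingScheme,
        tree: WeightTree | None = None,
        areas: pd.Series | None = None,
    ) -> None:
        self.raw = raw.set_index("unit_id") if "unit_id" in raw.columns else raw
        self.scheme = scheme
        self.tree = tree
        self.areas = areas

    @classmethod
    def from_dataframe(
        cls, raw: pd.DataFrame, scheme: GradingScheme, **kwargs
    ) -> "SensitivityModel":
        return cls(raw=raw, scheme=scheme, **kwargs)

    def fit(
        self,
        weights: str = "auto",
        variant: str = "euclid",
        mode: str = "hierarchical",
        tie: str = "higher",
        missing: str = "error",
    ) -> "SensitivityResults":
        """Run the full evaluation.

        weights : {"auto", "fixed", "entropy"}
            ``fixed`` uses the supplied tree (renormalized); ``entropy``
            derives every group's weights from the graded data; ``auto``
            picks ``fixed`` when a tree was supplied, else ``entropy``.
        variant : {"euclid", "hamming"}
            Approach-degree form (with / without the square root).
        """
        if weights == "auto":
            weights = "fixed" if self.tree is not None else "entropy"
        grades = grade_table(self.scheme, self.raw, tie=tie)
        if weights == "fixed":
            if self.tree is None:
                raise ContractError("weights='fixed' requires a weight tree")
            tree = self.tree.normalized()
        elif weights == "entropy":
            tree = build_weight_tree(_topology_from_scheme(self.scheme), data=grades)
        else:
            raise ContractError(f"weights must be auto|fixed|entropy, got {weights!r}")

        comp = composite_index(grades, tree, missing=missing, mode=mode)
        classes = classify(comp[tree.root.id], DEFAULT_CLASSES)

        leaf_w = tree.leaf_weights()
        matrix = fme.EvaluationMatrix.from_dataframe(
            grades[list(leaf_w.index)], directions="benefit"
        )
        ph = fme.approach_degrees(matrix, leaf_w / leaf_w.sum(), variant=variant)

        return SensitivityResults(
            model=self,
            grades=grades,
            weight_tree=tree,
            weight_source=weights,
            variant=variant,
            composite=comp,
            classes=classes,
            approach=ph,
        )


@dataclass
class SensitivityResults:
    """Fitted evaluation: per-unit composite indices, classes and PH scores."""

    model: SensitivityModel
    grades: pd.DataFrame
    weight_tree: WeightTree
    weight_source: str
    variant: str
    composite: pd.DataFrame
    classes: pd.DataFrame
    approach: pd.Series

    @property
    def G(self) -> pd.Series:
        """Root composite sensitivity index per unit."""
        return self.composite[self.weight_tree.root.id]

    def rank(self) -> list:
        """Units ordered by approach degree, closest to the ideal first."""
        return fme.rank_objects(self.approach)

    def area_summary(self, areas: pd.Series | None = None, drop_empty: bool = True) -> pd.DataFrame:
        a = areas if areas is not None else self.model.areas
        if a is None:
            raise ContractError("no per-unit areas supplied")
        return area_summary(self.classes, a, drop_empty=drop_empty)

    def frame(self) -> pd.DataFrame:
        """Tidy per-unit results (G, class, PH)."""
        out = self.classes.copy()
        out["PH"] = self.approach
        return out

    def summary(self) -> str:
        n = len(self.classes)
        lines = [
            "Eco-environmental sensitivity evaluation",
            "=" * 56,
            f"units: {n}    indicators: {len(self.model.scheme)}",
            f"weights: {self.weight_source}    approach-degree variant: {self.variant}",
            f"composite index G: min {self.G.min():.3f}  mean {self.G.mean():.3f}  max {self.G.max():.3f}",
            "",
            "class distribution:",
        ]
        counts = self.classes.groupby(["class_index", "class_label"]).size()
        for (gi, label), cnt in counts.items():
            lines.append(f"  {gi}  {label:<22} {cnt:>6}  ({100.0 * cnt / n:.2f}%)")
        if self.model.areas is not None:
            lines.append("")
            lines.append("area summary (hm², % of evaluated total):")
            for label, row in self.area_summary().iterrows():
                lines.append(
                    f"  {int(row['class_index'])}  {label:<22} "
                    f"{row['area_hm2']:>12,.2f}  {row['proportion_pct']:>6.2f}%"
                )
        return "\n".join(lines)
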