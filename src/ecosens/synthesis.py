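"""Composite sensitivity index, five-class classification, area summaries.

The composite index G of a hierarchy node is the weighted mean of its
children's values, applied recursively from the leaf grades (the discrete
indices 1/3/5/7/9) up to the root.  Because child weights are normalized at
every node, G is a convex combination of the leaf grades and always lies in
[1, 9].  Continuous composite scores are classified into the five
sensitivity classes by the intervals

    [1, 3)  insensitive
    [3, 5)  slightly sensitive
    [5, 7)  moderately sensitive
    [7, 9)  highly sensitive
    [9, 10] extremely sensitive

(left-closed / right-open, last interval closed, so every attainable score
has exactly one class).  Per-class areas are tabulated in hectares with
proportions of the evaluated total rounded half-up to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ContractError, SynthesisError
from .grading import GRADE_INDICES, GRADE_LABELS, LABEL_BY_INDEX
from .weights import WeightNode, WeightTree


@dataclass(frozen=True)
class SensitivityClass:
    label: str
    index: int
    lo: float
    hi: float
    closed_right: bool = False

    def contains(self, g: float) -> bool:
        if self.closed_right:
            return self.lo <= g <= self.hi
        return self.lo <= g < self.hi


DEFAULT_CLASSES: tuple[SensitivityClass, ...] = (
    SensitivityClass("insensitive", 1, 1.0, 3.0),
    SensitivityClass("slightly sensitive", 3, 3.0, 5.0),
    SensitivityClass("moderately sensitive", 5, 5.0, 7.0),
    SensitivityClass("highly sensitive", 7, 7.0, 9.0),
    SensitivityClass("extremely sensitive", 9, 9.0, 10.0, closed_right=True),
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (table conventions), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def composite_index(
    grades: pd.DataFrame,
    tree: WeightTree,
    missing: str = "error",
    mode: str = "hierarchical",
) -> pd.DataFrame:
    """Aggregate leaf grades up the weight tree; returns per-node G columns.

    Parameters
    ----------
    grades : DataFrame
        Units x leaf-indicator grade indices; columns must cover the tree's
        leaves.
    tree : WeightTree
    missing : {"error", "skip"}
        ``error`` raises if any unit misses a leaf grade; ``skip`` drops the
        missing leaves per unit and renormalizes the sibling weights.
    mode : {"hierarchical", "flat"}
        ``hierarchical`` composes weighted means level by level;
        ``flat`` applies the global (path-product) leaf weights in one sum.
        The two are algebraically identical for complete data.

    Returns
    -------
    DataFrame with one column per tree node (leaves carry their grades; the
    root column is the final composite index G).
    """
    leaf_ids = tree.leaf_ids()
    absent = [l for l in leaf_ids if l not in grades.columns]
    if absent:
        raise SynthesisError(f"grade table lacks columns for tree leaves: {absent}")
    sub = grades[leaf_ids].astype(float)
    if sub.isna().any().any():
        if missing == "error":
            bad_units = list(sub.index[sub.isna().any(axis=1)])
            raise SynthesisError(
                f"missing leaf grades with missing='error' for units: {bad_units[:10]}"
                + ("..." if len(bad_units) > 10 else "")
            )
        if missing != "skip":
            raise ContractError(f"missing must be 'error' or 'skip', got {missing!r}")

    out = pd.DataFrame(index=sub.index)

    if mode == "flat":
        w = tree.leaf_weights().reindex(leaf_ids)
        vals = sub.to_numpy()
        wv = w.to_numpy()
        mask = ~np.isnan(vals)
        num = np.nansum(vals * wv, axis=1)
        den = (mask * wv).sum(axis=1)
        out[tree.root.id] = num / den
        for l in leaf_ids:
            out[l] = sub[l]
        return out
    if mode != "hierarchical":
        raise ContractError(f"mode must be 'hierarchical' or 'flat', got {mode!r}")

    def aggregate(node: WeightNode) -> pd.Series:
        if node.is_leaf:
            s = sub[node.id]
            out[node.id] = s
            return s
        cols = {c.id: aggregate(c) for c in node.children}
        wts = pd.Series({c.id: c.weight for c in node.children})
        frame = pd.DataFrame(cols)
        mask = frame.notna()
        num = (frame * wts).sum(axis=1, min_count=1)
        den = (mask * wts).sum(axis=1)
        g = num / den
        out[node.id] = g
        return g

    aggregate(tree.root)
    # column order: root first, then depth-first
    ordered = [n.id for n in tree]
    return out[ordered]


def classify(
    index: pd.Series | pd.DataFrame,
    classes: tuple[SensitivityClass, ...] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Assign each unit's composite score to a sensitivity class.

    Returns a DataFrame with columns ``G``, ``class_index``, ``class_label``.
    """
    if isinstance(index, pd.DataFrame):
        g = index.iloc[:, 0]
    else:
        g = index
    g = g.astype(float)
    lo = min(c.lo for c in classes)
    hi = max(c.hi for c in classes)
    bad = g[(g < lo) | (g > hi)]
    if len(bad):
        raise ContractError(
            f"composite index outside [{lo}, {hi}] for units: {list(bad.index[:10])}"
        )
    idx = []
    lab = []
    for v in g:
        for c in classes:
            if c.contains(v):
                idx.append(c.index)
                lab.append(c.label)
                break
        else:  # pragma: no cover - intervals partition [lo, hi]
            raise ContractError(f"no class interval contains {v}")
    return pd.DataFrame({"G": g, "class_index": idx, "class_label": lab}, index=g.index)


def area_summary(
    classified: pd.Series | pd.DataFrame,
    areas: pd.Series,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Per-class area totals (hm²) and proportions (%) of the evaluated total.

    Parameters
    ----------
    classified : class index per unit (Series), or the frame from
        :func:`classify` (its ``class_index`` column is used).
    areas : per-unit areas in hm², aligned on the unit index.
    drop_empty : omit classes with zero area (matching published layouts
        that print only the classes present).

    Returns
    -------
    DataFrame indexed by class label with columns ``class_index``,
    ``area_hm2`` and ``proportion_pct`` (rounded half-up to 2 decimals).
    """
    if isinstance(classified, pd.DataFrame):
        cls = classified["class_index"]
    else:
        cls = classified
    a = areas.reindex(cls.index).astype(float)
    if a.isna().any():
        raise ContractError(
            f"areas missing for units: {list(cls.index[a.isna()])[:10]}"
        )
    if (a < 0).any():
        raise ContractError("areas must be nonnegative")
    total = float(a.sum())
    if total <= 0:
        raise ContractError("total evaluated area must be positive")
    rows = []
    for gi, label in LABEL_BY_INDEX.items():
        mask = cls == gi
        area = float(a[mask].sum())
        if drop_empty and not mask.any():
            continue
        rows.append(
            {
                "class_label": label,
                "class_index": gi,
                "area_hm2": area,
                "proportion_pct": round_half_up(100.0 * area / total, 2),
            }
        )
    out = pd.DataFrame(rows).set_index("class_label")
    out.attrs["total_area_hm2"] = total
    return out
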