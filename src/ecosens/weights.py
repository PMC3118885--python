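"""Hierarchical weight trees (A/B/C/D indicator hierarchy).

Each internal node holds the weights of its children relative to that node;
weights at every node are nonnegative and sum to 1 (within tolerance).
Weights are either *fixed* (supplied by config, e.g. an expert table) or
*entropy-derived* from data at that node.  Global leaf weights are products
of the weights along the root-to-leaf path, so a level-by-level weighted
mean equals a single flat weighted sum over the leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import pandas as pd
import yaml

from .entropy import weight_chain
from .errors import ContractError, SchemaError
from .fme import EvaluationMatrix

WEIGHT_SUM_TOL = 1e-9


@dataclass
class WeightNode:
    id: str
    weight: float = 1.0  # relative to the parent; root carries 1
    children: list["WeightNode"] = field(default_factory=list)
    provenance: str = "fixed"  # fixed | entropy
    flags: tuple[str, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def child(self, node_id: str) -> "WeightNode":
        for c in self.children:
            if c.id == node_id:
                return c
        raise KeyError(node_id)


@dataclass
class WeightTree:
    """A validated weight hierarchy rooted at a single node."""

    root: WeightNode

    def __iter__(self) -> Iterator[WeightNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def node(self, node_id: str) -> WeightNode:
        for n in self:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def leaves(self) -> list[WeightNode]:
        return [n for n in self if n.is_leaf]

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def leaf_weights(self) -> pd.Series:
        """Global leaf weights: products of relative weights along each path."""
        out: dict[str, float] = {}

        def walk(node: WeightNode, acc: float) -> None:
            if node.is_leaf:
                out[node.id] = acc
            for c in node.children:
                walk(c, acc * c.weight)

        walk(self.root, 1.0)
        return pd.Series(out, name="weight")

    def validate(self, tol: float = WEIGHT_SUM_TOL, strict: bool = True) -> list[str]:
        """Check child-weight normalization at every internal node.

        Returns the ids of nodes whose children do not sum to 1.  In strict
        mode any unflagged offending node raises; flagged nodes (e.g.
        transcribed as printed from a source table) are reported only.
        """
        seen: set[str] = set()
        bad: list[str] = []
        for n in self:
            if n.id in seen:
                raise SchemaError(f"duplicate node id {n.id!r}")
            seen.add(n.id)
            if n.weight < 0:
                raise SchemaError(f"node {n.id!r}: negative weight {n.weight}")
            if n.children:
                s = sum(c.weight for c in n.children)
                if abs(s - 1.0) > tol:
                    bad.append(n.id)
                    if strict and "non-normalized" not in n.flags:
                        raise SchemaError(
                            f"node {n.id!r}: child weights sum to {s:.6g}, not 1"
                        )
        return bad

    def normalized(self) -> "WeightTree":
        """A copy with every node's child weights renormalized to sum to 1."""

        def copy(node: WeightNode) -> WeightNode:
            kids = [copy(c) for c in node.children]
            if kids:
                s = sum(c.weight for c in kids)
                if s <= 0:
                    raise SchemaError(f"node {node.id!r}: child weights sum to {s}")
                for c in kids:
                    c.weight = c.weight / s
            return WeightNode(
                id=node.id,
                weight=node.weight,
                children=kids,
                provenance=node.provenance,
                flags=node.flags,
            )

        return WeightTree(root=copy(self.root))

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, doc: Mapping) -> "WeightTree":
        def build(d: Mapping) -> WeightNode:
            return WeightNode(
                id=str(d["id"]),
                weight=float(d.get("weight", 1.0)),
                children=[build(c) for c in d.get("children", [])],
                provenance=d.get("provenance", "fixed"),
                flags=tuple(d.get("flags", [])),
            )

        return cls(root=build(doc))

    def to_dict(self) -> dict:
        def dump(n: WeightNode) -> dict:
            d: dict = {"id": n.id, "weight": n.weight, "provenance": n.provenance}
            if n.flags:
                d["flags"] = list(n.flags)
            if n.children:
                d["children"] = [dump(c) for c in n.children]
            return d

        return dump(self.root)

    @classmethod
    def from_yaml(cls, path) -> "WeightTree":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_frame(self) -> pd.DataFrame:
        """Flat table of nodes (id, parent, relative weight, provenance)."""
        rows = []

        def walk(n: WeightNode, parent: str | None) -> None:
            rows.append(
                {"id": n.id, "parent": parent, "weight": n.weight, "provenance": n.provenance}
            )
            for c in n.children:
                walk(c, n.id)

        walk(self.root, None)
        return pd.DataFrame(rows)


def build_weight_tree(
    config: Mapping,
    data: pd.DataFrame | None = None,
    tol: float = WEIGHT_SUM_TOL,
) -> WeightTree:
    """Build a validated weight tree from config, deriving weights where asked.

    ``config`` mirrors the YAML layout (nested ``id``/``children``); a node
    may set ``derive: entropy`` instead of fixed child weights, in which case
    ``data`` (units x leaf-indicator grades) must cover the node's leaves.
    Derivation is bottom-up: each child's per-unit value is its own leaf
    grade (leaf child) or its already-aggregated weighted mean (internal
    child); the entropy chain on those child columns yields the weights.
    """

    def leaf_set(d: Mapping) -> list[str]:
        kids = d.get("children", [])
        if not kids:
            return [str(d["id"])]
        return [lid for c in kids for lid in leaf_set(c)]

    def build(d: Mapping) -> tuple[WeightNode, pd.Series | None]:
        kids_cfg = d.get("children", [])
        if not kids_cfg:
            col = data[str(d["id"])] if data is not None and str(d["id"]) in data else None
            return (
                WeightNode(id=str(d["id"]), weight=float(d.get("weight", 1.0))),
                col,
            )
        built = [build(c) for c in kids_cfg]
        nodes = [n for n, _ in built]
        derive = d.get("derive")
        if derive == "entropy":
            cols = {n.id: v for (n, v) in built}
            if any(v is None for v in cols.values()):
                missing = [k for k, v in cols.items() if v is None]
                raise ContractError(
                    f"node {d['id']!r}: entropy derivation requested but no data "
                    f"for children {missing}"
                )
            frame = pd.DataFrame(cols)
            w = weight_chain(EvaluationMatrix.from_dataframe(frame)).weights
            for n in nodes:
                n.weight = float(w[n.id])
            provenance = "entropy"
        elif derive:
            raise SchemaError(f"node {d['id']!r}: unknown derive method {derive!r}")
        else:
            if any("weight" not in c for c in kids_cfg):
                raise SchemaError(
                    f"node {d['id']!r}: children need fixed weights or derive: entropy"
                )
            provenance = "fixed"
        s = sum(n.weight for n in nodes)
        if abs(s - 1.0) > tol and "non-normalized" not in tuple(d.get("flags", ())):
            raise SchemaError(f"node {d['id']!r}: child weights sum to {s:.6g}, not 1")
        if s > 0:
            for n in nodes:
                n.weight = n.weight / s
        node = WeightNode(
            id=str(d["id"]),
            weight=float(d.get("weight", 1.0)),
            children=nodes,
            provenance=provenance if kids_cfg else "fixed",
            flags=tuple(d.get("flags", [])),
        )
        agg = None
        if all(v is not None for _, v in built):
            agg = sum(n.weight * v for n, (_, v) in zip(nodes, built))
        return node, agg

    root, _ = build(config)
    tree = WeightTree(root=root)
    tree.validate(tol=max(tol, 1e-9), strict=True)
    return tree
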