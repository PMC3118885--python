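"""Fuzzy matter-element (FME) machinery.

A compound fuzzy matter-element collects *m* evaluated objects (rows) by
*n* characters (columns) of crisp values ``x_ij``.  Each character is
normalized to an *excellent dependent degree* ``u`` in [0, 1]:

* benefit characters (larger is closer to the ideal): ``u = x / max(x)``
* cost characters (smaller is closer to the ideal):   ``u = min(x) / x``

The *standard* matter-element is the ideal object whose dependent degree is
the columnwise optimum — identically 1 under these normalizations.  Squared
differences ``Δ = (u0 - u)²`` against the standard element, aggregated with
a normalized character weight vector, yield the approach degree

* ``hamming``:  ``PH = 1 - Σ w·Δ``
* ``euclid``:   ``PH = 1 - sqrt(Σ w·Δ)``  (default)

Both variants are monotone transforms of the same weighted distance and so
induce the same ranking; larger PH means closer to the ideal scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, NormalizationError

WEIGHT_TOL = 1e-9

BENEFIT = "benefit"
COST = "cost"


@dataclass
class EvaluationMatrix:
    """Objects x characters raw-value matrix with per-character directions.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are object ids, columns are character ids, entries ``x_ij``.
    directions : mapping of character id -> {"benefit", "cost"}
        Characters absent from the mapping default to ``benefit``.
    """

    values: pd.DataFrame
    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ContractError("evaluation matrix needs at least 1 object and 1 character")
        if self.values.isna().all(axis=0).any():
            bad = list(self.values.columns[self.values.isna().all(axis=0)])
            raise ContractError(f"characters entirely missing: {bad}")
        unknown = set(self.directions) - set(self.values.columns)
        if unknown:
            raise ContractError(f"directions for unknown characters: {sorted(unknown)}")
        for c, d in self.directions.items():
            if d not in (BENEFIT, COST):
                raise ContractError(f"character {c!r}: direction must be benefit|cost, got {d!r}")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, directions: Mapping[str, str] | str = BENEFIT
    ) -> "EvaluationMatrix":
        if isinstance(directions, str):
            directions = {c: directions for c in df.columns}
        return cls(values=df.astype(float), directions=dict(directions))

    def direction(self, character) -> str:
        return self.directions.get(character, BENEFIT)

    @property
    def objects(self) -> pd.Index:
        return self.values.index

    @property
    def characters(self) -> pd.Index:
        return self.values.columns


def normalize(matrix: EvaluationMatrix) -> pd.DataFrame:
    """Excellent-dependent-degree normalization to [0, 1] per character.

    Benefit characters require a positive maximum; cost characters require
    strictly positive values (the ``min/x`` form is undefined otherwise).
    """
    out = {}
    for c in matrix.characters:
        x = matrix.values[c].astype(float)
        if matrix.direction(c) == BENEFIT:
            mx = x.max()
            if not mx > 0:
                raise NormalizationError(
                    f"character {c!r}: benefit normalization needs max > 0, got {mx}"
                )
            out[c] = x / mx
        else:
            if not (x > 0).all():
                raise NormalizationError(
                    f"character {c!r}: cost normalization needs all values > 0"
                )
            out[c] = x.min() / x
    dep = pd.DataFrame(out, index=matrix.objects)[list(matrix.characters)]
    return dep


def standard_element(dep: pd.DataFrame) -> pd.Series:
    """The ideal (standard) matter-element: columnwise optimum of ``u`` (all 1)."""
    return dep.max(axis=0)


def squared_differences(dep: pd.DataFrame, std: pd.Series | None = None) -> pd.DataFrame:
    """Elementwise squared difference ``Δ = (u0 - u)²`` against the standard element."""
    if std is None:
        std = standard_element(dep)
    if list(std.index) != list(dep.columns):
        raise ContractError("standard element characters do not match the dependency matrix")
    return (std - dep) ** 2


def _as_weight_series(weights, characters: pd.Index) -> pd.Series:
    if isinstance(weights, pd.Series):
        w = weights.reindex(characters)
        if w.isna().any():
            missing = list(characters[w.isna()])
            raise ContractError(f"weights missing for characters: {missing}")
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=characters)
    if (w < 0).any():
        raise ContractError("weights must be nonnegative")
    s = float(w.sum())
    if abs(s - 1.0) > WEIGHT_TOL:
        raise ContractError(f"weights must sum to 1 within {WEIGHT_TOL:g}; got {s!r}")
    return w / s


def approach_degree(
    diff: pd.DataFrame, weights, variant: str = "euclid"
) -> pd.Series:
    """Per-object approach degree PH toward the standard element.

    Parameters
    ----------
    diff : DataFrame of squared differences, objects x characters.
    weights : per-character weight vector (Series keyed by character, or
        array-like in column order); nonnegative, summing to 1 within 1e-9
        (renormalized after the check to absorb config rounding).
    variant : {"euclid", "hamming"}
        ``hamming`` applies the weighted sum directly; ``euclid`` takes its
        square root before subtracting from 1.
    """
    if variant not in ("euclid", "hamming"):
        raise ContractError(f"variant must be euclid|hamming, got {variant!r}")
    w = _as_weight_series(weights, diff.columns)
    d = diff.to_numpy(dtype=float) @ w.to_numpy()
    if variant == "euclid":
        d = np.sqrt(d)
    ph = pd.Series(1.0 - d, index=diff.index, name="PH")
    return ph


def rank_objects(ph: pd.Series) -> list:
    """Object ids in descending PH order; ties keep input order (stable sort)."""
    order = ph.sort_values(ascending=False, kind="stable")
    return list(order.index)


def approach_degrees(
    matrix: EvaluationMatrix, weights, variant: str = "euclid"
) -> pd.Series:
    """Convenience chain: normalize -> squared differences -> approach degree."""
    dep = normalize(matrix)
    diff = squared_differences(dep)
    return approach_degree(diff, weights, variant=variant)
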