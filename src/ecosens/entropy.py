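"""Entropy weighting: objective indicator weights from data dispersion.

The chain, per indicator (column) over the evaluated objects (rows):

1. min-max ranking ``b = (r - r_min) / (r_max - r_min)``, reversed for cost
   indicators; a constant column (``r_max == r_min``) maps to all zeros —
   it carries no information and will end with weight exactly 0;
2. corrected frequencies ``f_j = (1 + b_j) / Σ_j (1 + b_j)`` (the +1 shift
   keeps every frequency strictly positive so ``ln f`` is defined; the
   uncorrected ``f = b / Σ b`` is available for comparison only);
3. Shannon entropy normalized by ``ln m``: ``H = -Σ f ln f / ln m`` in
   (0, 1], with H = 1 iff f is uniform;
4. weights ``w_i = (1 - H_i) / (n - Σ H)``, nonnegative, summing to 1.

Lower entropy (more discrimination between objects) yields larger weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateWeightsError
from .fme import BENEFIT, COST, EvaluationMatrix

_H_ONE_TOL = 1e-12


def minmax_rank(matrix: EvaluationMatrix) -> pd.DataFrame:
    """Min-max rank each character into [0, 1]; constant columns map to zeros."""
    if matrix.values.shape[0] < 2:
        raise ContractError("min-max ranking needs at least 2 objects")
    out = {}
    for c in matrix.characters:
        x = matrix.values[c].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            out[c] = pd.Series(0.0, index=matrix.objects)
            continue
        b = (x - lo) / (hi - lo)
        if matrix.direction(c) == COST:
            b = 1.0 - b
        out[c] = b
    return pd.DataFrame(out, index=matrix.objects)[list(matrix.characters)]


def corrected_frequencies(ranked: pd.DataFrame, use_correction: bool = True) -> pd.DataFrame:
    """Per-indicator frequency distribution over objects.

    With ``use_correction`` (default) the +1-shifted form is used, which is
    strictly positive and sums to 1 per column.  The uncorrected form
    ``b / Σ b`` is provided for comparison; it is undefined for all-zero
    columns and may contain zeros.
    """
    b = ranked.astype(float)
    if use_correction:
        shifted = 1.0 + b
        return shifted / shifted.sum(axis=0)
    sums = b.sum(axis=0)
    if (sums == 0).any():
        bad = list(b.columns[sums == 0])
        raise ContractError(f"uncorrected frequencies undefined for all-zero columns: {bad}")
    return b / sums


def entropy(f: pd.DataFrame) -> pd.Series:
    """Normalized Shannon entropy per indicator: ``H = -Σ f ln f / ln m``."""
    m = f.shape[0]
    if m < 2:
        raise ContractError("entropy needs at least 2 objects (ln m = 0 for m = 1)")
    arr = f.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, arr * np.log(arr), 0.0)
    h = -terms.sum(axis=0) / np.log(m)
    # snap to the exact maximum: a uniform f must give H = 1 (and weight 0)
    # despite rounding in the log sums
    h = np.where(np.abs(h - 1.0) < 1e-12, 1.0, h)
    return pd.Series(np.minimum(h, 1.0), index=f.columns, name="H")


def entropy_weights(H: pd.Series) -> pd.Series:
    """Weights ``w = (1 - H) / (n - Σ H)``; indicators with H = 1 get weight 0."""
    h = H.astype(float)
    n = len(h)
    denom = n - float(h.sum())
    if denom <= _H_ONE_TOL:
        raise DegenerateWeightsError(
            "all indicators have entropy 1 (no discrimination); weights undefined"
        )
    w = (1.0 - h) / denom
    w = w.clip(lower=0.0)
    return (w / w.sum()).rename("w")


@dataclass
class EntropyResult:
    """Intermediate and final products of the entropy-weighting chain."""

    ranked: pd.DataFrame
    frequencies: pd.DataFrame
    H: pd.Series
    weights: pd.Series


def weight_chain(matrix: EvaluationMatrix) -> EntropyResult:
    """Run the full chain (rank -> frequencies -> entropy -> weights)."""
    b = minmax_rank(matrix)
    f = corrected_frequencies(b)
    h = entropy(f)
    w = entropy_weights(h)
    return EntropyResult(ranked=b, frequencies=f, H=h, weights=w)
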