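"""Independent brute-force oracles, written with plain Python loops and the
math module only, so they share no code path with the package internals."""

import math


def entropy_weights_bruteforce(rows, directions):
    """Step-by-step entropy weighting on a list-of-rows matrix.

    rows : list of m lists (objects), each of n raw values (indicators)
    directions : list of n strings, "benefit" or "cost"
    returns : list of n weights
    """
    m = len(rows)
    n = len(rows[0])
    # min-max ranking per indicator
    b = [[0.0] * n for _ in range(m)]
    for i in range(n):
        col = [rows[j][i] for j in range(m)]
        lo, hi = min(col), max(col)
        for j in range(m):
            if hi == lo:
                b[j][i] = 0.0
            elif directions[i] == "benefit":
                b[j][i] = (col[j] - lo) / (hi - lo)
            else:
                b[j][i] = (hi - col[j]) / (hi - lo)
    # corrected frequencies per indicator
    f = [[0.0] * n for _ in range(m)]
    for i in range(n):
        tot = sum(1.0 + b[j][i] for j in range(m))
        for j in range(m):
            f[j][i] = (1.0 + b[j][i]) / tot
    # normalized entropy per indicator
    H = []
    for i in range(n):
        s = 0.0
        for j in range(m):
            s += f[j][i] * math.log(f[j][i])
        H.append(-s / math.log(m))
    # weights
    denom = n - sum(H)
    w = [(1.0 - H[i]) / denom for i in range(n)]
    total = sum(w)
    return [x / total for x in w]


def approach_degree_bruteforce(diff_row, weights, variant):
    s = sum(w * d for w, d in zip(weights, diff_row))
    if variant == "euclid":
        s = math.sqrt(s)
    return 1.0 - s


def segment_buffer_area(length, d):
    """Analytic area of the buffer of a straight segment: rectangle + disc."""
    return 2.0 * length * d + math.pi * d * d
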