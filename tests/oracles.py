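"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementation: the run scanner
walks positions one by one, the local-alignment oracle is an explicit
three-matrix affine-gap dynamic program, the rank-sum oracle enumerates all
group assignments, and the column classifier inspects each alignment column
directly.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from Bio.Align import substitution_matrices


def brute_force_runs(calls, min_len):
    """Position-by-position scan for maximal 1-runs of length >= min_len."""
    runs = []
    start = None
    for i, c in enumerate(list(calls) + [0]):
        if c == 1 and start is None:
            start = i
        elif c != 1 and start is not None:
            if i - start >= min_len:
                runs.append((start + 1, i))  # 1-based closed
            start = None
    return runs


def sw_affine_score(a, b, matrix_name="BLOSUM62", gap_open=10.0, gap_extend=0.5):
    """Optimal local-alignment score via explicit 3-matrix recursion.

    A gap of length L costs gap_open + gap_extend * (L - 1): the opening
    penalty is charged on the first gap residue, extension on each further
    one (EMBOSS water semantics).
    """
    mat = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(
                M[i - 1][j] - gap_open,
                Ix[i - 1][j] - gap_extend,
                Iy[i - 1][j] - gap_open,
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open,
                Iy[i][j - 1] - gap_extend,
                Ix[i][j - 1] - gap_open,
            )
            best = max(best, M[i][j])
    return best


def exact_ranksum_p(a, b):
    """Two-sided exact rank-sum p-value by full enumeration (no ties)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    n1, n2 = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    u_hi = max(u_obs, n1 * n2 - u_obs)
    count = 0
    for idx in combinations(range(n1 + n2), n1):
        u = sum(i + 1 for i in idx) - n1 * (n1 + 1) / 2
        if u >= u_hi:
            count += 1
    p = 2.0 * count / comb(n1 + n2, n1)
    return min(p, 1.0)


def classify_column(letters):
    """Direct classifier for one alignment column: set of class labels."""
    residues = [ch for ch in letters if ch != "-"]
    labels = set()
    if "-" in letters:
        labels.add("insertion")
    if len(set(residues)) >= 2:
        labels.add("mutation")
    if "-" not in letters and len(set(residues)) == 1:
        labels.add("identical")
    return labels


def quantile_type7(sorted_values, q):
    """Linear-interpolation (type 7) quantile computed by hand."""
    n = len(sorted_values)
    if n == 1:
        return sorted_values[0]
    h = (n - 1) * q
    lo = int(h)
    hi = min(lo + 1, n - 1)
    return sorted_values[lo] + (h - lo) * (sorted_values[hi] - sorted_values[lo])
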