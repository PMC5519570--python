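"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (loops, explicit enumeration) and
shares no code with the package implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def absences_bruteforce(values: np.ndarray, margins: str = "both") -> int:
    """Embedded absences by explicit scanning of every column (and row)."""
    def scan(v):
        total = 0
        for col in v.T:
            ones = [i for i, x in enumerate(col) if x == 1]
            if not ones:
                continue
            for i in range(ones[0], ones[-1] + 1):
                if col[i] == 0:
                    total += 1
        return total

    total = scan(values)
    if margins == "both":
        total += scan(values.T)
    return total


def replacements_bruteforce(values: np.ndarray) -> int:
    """Species replacements by explicit range fill and pair enumeration."""
    T, S = values.shape
    filled = np.array(values, copy=True)
    for j in range(S):
        ones = [i for i in range(T) if values[i, j] == 1]
        if ones:
            filled[ones[0]: ones[-1] + 1, j] = 1
    total = 0
    for a in range(S):
        for b in range(a + 1, S):
            only_a = sum(
                1 for i in range(T) if filled[i, a] == 1 and filled[i, b] == 0
            )
            only_b = sum(
                1 for i in range(T) if filled[i, b] == 1 and filled[i, a] == 0
            )
            total += only_a * only_b
    return total


def morisita_bruteforce(values: np.ndarray) -> float:
    """Morisita's index from explicitly tallied range boundaries."""
    T, S = values.shape
    counts = [0] * T
    for j in range(S):
        ones = [i for i in range(T) if values[i, j] == 1]
        if ones:
            counts[ones[0]] += 1
            counts[ones[-1]] += 1
    N = sum(counts)
    return T * sum(n * (n - 1) for n in counts) / (N * (N - 1))


def ca_first_axis_eigh(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First non-trivial CA axis via dense eigendecomposition.

    Returns (row standard coordinates, column standard coordinates,
    eigenvalue). Independent of the package's SVD route: eigendecomposes
    the symmetric matrix M M^T where M is the chi-square standardized
    table.
    """
    X = np.asarray(values, dtype=float)
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    M = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = np.linalg.eigh(M @ M.T)
    order = np.argsort(evals)[::-1]
    lam = evals[order[0]]
    u = evecs[:, order[0]]
    # column coordinates from the transition formula
    v = (M.T @ u) / np.sqrt(lam)
    return u / np.sqrt(r), v / np.sqrt(c), float(lam)


def unifrac_bruteforce(
    tree, counts_a: dict[str, int], counts_b: dict[str, int], weighted: bool
) -> float:
    """UniFrac by explicit summation over every branch of the tree.

    ``tree`` is an skbio TreeNode; counts are leaf-name -> reads.
    Unweighted: unique branch length / union branch length over the two
    presence sets. Weighted (normalized): sum l |pA - pB| / sum l (pA + pB).
    """
    total_a = sum(counts_a.values()) or 1
    total_b = sum(counts_b.values()) or 1
    unique = union = 0.0
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = (
            {node.name} if node.is_tip() else {t.name for t in node.tips()}
        )
        in_a = any(counts_a.get(l, 0) > 0 for l in leaves)
        in_b = any(counts_b.get(l, 0) > 0 for l in leaves)
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unique += length
        pa = sum(counts_a.get(l, 0) for l in leaves) / total_a
        pb = sum(counts_b.get(l, 0) for l in leaves) / total_b
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    if weighted:
        return num / den if den else 0.0
    return unique / union if union else 0.0


def permanova_centroid_oracle(points: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from explicit centroid sums of squares (Euclidean)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    labels = list(dict.fromkeys(groups))
    k = len(labels)
    grand = points.mean(axis=0)
    ss_total = ((points - grand) ** 2).sum()
    ss_within = 0.0
    for g in labels:
        sub = points[np.asarray(groups) == g]
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total
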