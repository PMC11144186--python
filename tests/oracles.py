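"""Independently coded reference implementations used only by the tests.

These deliberately avoid importing any clustering or alignment code from
the package: they restate the definitions from scratch so the tests check
two separate routes to the same answer.
"""
from __future__ import annotations


def brute_dpc_partition(d, dc, rho_min=1.0, delta_min=0.5):
    """Plain-python density-peak partition over a distance matrix (list of lists).

    Tie rules: item j is denser than i iff rho[j] > rho[i], or equal rho and
    j < i. Among equidistant denser items the nearest-denser link goes to
    the densest, ties to the lowest index. If thresholds select no center,
    the densest item is forced. Returns a set of frozensets (the partition).
    """
    n = len(d)
    rho = [sum(1 for j in range(n) if j != i and d[i][j] < dc) for i in range(n)]

    def denser(j, i):
        return rho[j] > rho[i] or (rho[j] == rho[i] and j < i)

    delta = [0.0] * n
    nearest = [None] * n
    for i in range(n):
        hs = [j for j in range(n) if denser(j, i)]
        if not hs:
            delta[i] = max((d[i][j] for j in range(n) if j != i), default=0.0)
        else:
            dmin = min(d[i][j] for j in hs)
            delta[i] = dmin
            cands = [j for j in hs if d[i][j] == dmin]
            nearest[i] = max(cands, key=lambda j: (rho[j], -j))

    centers = {i for i in range(n) if rho[i] >= rho_min and delta[i] >= delta_min}
    if not centers:
        centers = {max(range(n), key=lambda i: (rho[i], -i))}

    def root(i):
        while i not in centers:
            i = nearest[i]
        return i

    parts: dict[int, set[int]] = {}
    for i in range(n):
        parts.setdefault(root(i), set()).add(i)
    return {frozenset(s) for s in parts.values()}


def partition_of_labels(labels):
    """Group indices by label into a set of frozensets."""
    parts: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        parts.setdefault(int(lab), set()).add(i)
    return {frozenset(s) for s in parts.values()}


def local_dp_score(a, b, sub, gap_open, gap_extend):
    """Textbook three-state local-alignment DP, plain python.

    ``sub`` maps (char, char) -> score; a gap of length k costs
    ``gap_open + k * gap_extend``.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])], E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def enumerate_local_score(a, b, sub, gap_open, gap_extend):
    """Exhaustive enumeration of every local alignment path (tiny inputs only)."""
    best = 0.0

    def extend(i, j, score, state):
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, score + sub[(a[i], b[j])], "M")
        if i < len(a):
            cost = gap_extend if state == "A" else gap_open + gap_extend
            extend(i + 1, j, score - cost, "A")
        if j < len(b):
            cost = gap_extend if state == "B" else gap_open + gap_extend
            extend(i, j + 1, score - cost, "B")

    for i in range(len(a)):
        for j in range(len(b)):
            extend(i + 1, j + 1, sub[(a[i], b[j])], "M")
    return best
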