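"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's alignment/graph code paths: the
aligner oracle is a direct Gotoh affine-gap dynamic program, and the
component oracle is a plain union-find.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = {c: i for i, c in enumerate(str(_B62.alphabet))}


def sw_affine_bruteforce(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith-Waterman optimal local score, affine gaps costing open+extend*L.

    Plain O(mn) Gotoh recurrence with a zero floor; independent of any
    library aligner.
    """
    a = a.replace("U", "C")
    b = b.replace("U", "C")
    m, n = len(a), len(b)
    NEG = -10**9
    best = 0
    # H: best ending in match; E: gap in b (horizontal); F: gap in a (vertical)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - open_cost)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - open_cost)
            s = _B62[_ALPHA[a[i - 1]], _ALPHA[b[j - 1]]]
            H[i][j] = max(0, H[i - 1][j - 1] + int(s), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def ka_bits_evalue(raw: int, lam: float, kappa: float, m: int, n: int):
    """Scalar recomputation of the Karlin-Altschul transform."""
    bits = (lam * raw - math.log(kappa)) / math.log(2)
    return bits, m * n * 2.0 ** (-bits)


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return {frozenset(v) for v in out.values()}


def group_a_rule_oracle(domains: set[str]) -> str:
    """Independent restatement of the Group A downstream-domain rules."""
    d = {x.lower() for x in domains}
    glt = {"glta", "gltd", "glutamate synthase small subunit",
           "putative oxidoreductase"}
    if "nuof" in d:
        return "A3"
    if d & glt:
        return "A2"
    if "hycb" in d:
        return "A4"
    return "A1"
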