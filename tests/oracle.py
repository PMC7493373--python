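"""Independent brute-force oracles used to cross-check the package.

Everything here recomputes results from first principles on the naive sorted
suffix list — no code is shared with the implementation under test.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
AMBIG = {c for c, s in IUPAC.items() if len(s) > 1}


def naive_index(seqs: list[str], r: int):
    """Sort all suffixes of the marker-terminated sequences by brute force.

    Marker of sequence j is the token (0, j) (distinct markers, ordered by
    sequence index, below every base token (1, c)).  Returns
    (ebwt string with '#' markers, da list, lcp list of length N+1 laid out so
    that lcp[k] is the 1-based lcp[k+1], sorted suffix token lists).
    """
    toks = [[(1, c) for c in s] + [(0, j)] for j, s in enumerate(seqs, 1)]
    entries = []
    for j, t in enumerate(toks, 1):
        for off in range(len(t)):
            entries.append((t[off:], j, off))
    entries.sort(key=lambda e: e[0])
    ebwt, da = [], []
    for suffix, j, off in entries:
        da.append(j)
        prev = toks[j - 1][off - 1] if off > 0 else (0, j)
        ebwt.append("#" if prev[0] == 0 else prev[1])
    lcp = [0]
    for k in range(1, len(entries)):
        a, b = entries[k - 1][0], entries[k][0]
        h = 0
        while h < len(a) and h < len(b) and a[h] == b[h]:
            h += 1
        lcp.append(h)
    lcp.append(0)
    return "".join(ebwt), da, lcp, [e[0] for e in entries]


def brute_clusters(lcp: list[int], da: list[int], r: int, alpha: int):
    """Maximal lcp>=alpha runs filtered by read/genome color mixing (1-based)."""
    n = len(da)
    marked = [False] * (n + 2)  # marked[i] for 1-based i: lcp[i] >= alpha
    for i in range(2, n + 1):
        marked[i] = lcp[i - 1] >= alpha
    clusters = []
    start = 1
    for i in range(2, n + 2):
        if i > n or not marked[i]:
            if i - 1 > start:
                colors = da[start - 1:i - 1]
                if any(c <= r for c in colors) and any(c > r for c in colors):
                    clusters.append((start, i - 1))
            start = i
    return clusters


def brute_delta(left: list[str], right: list[str]) -> int:
    """Exhaustive maximum one-to-one IUPAC pairing between residual symbol lists."""

    def compatible(x, y):
        return (x in AMBIG and y in IUPAC[x]) or (y in AMBIG and x in IUPAC[y])

    def best(li: int, used: frozenset) -> int:
        if li == len(left):
            return 0
        score = best(li + 1, used)
        for k, y in enumerate(right):
            if k not in used and compatible(left[li], y):
                score = max(score, 1 + best(li + 1, used | {k}))
        return score

    return best(0, frozenset())


def brute_similarities(seqs: list[str], r: int, alpha: int):
    """Both measures for every (read, genome) pair, recomputed from scratch.

    Returns (ebwt_raw, da_raw) as dicts keyed by 1-based (i, j).
    """
    ebwt, da, lcp, _ = naive_index(seqs, r)
    clusters = brute_clusters(lcp, da, r, alpha)
    m = len(seqs)
    s_ebwt = {(i, j): 0 for i in range(1, r + 1) for j in range(r + 1, m + 1)}
    s_da = dict(s_ebwt)
    for pS, pE in clusters:
        block = [(da[p], ebwt[p]) for p in range(pS - 1, pE)]
        for i in range(1, r + 1):
            syms_i = [c for col, c in block if col == i]
            for j in range(r + 1, m + 1):
                syms_j = [c for col, c in block if col == j]
                s_da[(i, j)] += min(len(syms_i), len(syms_j))
                exact = 0
                rest_i, rest_j = list(syms_i), list(syms_j)
                for a in set(syms_i) | set(syms_j):
                    k = min(rest_i.count(a), rest_j.count(a))
                    exact += k
                    for _ in range(k):
                        rest_i.remove(a)
                        rest_j.remove(a)
                rest_i = [c for c in rest_i if c != "#"]
                rest_j = [c for c in rest_j if c != "#"]
                s_ebwt[(i, j)] += exact + brute_delta(rest_i, rest_j)
    return s_ebwt, s_da


def brute_substring_count(seqs: list[str], pattern: str) -> int:
    """Overlapping occurrence count of an exact pattern across all sequences."""
    return sum(
        sum(1 for p in range(len(s) - len(pattern) + 1) if s[p:p + len(pattern)] == pattern)
        for s in seqs
    )


def random_collection(rng: np.random.Generator, max_seqs: int = 5, max_len: int = 30,
                      iupac_rate: float = 0.1):
    """A random small collection with occasional ambiguity codes; returns (seqs, r)."""
    m = int(rng.integers(2, max_seqs + 1))
    r = int(rng.integers(1, m))
    alphabet = "ACGT"
    codes = "RYSWKMBDHVN"
    seqs = []
    for _ in range(m):
        length = int(rng.integers(1, max_len + 1))
        chars = [
            codes[int(rng.integers(0, len(codes)))]
            if rng.random() < iupac_rate else alphabet[int(rng.integers(0, 4))]
            for _ in range(length)
        ]
        seqs.append("".join(chars))
    return seqs, r
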