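"""Step 1: alpha-cluster detection by one sequential scan of LCP and document arrays.

An alpha-cluster is a maximal block (pS, pE) of eBWT positions whose sorted
suffixes all share a common context (prefix) of length >= alpha — that is,
lcp[pS] < alpha, lcp[pE+1] < alpha and lcp[i] >= alpha for pS < i <= pE — and
which mixes colors from both sides of the read/genome split (some da[s] <= r
and some da[t] > r).  Blocks whose symbols all come from reads only, or from
genomes only, carry no read-vs-genome information and are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .ebwt_core import END_MARKER, EBWTIndex


@dataclass(frozen=True)
class ClusterParams:
    """alpha: minimum shared-context length; must be >= 1."""

    alpha: int

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be a positive integer")


@dataclass(frozen=True)
class AlphaCluster:
    """Maximal mixed-color LCP>=alpha block, 1-based inclusive [pS, pE]."""

    pS: int
    pE: int

    @property
    def size(self) -> int:
        return self.pE - self.pS + 1


@dataclass(frozen=True)
class ClusterProfile:
    """Per-color symbol counts of one cluster.

    ``occ[(i, a)]`` counts symbol ``a`` of sequence (color) ``i`` inside the
    cluster; end-marker positions are tallied under the reserved '#' symbol.
    ``totals[i]`` is the per-color position count (markers included), i.e. the
    quantity the document-array similarity measure uses.
    """

    occ: dict[tuple[int, str], int]
    totals: dict[int, int]

    def symbols_of(self, color: int) -> Counter:
        return Counter({a: c for (i, a), c in self.occ.items() if i == color})


def detect_alpha_clusters(index: EBWTIndex, params: ClusterParams) -> list[AlphaCluster]:
    """Detect all alpha-clusters in increasing pS order.

    Single streaming pass over lcp/da with O(1) state per open run: run start
    plus seen-read / seen-genome flags.  Returned clusters are pairwise
    disjoint and maximal by construction.
    """
    if index.r < 1 or index.g < 1:
        raise ValueError("index must contain at least one read and one genome")
    alpha = params.alpha
    r = index.r
    lcp = index.lcp.tolist()  # lcp[k] = 1-based lcp[k+1]
    da = index.da.tolist()
    n = index.N

    out: list[AlphaCluster] = []
    start = 1
    has_read = da[0] <= r
    has_genome = da[0] > r
    for i in range(2, n + 2):  # i is the 1-based lcp position closing/extending a run
        if i <= n and lcp[i - 1] >= alpha:
            color = da[i - 1]
            has_read = has_read or color <= r
            has_genome = has_genome or color > r
        else:
            if i - 1 > start and has_read and has_genome:
                out.append(AlphaCluster(start, i - 1))
            if i <= n:
                start = i
                color = da[i - 1]
                has_read = color <= r
                has_genome = color > r
    return out


def profile_cluster(index: EBWTIndex, cluster: AlphaCluster) -> ClusterProfile:
    """Tally the cluster's positions by (color, symbol).

    End-marker symbols are counted under '#'; the totals include them, so that
    ``sum_a occ[(i, a)] == totals[i]`` and ``sum_i totals[i]`` equals the
    cluster size.
    """
    if not (1 <= cluster.pS <= cluster.pE <= index.N):
        raise ValueError(f"cluster ({cluster.pS}, {cluster.pE}) outside [1, {index.N}]")
    occ: Counter = Counter()
    totals: Counter = Counter()
    for p in range(cluster.pS - 1, cluster.pE):
        color = int(index.da[p])
        occ[(color, index.ebwt[p])] += 1
        totals[color] += 1
    return ClusterProfile(occ=dict(occ), totals=dict(totals))


def clusters_to_tsv(index: EBWTIndex, clusters: list[AlphaCluster]) -> str:
    """Diagnostic TSV dump: pS, pE, size and per-color totals of each cluster."""
    lines = ["pS\tpE\tsize\tcolor_totals"]
    for c in clusters:
        prof = profile_cluster(index, c)
        totals = ",".join(f"{i}:{n}" for i, n in sorted(prof.totals.items()))
        lines.append(f"{c.pS}\t{c.pE}\t{c.size}\t{totals}")
    return "\n".join(lines) + "\n"
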