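"""Step 2: cluster-based read-vs-genome similarity and normalized similarity matrices.

Two measures are accumulated over all alpha-clusters:

* eBWT measure — per cluster, the number of exact per-symbol matches between
  the read's and the genome's symbols (sum over symbols of the minimum of the
  two occurrence counts) plus ``delta_IUPAC``, the number of extra one-to-one
  pairings between a residual ambiguity code on one side and a residual
  concrete base of its code set on the other.
* DA measure — per cluster, the minimum of the two sequences' symbol totals,
  ignoring symbol identity (only the document array is consulted).

Both are normalized by ``min(n_i, n_j) + 1 - alpha``, the maximum number of
length->=alpha contexts the shorter sequence can contribute, which bounds the
raw scores and maps them into [0, 1].

End-markers take part in the exact-match phase as one shared symbol (a read
suffix and a genome suffix preceded by their respective markers in the same
cluster count as a match) but never in the ambiguity-code phase.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow

from .cluster_detect import AlphaCluster, ClusterProfile, profile_cluster
from .ebwt_core import AMBIGUITY_CODES, END_MARKER, EBWTIndex, IUPAC_BASES

MatrixRole = Literal["1F", "1RC", "2F", "2RC", "F", "RC"]
Measure = Literal["eBWT", "DA"]


def _compatible(x: str, y: str) -> bool:
    """One side is an ambiguity code and the other a concrete base of its set."""
    return (x in AMBIGUITY_CODES and y in IUPAC_BASES[x]) or (
        y in AMBIGUITY_CODES and x in IUPAC_BASES[y]
    )


def delta_iupac(read_counts: Counter | dict, genome_counts: Counter | dict) -> int:
    """Maximum one-to-one ambiguity-code pairings between two residual multisets.

    Inputs are the residual per-symbol counts of one cluster after the exact
    per-symbol min-matching has been removed.  Computed as an integral maximum
    flow on the small bipartite symbol graph, so the result is deterministic
    and order-independent (a greedy pairing could undercount when two codes
    compete for the same bases).
    """
    left = [(a, int(c)) for a, c in read_counts.items() if c and a != END_MARKER]
    right = [(b, int(c)) for b, c in genome_counts.items() if c and b != END_MARKER]
    if any(c < 0 for _, c in left + right):
        raise ValueError("negative residual count")
    edges = [
        (i, j) for i, (a, _) in enumerate(left) for j, (b, _) in enumerate(right)
        if _compatible(a, b)
    ]
    if not edges:
        return 0
    # nodes: 0 = source, 1..L = read symbols, L+1..L+R = genome symbols, last = sink
    n_l, n_r = len(left), len(right)
    src, snk = 0, n_l + n_r + 1
    rows, cols, caps = [], [], []
    for i, (_, c) in enumerate(left):
        rows.append(src); cols.append(1 + i); caps.append(c)
    for j, (_, c) in enumerate(right):
        rows.append(1 + n_l + j); cols.append(snk); caps.append(c)
    big = sum(c for _, c in left) + 1
    for i, j in edges:
        rows.append(1 + i); cols.append(1 + n_l + j); caps.append(big)
    graph = csr_matrix((caps, (rows, cols)), shape=(snk + 1, snk + 1), dtype=np.int32)
    return int(maximum_flow(graph, src, snk).flow_value)


def _check_pair(profile_r: int, profile_g: int, r: int) -> None:
    if not (1 <= profile_r <= r < profile_g):
        raise ValueError(
            f"expected read color <= {r} < genome color, got ({profile_r}, {profile_g})"
        )


def ebwt_cluster_similarity(profile: ClusterProfile, read_color: int,
                            genome_color: int, r: int) -> int:
    """Per-cluster eBWT-measure contribution for one (read, genome) pair."""
    _check_pair(read_color, genome_color, r)
    ci = profile.symbols_of(read_color)
    cj = profile.symbols_of(genome_color)
    exact = 0
    resid_i: Counter = Counter()
    resid_j: Counter = Counter()
    for a in set(ci) | set(cj):
        matched = min(ci[a], cj[a])
        exact += matched
        if a != END_MARKER:
            resid_i[a] = ci[a] - matched
            resid_j[a] = cj[a] - matched
    return exact + delta_iupac(resid_i, resid_j)


def da_cluster_similarity(profile: ClusterProfile, read_color: int,
                          genome_color: int, r: int) -> int:
    """Per-cluster DA-measure contribution: min of the two symbol totals."""
    _check_pair(read_color, genome_color, r)
    return min(profile.totals.get(read_color, 0), profile.totals.get(genome_color, 0))


@dataclass
class SimilarityMatrix:
    """Normalized r x g similarity scores for one read-orientation role."""

    role: str
    read_ids: tuple[str, ...]
    genome_ids: tuple[str, ...]
    raw: np.ndarray      # integer accumulators
    denom: np.ndarray    # min(n_i, n_j) + 1 - alpha per entry
    values: np.ndarray   # raw / denom, clipped to 0 where denom <= 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape

    def to_tsv(self) -> str:
        lines = ["read_id\t" + "\t".join(self.genome_ids)]
        for i, rid in enumerate(self.read_ids):
            lines.append(rid + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]))
        return "\n".join(lines) + "\n"


def _validate_clusters(index: EBWTIndex, clusters: list[AlphaCluster], alpha: int) -> None:
    for c in clusters:
        if not (1 <= c.pS <= c.pE <= index.N):
            raise ValueError(f"cluster ({c.pS}, {c.pE}) outside [1, {index.N}]")
        if index.lcp_at(c.pS) >= alpha or index.lcp_at(c.pE + 1) >= alpha:
            raise ValueError(
                f"cluster ({c.pS}, {c.pE}) is not maximal for alpha={alpha}; "
                "was it detected with a different alpha?"
            )


def build_similarity_matrix(index: EBWTIndex, clusters: list[AlphaCluster],
                            measure: Measure, alpha: int, role: str) -> SimilarityMatrix:
    """Accumulate the chosen per-cluster measure over all clusters into an r x g matrix.

    ``raw[i][k]`` sums the per-cluster similarity between read color i+1 and
    genome color r+k+1; ``values = raw / (min(n_i, n_{r+k}) + 1 - alpha)``.
    Accumulation order does not affect the result.  An empty cluster list
    yields the zero matrix.
    """
    if measure not in ("eBWT", "DA"):
        raise ValueError(f"unknown measure {measure!r}")
    _validate_clusters(index, clusters, alpha)
    r, g = index.r, index.g
    raw = np.zeros((r, g), dtype=np.int64)
    for cluster in clusters:
        prof = profile_cluster(index, cluster)
        read_colors = [c for c in prof.totals if c <= r]
        genome_colors = [c for c in prof.totals if c > r]
        for i in read_colors:
            for j in genome_colors:
                if measure == "DA":
                    raw[i - 1, j - r - 1] += da_cluster_similarity(prof, i, j, r)
                else:
                    raw[i - 1, j - r - 1] += ebwt_cluster_similarity(prof, i, j, r)
    lengths = np.asarray(index.lengths, dtype=np.int64)
    denom = np.minimum.outer(lengths[:r], lengths[r:]) + 1 - alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, raw / np.maximum(denom, 1), 0.0)
    return SimilarityMatrix(
        role=role,
        read_ids=index.ids[:r],
        genome_ids=index.ids[r:],
        raw=raw,
        denom=denom,
        values=values,
    )
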