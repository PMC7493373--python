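"""End-to-end wiring: role indexes -> clusters -> similarity matrices -> assignments.

Read strand orientation is unknown, so each mate set is indexed together with
the genome set both forward and reverse-complemented.  Single-end data yields
two role matrices (F, RC); paired-end data yields four (1F, 1RC, 2F, 2RC).
Each role index is built independently over (oriented reads) ∪ genomes.
"""

from __future__ import annotations

from typing import Sequence

from .classify import ClassifyParams, ReadAssignment, classify_reads
from .cluster_detect import ClusterParams, detect_alpha_clusters
from .ebwt_core import build_index, make_collection, reverse_complement
from .similarity import Measure, SimilarityMatrix, build_similarity_matrix
from .taxonomy import GenomeTaxonMap, TaxonomyTree

Records = Sequence[tuple[str, str]]


def _strip_mate_suffix(rid: str) -> str:
    return rid[:-2] if rid.endswith(("/1", "/2")) else rid


def _role_reads(mate1: Records, mate2: Records | None) -> dict[str, list[tuple[str, str]]]:
    m1 = [(_strip_mate_suffix(i), s) for i, s in mate1]
    if mate2 is None:
        return {
            "F": m1,
            "RC": [(i, reverse_complement(s)) for i, s in m1],
        }
    m2 = [(_strip_mate_suffix(i), s) for i, s in mate2]
    ids1 = [i for i, _ in m1]
    ids2 = [i for i, _ in m2]
    if ids1 != ids2:
        raise ValueError("mate files do not pair 1:1 (ids differ after /1,/2 stripping)")
    return {
        "1F": m1,
        "1RC": [(i, reverse_complement(s)) for i, s in m1],
        "2F": m2,
        "2RC": [(i, reverse_complement(s)) for i, s in m2],
    }


def compute_matrices(mate1: Records, mate2: Records | None, genomes: Records,
                     alpha: int, measure: Measure = "eBWT") -> dict[str, SimilarityMatrix]:
    """Build one eBWT index per orientation role and accumulate its similarity matrix."""
    matrices: dict[str, SimilarityMatrix] = {}
    for role, reads in _role_reads(mate1, mate2).items():
        index = build_index(make_collection(reads, genomes))
        clusters = detect_alpha_clusters(index, ClusterParams(alpha))
        matrices[role] = build_similarity_matrix(index, clusters, measure, alpha, role)
    return matrices


def run_classification(mate1: Records, mate2: Records | None, genomes: Records,
                       tree: TaxonomyTree, gmap: GenomeTaxonMap, alpha: int = 16,
                       measure: Measure = "eBWT",
                       params: ClassifyParams | None = None,
                       ) -> tuple[list[ReadAssignment], dict[str, SimilarityMatrix]]:
    """Full pipeline over in-memory records; returns assignments and role matrices."""
    mode = "single" if mate2 is None else "paired"
    if params is None:
        params = ClassifyParams(mode=mode)
    elif params.mode != mode:
        raise ValueError(f"params.mode={params.mode!r} inconsistent with inputs ({mode})")
    matrices = compute_matrices(mate1, mate2, genomes, alpha, measure)
    assignments = classify_reads(matrices, tree, gmap, params)
    return assignments, matrices
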