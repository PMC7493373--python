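"""Step 3: assign each read (or read pair) to a taxon from its similarity-matrix rows.

Three phases, applied per read:

1. Take the overall maximum normalized score M across all role matrices.  If
   M <= beta the read is not classified.  Otherwise collect every genome that
   comes within ``tolerance`` of M in at least one role; if they all reduce to
   one taxonomic unit at the minimum rank, classify.
2. Otherwise re-examine only those candidates using mate-pair sums (forward of
   one mate with reverse complement of the other, taking the strand pairing
   that gives the maximum, never the sum of all four).  A unique unit within
   tolerance of the best sum classifies the pair.
3. Otherwise repeat the mate-sum maximization over ALL genomes.  A read still
   tied across units is ambiguous — unless lineage fallback is enabled, in
   which case the tied genomes' lowest common rank at or below phylum is
   assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix
from .taxonomy import GenomeTaxonMap, TaxonomyTree, common_taxon

PAIRED_ROLES = ("1F", "1RC", "2F", "2RC")
SINGLE_ROLES = ("F", "RC")


@dataclass(frozen=True)
class ClassifyParams:
    beta: float = 0.25
    tolerance: float = 0.02
    min_rank: str = "species"
    mode: str = "paired"
    fallback: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.mode not in ("single", "paired"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def roles(self) -> tuple[str, ...]:
        return PAIRED_ROLES if self.mode == "paired" else SINGLE_ROLES


@dataclass
class CandidateSet:
    """Genomes within tolerance of the overall maximum M for one read."""

    M: float
    indices: tuple[int, ...]            # 0-based genome column indices
    per_role_max: dict[str, float]


@dataclass
class ReadAssignment:
    read_id: str
    status: str                         # classified | ambiguous | not_classified
    taxid: int | None = None
    rank: str | None = None
    score: float = 0.0
    phase: str | None = None            # 1 | 2 | 3 | fallback
    tied: tuple[int, ...] = field(default_factory=tuple)  # tied taxids when ambiguous


def _resolve(tree: TaxonomyTree, genome_taxids: list[int], indices, min_rank: str):
    return common_taxon(tree, {genome_taxids[q] for q in indices}, min_rank, fallback=False)


def phase1(read_id: str, rows: dict[str, np.ndarray], params: ClassifyParams,
           tree: TaxonomyTree, genome_taxids: list[int]) -> ReadAssignment | CandidateSet:
    """Per-matrix maxima with tolerance; classify, reject, or emit candidates."""
    shapes = {v.shape for v in rows.values()}
    if len(shapes) != 1:
        raise ValueError("matrix rows have inconsistent shapes across roles")
    per_role_max = {x: float(np.max(row)) for x, row in rows.items()}
    m_i = max(per_role_max.values())
    if m_i <= params.beta:
        return ReadAssignment(read_id, "not_classified", score=m_i)
    in_tol = set()
    for row in rows.values():
        in_tol.update(np.nonzero(row >= m_i - params.tolerance)[0].tolist())
    indices = tuple(sorted(in_tol))
    unit = _resolve(tree, genome_taxids, indices, params.min_rank)
    if unit is not None:
        return ReadAssignment(read_id, "classified", unit[0], unit[1], m_i, "1")
    return CandidateSet(M=m_i, indices=indices, per_role_max=per_role_max)


def paired_sum(rows: dict[str, np.ndarray], j: int, mode: str) -> float:
    """Mate-combined score for genome column j.

    Paired mode: the better of the two strand pairings 1F+2RC and 1RC+2F.
    Single mode: the better of the forward and reverse-complement scores.
    """
    if mode == "paired":
        missing = [x for x in PAIRED_ROLES if x not in rows]
        if missing:
            raise ValueError(f"paired mode needs all four role matrices; missing {missing}")
        return max(
            float(rows["1F"][j]) + float(rows["2RC"][j]),
            float(rows["1RC"][j]) + float(rows["2F"][j]),
        )
    return max(float(rows["F"][j]), float(rows["RC"][j]))


def _sum_phase(read_id: str, rows, candidates: tuple[int, ...], params: ClassifyParams,
               tree, genome_taxids, phase: str) -> ReadAssignment | tuple[float, tuple[int, ...]]:
    """Shared core of phases 2 and 3: maximize mate sums over a candidate pool."""
    if not candidates:
        raise ValueError("empty candidate set")
    sums = {j: paired_sum(rows, j, params.mode) for j in candidates}
    best = max(sums.values())
    kept = tuple(sorted(j for j, s in sums.items() if s >= best - params.tolerance))
    unit = _resolve(tree, genome_taxids, kept, params.min_rank)
    if unit is not None:
        return ReadAssignment(read_id, "classified", unit[0], unit[1], best, phase)
    return best, kept


def phase2(read_id: str, candidates: CandidateSet, rows, params: ClassifyParams,
           tree, genome_taxids) -> ReadAssignment | CandidateSet:
    result = _sum_phase(read_id, rows, candidates.indices, params, tree, genome_taxids, "2")
    if isinstance(result, ReadAssignment):
        return result
    best, kept = result
    return CandidateSet(M=best, indices=kept, per_role_max=candidates.per_role_max)


def phase3(read_id: str, rows, params: ClassifyParams, tree,
           genome_taxids) -> ReadAssignment:
    all_genomes = tuple(range(len(genome_taxids)))
    result = _sum_phase(read_id, rows, all_genomes, params, tree, genome_taxids, "3")
    if isinstance(result, ReadAssignment):
        return result
    best, kept = result
    tied_taxids = tuple(sorted({genome_taxids[q] for q in kept}))
    if params.fallback:
        unit = common_taxon(tree, set(tied_taxids), params.min_rank, fallback=True)
        if unit is not None:
            return ReadAssignment(read_id, "classified", unit[0], unit[1], best, "fallback")
    return ReadAssignment(read_id, "ambiguous", score=best, tied=tied_taxids)


def classify_reads(matrices: dict[str, SimilarityMatrix], tree: TaxonomyTree,
                   gmap: GenomeTaxonMap, params: ClassifyParams) -> list[ReadAssignment]:
    """Run phases 1 -> 2 -> 3 for every read; one assignment per read (pair)."""
    roles = params.roles
    missing = [x for x in roles if x not in matrices]
    if missing:
        raise ValueError(f"missing similarity matrices for roles {missing}")
    shapes = {matrices[x].shape for x in roles}
    if len(shapes) != 1:
        raise ValueError("similarity matrices differ in shape across roles")
    ref = matrices[roles[0]]
    unmapped = [gid for gid in ref.genome_ids if gid not in gmap]
    if unmapped:
        raise ValueError(f"genomes not in taxon map: {unmapped}")
    genome_taxids = [gmap[gid] for gid in ref.genome_ids]

    out: list[ReadAssignment] = []
    for i, read_id in enumerate(ref.read_ids):
        rows = {x: matrices[x].values[i] for x in roles}
        res = phase1(read_id, rows, params, tree, genome_taxids)
        if isinstance(res, CandidateSet):
            res = phase2(read_id, res, rows, params, tree, genome_taxids)
        if isinstance(res, CandidateSet):
            res = phase3(read_id, rows, params, tree, genome_taxids)
        out.append(res)
    return out


_STATUS_CODE = {"classified": "C", "ambiguous": "A", "not_classified": "U"}
_CODE_STATUS = {v: k for k, v in _STATUS_CODE.items()}


def assignments_to_tsv(assignments: list[ReadAssignment]) -> str:
    """TSV export: read_id, status C/A/U, taxid (0 when absent), rank, score, phase, tied."""
    lines = ["read_id\tstatus\ttaxid\trank\tscore\tphase\ttied"]
    for a in assignments:
        lines.append(
            f"{a.read_id}\t{_STATUS_CODE[a.status]}\t{a.taxid or 0}\t{a.rank or '-'}"
            f"\t{a.score:.6f}\t{a.phase or '-'}\t{','.join(map(str, a.tied)) or '-'}"
        )
    return "\n".join(lines) + "\n"


def assignments_from_tsv(text: str) -> list[ReadAssignment]:
    lines = text.strip().split("\n")
    out = []
    for line in lines[1:]:
        rid, code, taxid, rank, score, phase, tied = line.split("\t")
        out.append(ReadAssignment(
            read_id=rid, status=_CODE_STATUS[code],
            taxid=int(taxid) or None, rank=None if rank == "-" else rank,
            score=float(score), phase=None if phase == "-" else phase,
            tied=tuple(int(t) for t in tied.split(",")) if tied != "-" else (),
        ))
    return out
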