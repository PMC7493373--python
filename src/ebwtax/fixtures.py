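"""Synthetic inputs: the built-in worked example, toy taxonomies, simulated genomes,
paired-end reads with substitution errors, and shuffled negative controls.

The read simulator emulates the structure of the benchmark datasets the
classifier targets: Illumina-style paired-end reads of length 100 in FR
orientation (mate 1 forward, mate 2 the reverse complement of the downstream
fragment end), a substitution-only error model, and negative controls built by
randomly permuting real reads so that base composition is preserved while all
long shared contexts are destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ebwt_core import Collection, make_collection, reverse_complement
from .taxonomy import GenomeTaxonMap, TaxonomyNode, TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def running_example() -> tuple[Collection, dict]:
    """The three-sequence worked example: one read, two genomes, one IUPAC code.

    Returns the collection {S1=GGCGTACCA (read), S2=GGGGCGTAT, S3=ACGARTACGAC}
    together with the hand-checkable expectations: the 2-cluster list, the
    per-pair raw and normalized similarities under both measures, and the two
    substring counts used to illustrate the suffix-range property.
    """
    collection = make_collection(
        reads=[("S1", "GGCGTACCA")],
        genomes=[("S2", "GGGGCGTAT"), ("S3", "ACGARTACGAC")],
    )
    expected = {
        "alpha": 2,
        "N": 32,
        "clusters": [(5, 8), (14, 17), (20, 21), (22, 25), (26, 27), (30, 32)],
        "lcp_17": 4,
        "raw_ebwt": {("S1", "S2"): 5, ("S1", "S3"): 2},
        "raw_da": {("S1", "S2"): 5, ("S1", "S3"): 3},
        "norm_ebwt": {("S1", "S2"): 0.625, ("S1", "S3"): 0.250},
        "norm_da": {("S1", "S2"): 0.625, ("S1", "S3"): 0.375},
        "per_cluster_ebwt": {("S1", "S2"): [0, 1, 1, 1, 1, 1], ("S1", "S3"): [1, 0, 0, 0, 0, 1]},
        "per_cluster_da": {("S1", "S2"): [0, 1, 1, 1, 1, 1], ("S1", "S3"): [1, 1, 0, 0, 0, 1]},
        "substring_counts": {"GT": 2, "T": 4},
    }
    return collection, expected


@dataclass(frozen=True)
class SimParams:
    """Simulation settings; defaults mirror the classifier's target data scale
    at desk size: 100 bp paired-end reads from kilobase-scale genomes."""

    n_genomes: int = 5
    genome_length: int = 10_000
    n_read_pairs: int = 500
    read_length: int = 100
    insert_size: int = 300
    substitution_rate: float = 0.01
    n_negative: int = 100
    seed: int = 0
    same_species_pairs: int = 0  # leading genome pairs sharing one species

    def __post_init__(self) -> None:
        if min(self.n_genomes, self.genome_length, self.read_length) < 1:
            raise ValueError("degenerate sizes")
        if not self.read_length <= self.insert_size <= self.genome_length:
            raise ValueError("need read_length <= insert_size <= genome_length")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.same_species_pairs * 2 > self.n_genomes:
            raise ValueError("too many same-species pairs for n_genomes")


@dataclass
class ReferenceSet:
    genomes: list[tuple[str, str]]           # (genome_id, sequence)
    nodes: list[TaxonomyNode]
    gmap: GenomeTaxonMap
    species_of: dict[str, int]               # genome_id -> species taxid

    @property
    def tree(self) -> TaxonomyTree:
        return TaxonomyTree(self.nodes)


def simulate_reference_set(params: SimParams) -> ReferenceSet:
    """i.i.d. uniform A/C/G/T genomes under a toy taxonomy.

    Taxids: root=1 (no_rank), phylum=2, genus 100+k, species 200+k, genome
    leaves 300+j.  The first ``same_species_pairs`` pairs of genomes share a
    species; every remaining genome gets its own.  Two consecutive species
    share a genus, so genus-level lineage fallback is exercisable.
    """
    rng = np.random.default_rng(params.seed)
    genomes = []
    for j in range(params.n_genomes):
        seq = _BASES[rng.integers(0, 4, size=params.genome_length)].tobytes().decode()
        genomes.append((f"genome_{j}", seq))

    p = params.same_species_pairs
    species_idx = [j // 2 if j < 2 * p else j - p for j in range(params.n_genomes)]
    n_species = max(species_idx) + 1
    nodes = [
        TaxonomyNode(1, 1, "no_rank", "root"),
        TaxonomyNode(2, 1, "phylum", "phylum_0"),
    ]
    for k in range(n_species):
        genus = 100 + k // 2
        if k % 2 == 0:
            nodes.append(TaxonomyNode(genus, 2, "genus", f"genus_{k // 2}"))
        nodes.append(TaxonomyNode(200 + k, genus, "species", f"species_{k}"))
    gmap: GenomeTaxonMap = {}
    species_of: dict[str, int] = {}
    for j, (gid, _) in enumerate(genomes):
        nodes.append(TaxonomyNode(300 + j, 200 + species_idx[j], "genome", gid))
        gmap[gid] = 300 + j
        species_of[gid] = 200 + species_idx[j]
    return ReferenceSet(genomes=genomes, nodes=nodes, gmap=gmap, species_of=species_of)


@dataclass
class TruthRow:
    read_id: str
    genome_id: str
    species_taxid: int
    is_random: bool


@dataclass
class SimulatedReads:
    mate1: list[tuple[str, str]]
    mate2: list[tuple[str, str]]
    truth: list[TruthRow]


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_paired_reads(reference: ReferenceSet, params: SimParams) -> SimulatedReads:
    """FR-orientation paired reads from uniformly chosen genomes and loci.

    Mate 1 is the forward fragment prefix; mate 2 the reverse complement of
    the fragment's last ``read_length`` bases at ``insert_size``.  Each base
    is substituted with a different uniform base at ``substitution_rate``.
    """
    rng = np.random.default_rng(params.seed + 1)
    # separate stream for the error model so that locus choice is identical
    # across substitution rates (same seed, different rate => aligned reads)
    err_rng = np.random.default_rng(params.seed + 1001)
    mate1, mate2, truth = [], [], []
    for k in range(params.n_read_pairs):
        j = int(rng.integers(0, len(reference.genomes)))
        gid, gseq = reference.genomes[j]
        if params.insert_size > len(gseq):
            raise ValueError(f"insert {params.insert_size} exceeds genome length {len(gseq)}")
        start = int(rng.integers(0, len(gseq) - params.insert_size + 1))
        frag = gseq[start:start + params.insert_size]
        m1 = _substitute(frag[: params.read_length], params.substitution_rate, err_rng)
        m2 = _substitute(reverse_complement(frag[-params.read_length:]),
                         params.substitution_rate, err_rng)
        rid = f"pair_{k}"
        mate1.append((f"{rid}/1", m1))
        mate2.append((f"{rid}/2", m2))
        truth.append(TruthRow(rid, gid, reference.species_of[gid], False))
    return SimulatedReads(mate1=mate1, mate2=mate2, truth=truth)


def simulate_negative_control(reads: Sequence[tuple[str, str]], n: int, seed: int,
                              with_replacement: bool = False) -> list[tuple[str, str]]:
    """Shuffled copies of source reads: composition preserved, order destroyed."""
    if n > len(reads) and not with_replacement:
        raise ValueError(f"requested {n} controls from {len(reads)} source reads")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        src_id, src_seq = reads[int(rng.integers(0, len(reads))) if with_replacement else k]
        shuffled = "".join(rng.permutation(list(src_seq)))
        out.append((f"neg_{k}_{src_id}", shuffled))
    return out


def add_negative_pairs(sim: SimulatedReads, params: SimParams) -> SimulatedReads:
    """Append shuffled negative-control pairs (both mates permuted) to a batch."""
    neg1 = simulate_negative_control(sim.mate1, params.n_negative, params.seed + 2,
                                     with_replacement=True)
    neg2 = simulate_negative_control(sim.mate2, params.n_negative, params.seed + 3,
                                     with_replacement=True)
    mate1 = list(sim.mate1)
    mate2 = list(sim.mate2)
    truth = list(sim.truth)
    for k, ((_, s1), (_, s2)) in enumerate(zip(neg1, neg2)):
        rid = f"neg_{k}"
        mate1.append((f"{rid}/1", s1))
        mate2.append((f"{rid}/2", s2))
        truth.append(TruthRow(rid, "-", 0, True))
    return SimulatedReads(mate1=mate1, mate2=mate2, truth=truth)


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truth: Sequence[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgenome_id\tspecies_taxid\tis_random\n")
        for row in truth:
            fh.write(f"{row.read_id}\t{row.genome_id}\t{row.species_taxid}\t{int(row.is_random)}\n")
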