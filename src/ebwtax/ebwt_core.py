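"""Core index structures: eBWT, LCP array and document array of a sequence collection.

The extended Burrows-Wheeler transform (eBWT) of a collection S = {S_1, ..., S_m}
is the permutation of the symbols of S obtained by sorting all suffixes of the
(end-marker terminated) sequences lexicographically and taking, for each sorted
suffix, the symbol that circularly precedes it in its own sequence.  Alongside it
we keep the document array ``da`` (the "color" 1..m of the sequence each sorted
suffix belongs to) and the LCP array (length of the longest common prefix of
lexicographically adjacent suffixes).

Conventions
-----------
* Each sequence is terminated by its own distinct end-marker ``$_j``; markers
  sort below every alphabet symbol and among themselves by sequence index, so
  the suffix order is total and construction is deterministic.
* Positions are 1-based in the public contract, matching the usual presentation
  ``ebwt[1..N]``, ``lcp[1..N+1]`` with ``lcp[1] = lcp[N+1] = 0``.  The backing
  numpy arrays are 0-based; ``lcp[k]`` in the array is the 1-based ``lcp[k+1]``.
* In memory and on disk the end-marker is the single printable byte ``#``
  (smaller than every alphabet letter); the distinction between markers is only
  needed during sorting and is never needed afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

END_MARKER = "#"

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Set-wise complement of each code: bases(complement(c)) == {complement(b) for b in bases(c)}.
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

ALPHABET = frozenset(IUPAC_BASES)
AMBIGUITY_CODES = frozenset(c for c, b in IUPAC_BASES.items() if len(b) > 1)

INDEX_FORMAT_VERSION = 1


class CollectionError(ValueError):
    """Raised for malformed input sequences or files."""


class IndexFormatError(ValueError):
    """Raised when serialized index components are missing or inconsistent."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its role in the collection ('read' or 'genome')."""

    id: str
    seq: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("read", "genome"):
            raise CollectionError(f"record {self.id!r}: role must be 'read' or 'genome'")
        if not self.seq:
            raise CollectionError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.seq, 1):
            if ch not in ALPHABET:
                raise CollectionError(
                    f"record {self.id!r}: invalid character {ch!r} at position {pos}"
                )


@dataclass(frozen=True)
class Collection:
    """Ordered sequence collection: reads first (colors 1..r), genomes after (r+1..m)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        roles = [rec.role for rec in self.records]
        r = sum(1 for x in roles if x == "read")
        if roles != ["read"] * r + ["genome"] * (len(roles) - r):
            raise CollectionError("reads must precede genomes in the collection")

    @property
    def r(self) -> int:
        return sum(1 for rec in self.records if rec.role == "read")

    @property
    def g(self) -> int:
        return len(self.records) - self.r

    @property
    def m(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(rec.seq) for rec in self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)


def make_collection(reads: Iterable[tuple[str, str]],
                    genomes: Iterable[tuple[str, str]]) -> Collection:
    """Build a Collection from (id, sequence) pairs; sequences are uppercased."""
    recs = [SequenceRecord(i, s.upper(), "read") for i, s in reads]
    recs += [SequenceRecord(i, s.upper(), "genome") for i, s in genomes]
    if not recs:
        raise CollectionError("empty collection")
    return Collection(tuple(recs))


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line[0] == "@" else "fasta"
    raise CollectionError(f"{path}: empty file")


def _read_records(path: Path) -> list[tuple[str, str]]:
    fmt = _sniff_format(path)
    out = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
    if not out:
        raise CollectionError(f"{path}: no records parsed")
    return out


def load_collection(reads_path: str | Path, genomes_path: str | Path) -> Collection:
    """Load reads (FASTA/FASTQ) and genomes (FASTA) into one collection.

    Reads receive colors 1..r and genomes r+1..m in file order; FASTQ quality
    strings are discarded.
    """
    return make_collection(_read_records(Path(reads_path)), _read_records(Path(genomes_path)))


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; an involution on the full code alphabet."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise CollectionError(f"symbol {exc.args[0]!r} has no complement") from None


@dataclass
class EBWTIndex:
    """eBWT / LCP / document-array triple over a collection of r reads + g genomes.

    Attributes
    ----------
    ebwt : str of length N; end-markers appear as '#'.
    da : uint32 array of length N with colors in 1..m.
    lcp : uint32 array of length N+1; entry k is the 1-based lcp[k+1], so
        ``lcp[0]`` and ``lcp[N]`` are the zero sentinels at positions 1 and N+1.
    """

    ebwt: str
    da: np.ndarray
    lcp: np.ndarray
    r: int
    g: int
    ids: tuple[str, ...]
    lengths: tuple[int, ...]

    @property
    def m(self) -> int:
        return self.r + self.g

    @property
    def N(self) -> int:
        return len(self.ebwt)

    # 1-based accessors matching the written presentation of the arrays.
    def lcp_at(self, i: int) -> int:
        if not 1 <= i <= self.N + 1:
            raise IndexError(f"lcp position {i} outside [1, {self.N + 1}]")
        return int(self.lcp[i - 1])

    def da_at(self, i: int) -> int:
        if not 1 <= i <= self.N:
            raise IndexError(f"da position {i} outside [1, {self.N}]")
        return int(self.da[i - 1])

    def ebwt_at(self, i: int) -> str:
        if not 1 <= i <= self.N:
            raise IndexError(f"ebwt position {i} outside [1, {self.N}]")
        return self.ebwt[i - 1]

    def validate(self) -> None:
        n_expected = sum(self.lengths) + self.m
        if self.N != n_expected:
            raise IndexFormatError(f"N={self.N} but lengths+markers give {n_expected}")
        if len(self.da) != self.N or len(self.lcp) != self.N + 1:
            raise IndexFormatError("component length mismatch")
        if self.lcp[0] != 0 or self.lcp[-1] != 0:
            raise IndexFormatError("LCP sentinels must be zero")
        counts = np.bincount(self.da, minlength=self.m + 1)
        for j in range(1, self.m + 1):
            if counts[j] != self.lengths[j - 1] + 1:
                raise IndexFormatError(
                    f"color {j} occurs {counts[j]} times, expected {self.lengths[j - 1] + 1}"
                )


def _encode(collection: Collection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate marker-terminated sequences into one integer text.

    Marker of sequence j encodes as j (1..m); alphabet symbol c as m + ord(c).
    Because markers are distinct and position-unique, suffixes of the
    concatenation order exactly like the suffixes of the individual terminated
    sequences, and shared prefixes can never extend through a marker.
    """
    m = collection.m
    chunks, colors, offsets = [], [], []
    for j, rec in enumerate(collection.records, 1):
        enc = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8).astype(np.int64) + m
        chunks.append(np.concatenate([enc, [j]]))
        colors.append(np.full(len(rec.seq) + 1, j, dtype=np.int64))
        offsets.append(np.arange(len(rec.seq) + 1, dtype=np.int64))
    return np.concatenate(chunks), np.concatenate(colors), np.concatenate(offsets)


def _suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(N log^2 N) with numpy lexsort)."""
    n = len(text)
    rank = text.copy()
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        r_o, s_o = rank[order], second[order]
        changed = (r_o[1:] != r_o[:-1]) | (s_o[1:] != s_o[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _kasai_lcp(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP of adjacent sorted suffixes (Kasai's algorithm, O(N) total)."""
    n = len(text)
    inv = np.empty(n, dtype=np.int64)
    inv[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    t = text.tolist()  # list indexing is much faster than ndarray scalar access
    sal = sa.tolist()
    h = 0
    for i in range(n):
        ri = inv[i]
        if ri > 0:
            j = sal[ri - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[ri] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def build_index(collection: Collection) -> EBWTIndex:
    """Build the eBWT, document array and LCP array of a collection.

    The contract is the output, not the algorithm: the result is identical to
    naively sorting all suffixes of the marker-terminated sequences with
    distinct markers ordered by sequence index.
    """
    text, colors, offsets = _encode(collection)
    m = collection.m
    sa = _suffix_array(text)
    lcp_core = _kasai_lcp(text, sa)

    da = colors[sa].astype(np.uint32)
    # ebwt[i]: symbol circularly preceding the i-th sorted suffix within its own
    # sequence -- the previous text symbol, or that sequence's marker when the
    # suffix starts at the sequence head.
    prev = np.where(offsets[sa] == 0, -1, text[np.maximum(sa - 1, 0)])
    ebwt_chars = np.where(prev <= m, ord(END_MARKER), prev - m).astype(np.uint8)
    ebwt = ebwt_chars.tobytes().decode("ascii")

    lcp = np.zeros(len(text) + 1, dtype=np.uint32)
    lcp[: len(text)] = lcp_core  # lcp_core[0] is already 0 (position 1 sentinel)

    index = EBWTIndex(
        ebwt=ebwt, da=da, lcp=lcp,
        r=collection.r, g=collection.g,
        ids=collection.ids, lengths=collection.lengths,
    )
    index.validate()
    return index


def count_occurrences(index: EBWTIndex, pattern: str) -> int:
    """Count occurrences of ``pattern`` across the collection by FM backward search.

    Exact symbol matching over the stored alphabet (no IUPAC expansion); every
    occurrence corresponds to one suffix in the pattern's suffix range.
    """
    if not pattern:
        raise ValueError("empty pattern")
    pattern = pattern.upper()
    codes = np.frombuffer(index.ebwt.encode("ascii"), dtype=np.uint8)
    symbols, counts = np.unique(codes, return_counts=True)
    count_of = dict(zip(symbols.tolist(), counts.tolist()))
    # C[c]: number of suffixes starting with a symbol < c (markers are smallest).
    c_table: dict[int, int] = {}
    acc = 0
    for s, c in zip(symbols.tolist(), counts.tolist()):
        c_table[s] = acc
        acc += c
    lo, hi = 0, index.N
    for ch in reversed(pattern):
        code = ord(ch)
        if code not in c_table:
            return 0
        is_c = codes == code
        occ = np.concatenate(([0], np.cumsum(is_c)))
        lo = c_table[code] + int(occ[lo])
        hi = c_table[code] + int(occ[hi])
        if lo >= hi:
            return 0
    return hi - lo


def write_index(index: EBWTIndex, prefix: str | Path) -> None:
    """Serialize the index as <prefix>.ebwt / .da / .lcp / .meta.json.

    ``.ebwt`` is the raw byte string (marker as '#'); ``.da`` and ``.lcp`` are
    little-endian uint32, lengths N and N+1.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}.ebwt").write_bytes(index.ebwt.encode("ascii"))
    index.da.astype("<u4").tofile(f"{prefix}.da")
    index.lcp.astype("<u4").tofile(f"{prefix}.lcp")
    meta = {
        "format_version": INDEX_FORMAT_VERSION,
        "r": index.r, "g": index.g, "m": index.m, "N": index.N,
        "ids": list(index.ids), "lengths": list(index.lengths),
    }
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta, indent=1))


def read_index(prefix: str | Path) -> EBWTIndex:
    """Load an index written by :func:`write_index`, verifying consistency."""
    prefix = Path(prefix)
    for ext in (".ebwt", ".da", ".lcp", ".meta.json"):
        if not Path(f"{prefix}{ext}").exists():
            raise IndexFormatError(f"missing index component {prefix}{ext}")
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    if meta.get("format_version") != INDEX_FORMAT_VERSION:
        raise IndexFormatError(f"unsupported index format version {meta.get('format_version')}")
    ebwt = Path(f"{prefix}.ebwt").read_bytes().decode("ascii")
    da = np.fromfile(f"{prefix}.da", dtype="<u4").astype(np.uint32)
    lcp = np.fromfile(f"{prefix}.lcp", dtype="<u4").astype(np.uint32)
    if len(ebwt) != meta["N"] or len(da) != meta["N"] or len(lcp) != meta["N"] + 1:
        raise IndexFormatError(
            f"component lengths (ebwt={len(ebwt)}, da={len(da)}, lcp={len(lcp)}) "
            f"inconsistent with meta N={meta['N']}"
        )
    index = EBWTIndex(
        ebwt=ebwt, da=da, lcp=lcp,
        r=meta["r"], g=meta["g"],
        ids=tuple(meta["ids"]), lengths=tuple(meta["lengths"]),
    )
    index.validate()
    return index
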