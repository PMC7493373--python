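"""Accuracy metrics against a known truth, and concordance between two classifiers.

Scoring convention at species level: a non-random read counts as TP if its
assignment resolves to its true species, FP if to a wrong species, and FN if
it is unassigned OR assigned above species (higher-rank assignments leave the
species undetermined).  Negative-control (shuffled) reads are scored only for
specificity: TN counts those not assigned to any species.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .classify import ReadAssignment
from .taxonomy import TaxonomyTree, taxon_at_rank


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    t_random: int

    def __post_init__(self) -> None:
        if self.TN > self.t_random:
            raise ValueError("TN cannot exceed the number of negative-control reads")


@dataclass(frozen=True)
class ConcordanceResult:
    t: int       # |A U B|, union of the two classified-read sets
    I_id: int    # |A ∩ B| by read identifier
    I_as: int    # reads in the intersection with identical assigned taxon
    r_id: float
    r_as: float


def load_truth(path: str | Path) -> tuple[dict[str, int], set[str]]:
    """Read a truth TSV (read_id, species_taxid, is_random) -> (truth map, random ids)."""
    truth: dict[str, int] = {}
    random_ids: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rid = row["read_id"]
            if int(row["is_random"]):
                random_ids.add(rid)
            else:
                truth[rid] = int(row["species_taxid"])
    return truth, random_ids


def _assigned_species(a: ReadAssignment, tree: TaxonomyTree) -> int | None:
    """Species-level resolution of an assignment, or None if above species."""
    if a.status != "classified" or a.taxid is None:
        return None
    return taxon_at_rank(tree, a.taxid, "species")


def score_against_truth(assignments: list[ReadAssignment], truth: dict[str, int],
                        random_ids: set[str], tree: TaxonomyTree) -> ConfusionCounts:
    """Confusion counts at species level under the FN-for-higher-rank convention."""
    if not assignments:
        raise ValueError("empty assignment list")
    tp = fp = fn = tn = 0
    for a in assignments:
        if a.read_id in random_ids:
            if _assigned_species(a, tree) is None:
                tn += 1
        elif a.read_id in truth:
            species = _assigned_species(a, tree)
            if species is None:
                fn += 1
            elif species == truth[a.read_id]:
                tp += 1
            else:
                fp += 1
        else:
            raise ValueError(f"read {a.read_id!r} in neither truth nor negative-control set")
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn, t_random=len(random_ids))


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """SEN, PREC, F1, SPEC; a metric with zero denominator is None (undefined)."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "SEN": ratio(counts.TP, counts.TP + counts.FN),
        "PREC": ratio(counts.TP, counts.TP + counts.FP),
        "F1": ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN),
        "SPEC": ratio(counts.TN, counts.t_random),
    }


def _classified_at(assignments: list[ReadAssignment], level: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for a in assignments:
        if a.read_id in out:
            raise ValueError(f"duplicate read id {a.read_id!r}")
        if a.status == "classified" and a.rank == level and a.taxid is not None:
            out[a.read_id] = a.taxid
    # also register non-classified ids for duplicate detection symmetry
    return out


def concordance(a: list[ReadAssignment], b: list[ReadAssignment],
                level: str = "species") -> ConcordanceResult:
    """Jaccard-style agreement of two classifiers' outputs at one rank.

    t = |A U B| where A, B are the read sets each classifier assigned at the
    level; r_id = |A ∩ B| / t and r_as adds the requirement that the assigned
    taxon agree.
    """
    map_a = _classified_at(a, level)
    map_b = _classified_at(b, level)
    union = set(map_a) | set(map_b)
    inter = set(map_a) & set(map_b)
    same = {rid for rid in inter if map_a[rid] == map_b[rid]}
    t = len(union)
    return ConcordanceResult(
        t=t, I_id=len(inter), I_as=len(same),
        r_id=len(inter) / t if t else 0.0,
        r_as=len(same) / t if t else 0.0,
    )


def venn3_counts(a: list[ReadAssignment], b: list[ReadAssignment],
                 c: list[ReadAssignment], level: str = "species") -> dict[str, int]:
    """Three-way region sizes of the classified-read sets (derived report)."""
    sets = [set(_classified_at(x, level)) for x in (a, b, c)]
    sa, sb, sc = sets
    return {
        "a_only": len(sa - sb - sc), "b_only": len(sb - sa - sc), "c_only": len(sc - sa - sb),
        "ab_only": len((sa & sb) - sc), "ac_only": len((sa & sc) - sb),
        "bc_only": len((sb & sc) - sa), "abc": len(sa & sb & sc),
    }


def metrics_report(counts: ConfusionCounts) -> str:
    m = metrics(counts)
    lines = [
        f"TP={counts.TP}\tFP={counts.FP}\tFN={counts.FN}\tTN={counts.TN}\tt_random={counts.t_random}",
    ]
    for key in ("SEN", "PREC", "F1", "SPEC"):
        val = m[key]
        lines.append(f"{key}\t{'undefined' if val is None else f'{val:.4f}'}")
    return "\n".join(lines) + "\n"
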