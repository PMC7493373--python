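import numpy as np
import pytest

from ebwtax.classify import (ClassifyParams, CandidateSet, classify_reads,
                             assignments_from_tsv, assignments_to_tsv,
                             paired_sum, phase1)
from ebwtax.similarity import SimilarityMatrix

GENOMES = ("gA", "gB", "gC", "gD", "gE")  # species 20, 20, 21, 22, 23


def _matrices(rows_by_role, read_ids=("p0",), genome_ids=GENOMES):
    """Build role matrices from {role: list-of-rows}; missing roles are zero."""
    g = len(genome_ids)
    r = len(read_ids)
    out = {}
    roles = set(rows_by_role) | ({"1F", "1RC", "2F", "2RC"}
                                 if any(x in rows_by_role for x in ("1F", "2F", "1RC", "2RC"))
                                 else {"F", "RC"})
    for role in roles:
        vals = np.array(rows_by_role.get(role, np.zeros((r, g))), dtype=float)
        out[role] = SimilarityMatrix(
            role=role, read_ids=read_ids, genome_ids=genome_ids,
            raw=(vals * 100).astype(int), denom=np.full((r, g), 100), values=vals,
        )
    return out


def _run(rows_by_role, toy_tree, **kw):
    tree, gmap = toy_tree
    mode = "paired" if "1F" in rows_by_role else "single"
    params = ClassifyParams(mode=mode, **kw)
    return classify_reads(_matrices(rows_by_role), tree, gmap, params)[0]


class TestPairedSum:
    def test_first_pairing_dominates(self):
        rows = {"1F": np.array([0.5]), "2RC": np.array([0.4]),
                "1RC": np.array([0.1]), "2F": np.array([0.1])}
        assert paired_sum(rows, 0, "paired") == pytest.approx(0.9)

    def test_symmetric_strands(self):
        rows = {x: np.array([0.3]) for x in ("1F", "1RC", "2F", "2RC")}
        assert paired_sum(rows, 0, "paired") == pytest.approx(0.6)

    def test_single_mode_takes_best_strand(self):
        rows = {"F": np.array([0.2]), "RC": np.array([0.7])}
        assert paired_sum(rows, 0, "single") == pytest.approx(0.7)

    def test_missing_mate_matrix_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            paired_sum({"1F": np.array([0.5])}, 0, "paired")


class TestPhase1:
    def test_unique_dominant_genome(self, toy_tree):
        a = _run({"1F": [[0.9, 0.1, 0.1, 0.1, 0.1]]}, toy_tree, beta=0.25)
        assert (a.status, a.taxid, a.rank, a.phase) == ("classified", 20, "species", "1")
        assert a.score == pytest.approx(0.9)

    def test_all_below_threshold(self, toy_tree):
        a = _run({"1F": [[0.25, 0.1, 0.2, 0.1, 0.25]]}, toy_tree, beta=0.25)
        assert a.status == "not_classified"

    def test_two_genomes_of_one_species_within_tolerance(self, toy_tree):
        a = _run({"1F": [[0.80, 0.79, 0.1, 0.1, 0.1]]}, toy_tree, tolerance=0.02)
        assert (a.status, a.taxid, a.phase) == ("classified", 20, "1")

    def test_tolerance_zero_unique_max_classifies_at_genome_rank(self, toy_tree):
        a = _run({"1F": [[0.80, 0.79, 0.1, 0.1, 0.1]]}, toy_tree,
                 tolerance=0.0, min_rank="genome")
        assert (a.status, a.taxid, a.rank, a.phase) == ("classified", 30, "genome", "1")

    def test_shape_mismatch_rejected(self, toy_tree):
        tree, gmap = toy_tree
        rows = {"F": np.zeros(5), "RC": np.zeros(4)}
        with pytest.raises(ValueError, match="shape"):
            phase1("p0", rows, ClassifyParams(mode="single"), tree, list(gmap.values()))


class TestPhases2And3:
    def test_mate_sum_separates_species(self, toy_tree):
        # gA (sp20) and gC (sp21) tie in phase 1; mates break the tie
        a = _run({"1F": [[0.8, 0.0, 0.8, 0.0, 0.0]],
                  "2RC": [[0.4, 0.0, 0.1, 0.0, 0.0]]}, toy_tree)
        assert (a.status, a.taxid, a.phase) == ("classified", 20, "2")

    def test_candidates_of_one_species_classify_in_phase2(self, toy_tree):
        a = _run({"1F": [[0.8, 0.8, 0.1, 0.1, 0.1]],
                  "2RC": [[0.3, 0.2, 0.0, 0.0, 0.0]]}, toy_tree, min_rank="species")
        assert (a.status, a.taxid, a.phase) in {("classified", 20, "1"), ("classified", 20, "2")}

    def test_outsider_with_top_mate_sum_wins_phase3(self, toy_tree):
        # gD is outside the phase-1 candidate set but dominates the paired sum
        a = _run({"1F": [[0.8, 0.0, 0.8, 0.5, 0.0]],
                  "2RC": [[0.0, 0.0, 0.0, 0.5, 0.0]]}, toy_tree)
        assert (a.status, a.taxid, a.phase) == ("classified", 22, "3")

    def test_unresolved_tie_is_ambiguous_with_tied_list(self, toy_tree):
        a = _run({"1F": [[0.8, 0.0, 0.8, 0.0, 0.0]]}, toy_tree)
        assert a.status == "ambiguous"
        assert a.tied == (30, 32)

    def test_fallback_classifies_genus_tie_at_genus(self, toy_tree):
        a = _run({"1F": [[0.8, 0.0, 0.8, 0.0, 0.0]]}, toy_tree, fallback=True)
        assert (a.status, a.taxid, a.rank, a.phase) == ("classified", 10, "genus", "fallback")

    def test_fallback_across_phyla_stays_ambiguous(self, toy_tree):
        a = _run({"1F": [[0.8, 0.0, 0.0, 0.0, 0.8]]}, toy_tree, fallback=True)
        assert a.status == "ambiguous"


class TestClassifyReads:
    def test_statuses_partition_reads(self, toy_tree):
        tree, gmap = toy_tree
        rng = np.random.default_rng(7)
        vals = {x: rng.random((20, 5)) * 0.6 for x in ("1F", "1RC", "2F", "2RC")}
        mats = _matrices(vals, read_ids=tuple(f"p{i}" for i in range(20)))
        out = classify_reads(mats, tree, gmap, ClassifyParams(mode="paired"))
        assert len(out) == 20
        assert all(a.status in ("classified", "ambiguous", "not_classified") for a in out)
        again = classify_reads(mats, tree, gmap, ClassifyParams(mode="paired"))
        assert [(a.status, a.taxid, a.score) for a in out] == \
               [(a.status, a.taxid, a.score) for a in again]

    def test_beta_monotonicity(self, toy_tree):
        tree, gmap = toy_tree
        rng = np.random.default_rng(11)
        vals = {x: rng.random((50, 5)) * 0.6 for x in ("1F", "1RC", "2F", "2RC")}
        mats = _matrices(vals, read_ids=tuple(f"p{i}" for i in range(50)))
        classified = []
        for beta in (0.15, 0.25, 0.40):
            out = classify_reads(mats, tree, gmap,
                                 ClassifyParams(mode="paired", beta=beta))
            classified.append({a.read_id for a in out if a.status == "classified"})
        assert classified[2] <= classified[1] <= classified[0]

    def test_unmapped_genome_rejected(self, toy_tree):
        tree, _ = toy_tree
        mats = _matrices({"1F": [[0.9, 0.1, 0.1, 0.1, 0.1]]})
        with pytest.raises(ValueError, match="not in taxon map"):
            classify_reads(mats, tree, {"gA": 30}, ClassifyParams(mode="paired"))

    def test_tsv_round_trip(self, toy_tree):
        tree, gmap = toy_tree
        mats = _matrices({"1F": [[0.9, 0.1, 0.1, 0.1, 0.1]]})
        out = classify_reads(mats, tree, gmap, ClassifyParams(mode="paired"))
        parsed = assignments_from_tsv(assignments_to_tsv(out))
        assert [(a.read_id, a.status, a.taxid, a.rank, a.phase) for a in parsed] == \
               [(a.read_id, a.status, a.taxid, a.rank, a.phase) for a in out]
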