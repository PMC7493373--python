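"""Simulate a small paired-end metagenomic sample and classify it end to end.

Five synthetic 5 kb genomes, each its own species, 100 read pairs at 1%
substitution error, plus 20 shuffled negative-control pairs that mimic reads
from organisms absent from the reference set.  The classifier should place
(nearly) every true pair with its source species in phase 1 and leave the
shuffled pairs unclassified.
"""

from ebwtax.classify import ClassifyParams
from ebwtax.evaluate import metrics, score_against_truth
from ebwtax.fixtures import (SimParams, add_negative_pairs,
                             simulate_paired_reads, simulate_reference_set)
from ebwtax.pipeline import run_classification

params = SimParams(n_genomes=5, genome_length=5000, n_read_pairs=100,
                   read_length=100, insert_size=300, substitution_rate=0.01,
                   n_negative=20, seed=42)
ref = simulate_reference_set(params)
sim = add_negative_pairs(simulate_paired_reads(ref, params), params)

assignments, _ = run_classification(
    sim.mate1, sim.mate2, ref.genomes, ref.tree, ref.gmap,
    alpha=16, measure="eBWT",
    params=ClassifyParams(mode="paired", beta=0.25, min_rank="species"))

by_status = {s: sum(a.status == s for a in assignments)
             for s in ("classified", "ambiguous", "not_classified")}
print("assignment statuses:", by_status)

truth = {r.read_id: r.species_taxid for r in sim.truth if not r.is_random}
random_ids = {r.read_id for r in sim.truth if r.is_random}
counts = score_against_truth(assignments, truth, random_ids, ref.tree)
print(f"confusion: TP={counts.TP} FP={counts.FP} FN={counts.FN} "
      f"TN={counts.TN}/{counts.t_random}")
for name, value in metrics(counts).items():
    print(f"{name:>4} = {value if value is None else round(value, 4)}")
print()
print("SEN/PREC near 1.0 show the true pairs land on their source species;")
print("SPEC near 1.0 shows the shuffled controls stay unclassified (their")
print("base composition matches real reads but no length-16 context survives")
print("the permutation).")
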