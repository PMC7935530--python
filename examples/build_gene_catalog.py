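"""Cluster near-duplicate genes into a nonredundant catalog and merge two
independently derived gene sets.

A parent gene and its low-divergence mutants collapse into one cluster at the
conventional 95% identity / 90% coverage thresholds, while unrelated genes
stay separate.  The merge step reports the overlap statistics used to decide
whether two gene sets are worth combining.
"""

import numpy as np

import oceanmg as om

rng = np.random.default_rng(0)
bases = np.array(list("ACGT"))


def random_gene(gid, length=600):
    return om.GeneRecord(gid, "".join(rng.choice(bases, size=length)))


parent = random_gene("parent")
mutants = [
    om.GeneRecord(f"variant{i:02d}", om.mutate_sequence(parent.sequence, 0.02, seed=i))
    for i in range(10)
]
unrelated = [random_gene(f"novel{i:02d}") for i in range(5)]

catalog = om.cluster_genes([parent] + mutants + unrelated, id_thresh=0.95, cov_thresh=0.90)
print(f"input genes: {1 + len(mutants) + len(unrelated)}")
print(f"nonredundant clusters: {len(catalog)} "
      f"(one variant family + {len(unrelated)} singletons)")

# merge a second set: 4 exact copies from the catalog plus 6 novel genes
reps = catalog.representatives
copies = [om.GeneRecord(f"b_copy{i}", reps[i].sequence) for i in range(4)]
novel = [random_gene(f"b_novel{i}") for i in range(6)]
set_b = om.cluster_genes(copies + novel, 0.95, 0.90)
merged, overlap = om.merge_gene_sets(catalog, set_b)
print(f"shared genes: {overlap['shared_count']} "
      f"({overlap['frac_of_a']:.0%} of A, {overlap['frac_of_b']:.0%} of B); "
      f"merged catalog size: {len(merged)}")
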