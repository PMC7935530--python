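"""Call strain presence from pangenome read recruitment.

Two strains are simulated at a 3:1 abundance ratio along with a third strain
absent from the sample.  A strain is called present when strictly more than
50% of its pangenome genes recruit reads; present strains are quantified by
the mean count/length of their detected genes, so the printed abundance ratio
should recover the simulated 3:1.
"""

import oceanmg as om

pangenomes, records = om.generate_pangenomes(
    n_strains=2, core_size=0, accessory_size=25, gene_len_range=(300, 300), seed=3,
)
spec = om.community_spec(pangenomes, records, [0.75, 0.25])
counts = om.simulate_counts(spec, n_reads_per_sample=100_000, n_samples=1, seed=4)

ghost = om.StrainPangenome("ghost_strain", frozenset(f"ghost{i}" for i in range(20)))
counts = counts.reindex(list(counts.index) + sorted(ghost.gene_ids), fill_value=0)

calls = om.detect_strains(
    list(pangenomes) + [ghost], counts, "S01",
    presence_frac=0.5, lengths=spec.gene_lengths,
)
for c in calls:
    ab = f", abundance {c.abundance:.3f}" if c.abundance is not None else ""
    print(f"{c.strain_id}: detected genes {c.detected_gene_fraction:.0%}, "
          f"present={c.present}{ab}")

present = [c for c in calls if c.present]
print(f"abundance ratio (true 3.0): {present[0].abundance / present[1].abundance:.2f}")
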