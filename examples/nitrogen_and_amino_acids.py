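"""Nitrogen-assimilation routes, N-cycle modules and amino-acid gap analysis.

Uses the curated enzyme observations shipped with the package: the
*Prochlorococcus* population's nitrogen repertoire supports six assimilation
routes (urea, nitrile, glutamine/glutamate, ammonium uptake,
nitrite/nitroalkane + NirA, cyanate) but only the assimilatory
nitrate-reduction module, while the whole community additionally detects
dissimilatory nitrate reduction, denitrification and nitrification.  The
amino-acid analysis finds six broken de novo pathways, two of which are
compensated by direct transporters (Gly, Ala) and one by conversion from an
imported amino acid (Ser from Gly via glyA).
"""

import oceanmg as om

db = om.load_routedb()

proc = db.observed_sets["prochlorococcus_nitrogen"]
routes = om.enumerate_routes(proc, db)
print(f"Prochlorococcus N-assimilation routes ({len(routes)}):")
for r in routes:
    print(f"  - {r}")

community = db.observed_sets["community_nitrogen"]
print("\nN-cycle modules (community vs Prochlorococcus):")
mp_c = om.module_presence(community, db)
mp_p = om.module_presence(proc, db)
for module in db.modules:
    print(f"  {module:34s} community={mp_c[module]!s:5} prochlorococcus={mp_p[module]}")

present, transporters = om.pathways.table1_enzyme_pattern(db)
statuses = om.aa_gap_analysis(present, transporters, db)
n_complete = sum(s.status == "complete" for s in statuses)
print(f"\nAmino-acid biosynthesis: {n_complete}/20 pathways complete")
for s in statuses:
    if s.status != "complete":
        via = f" (uptake via {s.uptake})" if s.uptake else ""
        print(f"  {s.amino_acid}: {s.status}, missing {list(s.missing_steps)}{via}")
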