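"""Scan a 3'-UTR for miR-29 seed sites, knock one out, design a sponge.

A canonical target site is the reverse complement of miRNA positions 2-8
on the UTR sense strand (7mer-m8), optionally flanked by an A opposite
position 1 (8mer). Mutating three bases inside the site abolishes it; a
sponge is seven tandem antisense sites with a 4-nt central bulge
(miRNA positions 9-12 unpaired) that sequesters the miRNA.
"""

from mirage import SeedDefinition, design_sponge, mutate_site, scan_utr

mir29a = SeedDefinition("UAGCACCAUCUGAAAUCGGUUA")
print(f"miR-29a seed (positions 2-8): {mir29a.seed}; "
      f"target-strand patterns: 8mer={mir29a.site_8mer} 7mer-m8={mir29a.site_7mer_m8}")

utr = "CCTTGACCTT" + mir29a.site_8mer + "GTTAGACCATTC" + mir29a.site_7mer_m8 + "AGCT"
sites = scan_utr(utr, mir29a, utr_id="toy-utr")
for s in sites:
    print(f"site [{s.start},{s.end}) class {s.site_class}")

mutated = mutate_site(utr, sites[0], n_mut=3, rng_seed=0, seed=mir29a)
print(f"after 3-nt mutation of the first site: "
      f"{len(scan_utr(mutated, mir29a))} site(s) remain (was {len(sites)})")

construct = design_sponge(mir29a)
rescan = scan_utr(construct.sequence, mir29a)
print(f"sponge: {len(construct.sequence)} nt, {len(construct.site_coords)} sites, "
      f"rescan finds {len(rescan)} seed matches")
print(construct.sequence)
# The rescan count equals the repeat number: every sponge site keeps a
# perfect seed match while the bulge blocks slicing.
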