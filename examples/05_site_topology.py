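"""Categorize amino-acid site changes across species by membrane region.

A cross-species ortholog alignment is scanned for variable columns, each
classified by how many species deviate from the consensus and how many
distinct residues they show; a hydropathy-based 7-TM topology assigns each
change to the extracellular, transmembrane or intracellular region.
"""

from v1r_clade_evo.sites import assign_regions, classify_sites, region_change_summary, representative_rows

msa = {
    "dom_tx": "MDKREILLVAGSTE" + "I" * 21 + "KDREAGSTVLMKRE",
    "spi_tx": "MDKREILLVAGSTE" + "I" * 21 + "KDREAGSTVLMKRE",
    "mac_tx": "MDKREILLVAGSTE" + "I" * 21 + "KDREAGSTVLMKRE",
    "spr_tx": "MDKREVLLVAGSTE" + "I" * 21 + "KDREAGSTVLMKRE",  # V at 6
    "car_tx": "MDKREILLVAGSTE" + "I" * 21 + "KDWEAGSTVLMKRE",  # W after the helix
    "pah_tx": "MDKREILLVAGSTE" + "I" * 21 + "KDWEAGSTVLMKRE",  # shared W
}
species_map = {sid: sid[:3] for sid in msa}

sites = classify_sites(msa, species_map, reference_species="dom")
for s in sites:
    print(f"column {s.column + 1}: {s.category} (consensus {s.consensus})")

rows = representative_rows(msa, species_map)
topo = assign_regions(rows["dom"].replace("-", ""))
print("regions:", "".join(r[0] for r in topo.regions))  # e/t/i per residue
print(region_change_summary(sites, rows["dom"], topo).to_string(index=False))
# The lone spretus V is a single-species change; the W shared by the two
# basal species is a shared_2_3 change, here landing in the region the
# hydropathy stand-in threads after the transmembrane block.
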