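"""Read-based copy numbers and PCR ladder prediction for the family presets.

Copy number = floor(genome_size * genome_proportion / monomer_length): the
read-cluster genome proportion of each family, scaled to a 470 Mb genome and
divided by the monomer length.  The amplicon ladder of an outward-facing
primer pair starts below the monomer length (the first band spans from the
forward primer across one junction to the reverse primer) and climbs in
exact monomer-length steps.
"""

from satkit import DEFAULT_GENOME_SIZE, FAMILY_PRESETS, copy_number, predict_amplicon_ladder

print(f"genome size: {DEFAULT_GENOME_SIZE / 1e6:.0f} Mb\n")
print(f"{'family':<10}{'monomer bp':>11}{'proportion %':>14}{'copies':>9}")
for fam in FAMILY_PRESETS.values():
    length = fam.notes.get("canonical_length", fam.monomer_length)
    n = copy_number(DEFAULT_GENOME_SIZE, fam.genome_proportion, length)
    print(f"{fam.name:<10}{length:>11}{100 * fam.genome_proportion:>14.3f}{n:>9,}")

fam = FAMILY_PRESETS["sat146"]
ladder = predict_amplicon_ladder(fam.primers, 146, 5)
print(f"\n{fam.name} predicted ladder (bp): {ladder.bands}")
print("first band < monomer length because the primers face outward;")
print("every further band adds exactly one 146 bp monomer.")
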