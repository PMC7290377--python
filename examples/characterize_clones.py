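"""From cloned PCR multimers to monomers, consensus, and HOR structure.

Simulates the clone-based characterization of one satellite family: a
tandem array amplified with outward-facing primers gives multimeric clones;
the clones are cut into monomers against the family consensus; the monomer
set yields a majority-rule consensus, pairwise identities, and the internal
higher-order-repeat (HOR) decomposition.
"""

import numpy as np

from satkit import (
    MutationModel,
    PrimerPair,
    Sequence,
    build_array,
    build_consensus,
    decompose_monomer,
    extract_monomers,
    identity_matrix,
    make_random_sequence,
    simulate_clone_set,
)
from satkit.synth import exact_substitutions

rng = np.random.default_rng(11)

# A 37 bp monomer with the classic two-subunit architecture: a 10 bp leading
# subunit whose slightly diverged echo starts the 27 bp second subunit.
s1 = make_random_sequence(10, 0.20, rng, "s1").residues
monomer = Sequence("mono", s1 + exact_substitutions(s1, 2, rng) + make_random_sequence(17, 0.20, rng).residues)
array, _ = build_array(monomer, 40, MutationModel(substitution_rate=0.05, seed=7))

primers = PrimerPair(10, 30, 8, 28)  # first band: 37 - 10 + 28 = 55 bp
clones = simulate_clone_set(array, primers, 37, 6, MutationModel(substitution_rate=0.01, seed=8))
print(f"simulated {len(clones)} clones, insert sizes: {[len(c) for c in clones]}")

monomers = []
for clone in clones:
    mono, partials, _ = extract_monomers(clone, monomer)
    monomers.extend(mono)
print(f"extracted {len(monomers)} monomers from the clone set")

full_length = [m for m in monomers if abs(len(m) - 37) <= 2]
print(f"{len(full_length)} of {len(monomers)} monomers are full length")

consensus = build_consensus(full_length)
ident = identity_matrix(full_length[:8])
off_diag = ident[np.triu_indices_from(ident, k=1)]
print(f"consensus length: {len(consensus)} bp")
print(f"pairwise monomer identity: {off_diag.min():.2f}-{off_diag.max():.2f}")

model = decompose_monomer(full_length)
print("HOR model:", " + ".join(f"{s.label}({len(s.consensus)} bp)" for s in model.subunits))
print("internal boundaries (bp):", model.boundaries)
# The ladder sizes (55, 92, 129, ...) step by one monomer length; the
# boundary at 10 bp recovers the planted leading-subunit duplication.
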