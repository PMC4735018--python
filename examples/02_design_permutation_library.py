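"""Design constructs from an ancestral posterior: permutation frames, a
combinatorial substitution library, the tandem-fusion trajectory and an
error-prone mutant library.

The six permutation frames are the extant Velcro topology (V) plus five
intact-blade rotations (B with end polishing of -2..+2 residues).  The
library enumerates every combination of alternative ancestral states whose
posterior probability exceeds the cutoff.
"""

import numpy as np

from propellerevo.ancestral import align_motifs, build_tree, root_posteriors
from propellerevo.librarydesign import (PermutationFrame, apply_frame,
                                        enumerate_frames, enumerate_library,
                                        mutagenize, permute_construct,
                                        tandem_fuse)
from propellerevo.synthetic import simulate_family

BLADE_SHIFT = 36   # rotation placing strand IV first (structural knowledge)

family = simulate_family(n_propellers=2, motif_count_range=(5, 5),
                         age_spread=(0.3, 0.35), stem_fraction=0.5, seed=21)
motifs = [m for rec in family.propellers
          for m in family.true_motifs[rec.id]]
alignment = align_motifs(motifs)
posterior = root_posteriors(alignment, build_tree(alignment))

frames = enumerate_frames(posterior.n_positions, BLADE_SHIFT,
                          polish_range=2)
print(f"permutation frames: {[f.tag for f in frames]}")

for cutoff in (0.25, 0.1):
    library = enumerate_library(posterior, cutoff, frames, BLADE_SHIFT)
    print(f"cutoff > {cutoff}: {library.n_substitutions} alternative "
          f"states at {len(library.alternatives)} positions -> "
          f"{library.n_variants} variants across {len(frames)} frames")

# the maturation trajectory: single blade-frame motif -> 5-fold tandem
# fusion -> 6-motif expansion intermediate -> 5-motif Velcro permutant
anc_1b = apply_frame(posterior.mpa, PermutationFrame("B"), BLADE_SHIFT)
anc_5b = tandem_fuse(anc_1b, 5, PermutationFrame("B"), name="Anc_5B")
anc_5v = permute_construct(anc_5b, PermutationFrame("V"), BLADE_SHIFT)
print("\ntrajectory lengths:",
      {"Anc_1B": len(anc_1b), "Anc_5B": len(anc_5b),
       "Anc_6B (intermediate)": len(anc_5v.intermediate),
       "Anc_5V": len(anc_5v)})

clones = mutagenize(anc_1b, rate=1.6, n_clones=10_000, seed=7)
counts = [sum(a != b for a, b in zip(anc_1b, c)) for c in clones]
print(f"\nerror-prone library: mean {np.mean(counts):.3f} mutations/motif "
      f"(target rate 1.6), {100 * np.mean(np.array(counts) == 0):.1f}% "
      "unmutated clones")
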