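"""The ENC-GC3 plot: separating mutation pressure from selection.

Generates one genome under pure mutation pressure and one with strong
translational selection, and compares their mean ENC to Wright's
expected curve at the same GC3.  Genes shaped only by nucleotide
composition sit on the curve; selection for preferred codons pulls
them below it.
"""

import numpy as np

from cubtools import GeneratorSpec, enc, enc_expected, generate_genome

GC3 = 0.34
for omega, label in [(0.0, "mutation pressure only"), (0.6, "strong selection")]:
    genome, _ = generate_genome(
        GeneratorSpec(n_genes=200, length_mean=300, length_sd=1,
                      gc3_target=GC3, selection_strength=omega, seed=3)
    )
    mean_enc = np.mean([enc(g) for g in genome])
    print(
        f"{label:>24}: mean ENC = {mean_enc:5.2f}  "
        f"(expected under neutrality at GC3={GC3}: {enc_expected(GC3):.2f})"
    )
print("\nThe selected genome falls far below the null curve — the")
print("below-curve diagnostic for translational selection.")
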