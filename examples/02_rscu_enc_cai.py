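"""RSCU classes, ENC and CAI on one synthetic genome.

Prints the over-/under-represented codons of a pooled genome (RSCU
above 1.6 / below 0.6), the stop-codon usage, and the per-gene ENC/CAI
distribution.  In an AT-rich genome the over-represented codons end in
A or T and the under-represented ones in G or C.
"""

import numpy as np

from cubtools import (
    GeneratorSpec,
    cai,
    cai_weights,
    classify_representation,
    codon_counts,
    enc,
    generate_genome,
    rscu,
    stop_usage,
)

genome, truth = generate_genome(GeneratorSpec(n_genes=300, seed=2, label="demo"))
vec = rscu(codon_counts(genome), scope="demo")
classes = classify_representation(vec)
over = sorted(classes[classes == "over"].index)
under = sorted(classes[classes == "under"].index)
print(f"over-represented codons (RSCU > 1.6): {', '.join(over)}")
print(f"under-represented codons (RSCU < 0.6): {', '.join(under)}")

usage = stop_usage(genome)
print("stop usage:", {s: round(f, 3) for s, f in usage.fractions.items()})

weights = cai_weights(genome.genes, reference_label="whole genome")
encs = [enc(g) for g in genome]
cais = [cai(g, weights) for g in genome]
print(f"ENC: median {np.median(encs):.1f} (range {min(encs):.1f}-{max(encs):.1f})")
print(f"CAI: median {np.median(cais):.3f}")
print("High ENC = weak codon bias; CAI near 1 = codon usage matching the reference.")
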