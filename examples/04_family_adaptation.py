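"""Codon-usage adaptation of gene families to their genome: D(A,B).

Generates a genome with two tagged families — one drawn from the
genome's own codon distribution (adapted) and one from a GC3-shifted
distribution (foreign).  D(A,B) = (1 - cosine)/2 between the family and
genome RSCU vectors; D < 0.1 is the conventional adaptation criterion.
"""

from cubtools import FamilySpec, GeneratorSpec, family_adaptation, generate_genome

spec = GeneratorSpec(
    n_genes=300,
    gc3_target=0.34,
    seed=4,
    label="demo",
    family_specs=(
        FamilySpec("adapted", 10, gc3=0.34),
        FamilySpec("foreign", 10, gc3=0.75),
    ),
)
genome, truth = generate_genome(spec)
print("family    n_genes  R(A,B)   D(A,B)  adapted?")
for tag in ("adapted", "foreign"):
    res = family_adaptation(genome, tag)
    print(
        f"{tag:<10}{res.n_genes:>5}   {res.r_ab:.4f}  {res.d_ab:.4f}  "
        f"{'yes' if res.d_ab < 0.1 else 'no'}"
    )
print("\nThe family sampled from the genome's own distribution sits near")
print("D = 0; the GC3-shifted family is measurably less adapted.")
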