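"""RSCU, ENC (with brute-force oracle), CAI, GRAVY and stop usage."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from cubtools.codon_indices import (
    CaiWeights,
    cai,
    cai_weights,
    classify_representation,
    codon_counts,
    enc,
    enc_expected,
    gravy_aromaticity,
    low_enc_reference,
    rscu,
    stop_usage,
)
from cubtools.genetic_code import DEGENERATE_FAMILIES, RSCU_CODONS, SENSE_CODONS
from cubtools.sequence_io import GenomeSet, StopRecord
from tests.conftest import make_gene


# ---------------------------------------------------------------------------
# independent brute-force ENC oracle: re-derives everything from scratch,
# translating codons with Biopython and enumerating families by translation
# rather than reusing the package's tables.
def enc_oracle(codons):
    by_aa = {}
    for codon in SENSE_CODONS:
        aa = str(Seq(codon).translate())
        by_aa.setdefault(aa, []).append(codon)
    counts = Counter(codons)
    f_values = {}  # aa -> F-hat
    for aa, fam in by_aa.items():
        if len(fam) < 2:
            continue
        n = sum(counts[c] for c in fam)
        if n < 2:
            continue
        s = sum((counts[c] / n) ** 2 for c in fam)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            f_values[aa] = (len(fam), f)
    if not f_values:
        return None
    class_means = {}
    for k in (2, 3, 4, 6):
        fs = [f for kk, f in f_values.values() if kk == k]
        class_means[k] = sum(fs) / len(fs) if fs else None
    if class_means[3] is None and class_means[2] is not None and class_means[4] is not None:
        class_means[3] = (class_means[2] + class_means[4]) / 2
    grand = sum(f for _, f in f_values.values()) / len(f_values)
    for k in class_means:
        if class_means[k] is None:
            class_means[k] = grand
    value = 2 + 9 / class_means[2] + 1 / class_means[3] + 5 / class_means[4] + 3 / class_means[6]
    return min(61.0, max(20.0, value))


class TestRscu:
    def test_twofold_hand_example(self):
        vec = rscu({"TTT": 3, "TTC": 1})
        assert vec.values["TTT"] == pytest.approx(1.5)
        assert vec.values["TTC"] == pytest.approx(0.5)

    def test_equal_usage_gives_all_ones(self):
        vec = rscu({c: 7 for c in RSCU_CODONS})
        assert np.allclose(vec.values.to_numpy(), 1.0)

    def test_single_codon_family_usage(self):
        vec = rscu({"CTG": 12})  # Leu used only as CTG
        assert vec.values["CTG"] == pytest.approx(6.0)
        assert vec.values["CTA"] == 0.0

    def test_unobserved_families_zero_and_flagged(self):
        vec = rscu({"TTT": 3, "TTC": 1})
        assert vec.family_observed["F"]
        assert not vec.family_observed["L"]
        assert (vec.values[list(DEGENERATE_FAMILIES["L"])] == 0).all()

    def test_negative_counts_fatal(self):
        with pytest.raises(ValueError):
            rscu({"TTT": -1})

    def test_family_sums_equal_degeneracy(self, random_genes):
        """Sum of RSCU within each observed family equals k, exhaustively
        over all 18 families on 200 random genes."""
        for gene in random_genes:
            vec = rscu(gene)
            for aa, codons in DEGENERATE_FAMILIES.items():
                if vec.family_observed[aa]:
                    assert vec.values[list(codons)].sum() == pytest.approx(
                        len(codons), abs=1e-9
                    )


class TestRepresentationClasses:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.61, "over"), (1.6, "unbiased"), (0.6, "unbiased"), (0.59, "under"), (1.0, "unbiased")],
    )
    def test_strict_thresholds(self, value, expected):
        vec = rscu({"TTT": 1, "TTC": 1})
        vec.values["TTT"] = value
        assert classify_representation(vec)["TTT"] == expected


class TestEnc:
    def test_one_codon_per_family_is_twenty(self):
        counts = {fam[0]: 15 for fam in DEGENERATE_FAMILIES.values()}
        assert enc(counts) == 20.0

    def test_uniform_large_gene_reaches_sixty_one(self):
        assert enc({c: 60 for c in RSCU_CODONS}) == 61.0

    def test_twofold_family_homozygosity_hand_value(self):
        """Phe counts (3,1): F = (4*(9/16+1/16)-1)/3 = 0.5; with every
        other class imputed from it, ENC = 2 + (9+1+5+3)/0.5 = 38."""
        value = enc({"TTT": 3, "TTC": 1})
        assert value == pytest.approx(2 + 18 / 0.5, abs=1e-12)
        assert value == enc_oracle(["TTT"] * 3 + ["TTC"])

    def test_no_computable_family_flagged_missing(self):
        assert enc({"TTT": 1}) is None  # n < 2 everywhere
        assert enc({}) is None

    def test_matches_bruteforce_oracle_on_random_genes(self, random_genes):
        for gene in random_genes:
            expected = enc_oracle(gene.codons)
            assert enc(gene) == pytest.approx(expected, abs=1e-9)


class TestEncExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0)])
    def test_curve_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_monotone_increasing_below_half(self):
        grid = np.linspace(0, 0.5, 51)
        values = [enc_expected(s) for s in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)


class TestCai:
    def test_weights_smoothing_hand_example(self):
        # reference uses only TTT (3 counts) for Phe
        w = cai_weights({"TTT": 3})
        assert w.w["TTT"] == pytest.approx(1.0)
        assert w.w["TTC"] == pytest.approx(0.5 / 3.5)

    def test_uniform_reference_all_ones(self):
        w = cai_weights({c: 10 for c in RSCU_CODONS})
        assert np.allclose(w.w.to_numpy(), 1.0)

    def test_weights_positive_with_max_one_per_family(self, random_genes):
        w = cai_weights(random_genes[:30])
        assert (w.w > 0).all()
        assert (w.w <= 1).all()
        for codons in DEGENERATE_FAMILIES.values():
            assert w.w[list(codons)].max() == pytest.approx(1.0)

    def test_duplicating_reference_approximately_invariant(self, random_genes):
        once = cai_weights(random_genes[:30]).w
        counts = codon_counts(random_genes[:30])
        twice = cai_weights({c: 2 * n for c, n in counts.items()}).w
        # smoothing makes this asymptotic rather than exact
        assert np.abs(once - twice).max() < 0.01

    def test_all_preferred_codons_gives_one(self):
        w = cai_weights({"TTT": 10, "CTT": 10})
        gene = make_gene(["TTT", "CTT", "TTT"])
        assert cai(gene, w) == pytest.approx(1.0)

    def test_geometric_mean_hand_example(self):
        w = CaiWeights(w=pd.Series(1.0, index=list(RSCU_CODONS)))
        w.w["TTC"] = 0.25
        gene = make_gene(["TTT", "TTC"])  # weights 1.0 and 0.25
        assert cai(gene, w) == pytest.approx(0.5)

    def test_single_codon_families_excluded(self):
        w = CaiWeights(w=pd.Series(0.5, index=list(RSCU_CODONS)))
        gene = make_gene(["ATG", "TGG"])  # Met + Trp only
        assert cai(gene, w) is None

    def test_monotone_in_nonpreferred_fraction(self):
        """CAI strictly decreases as non-preferred codons replace
        preferred ones."""
        w = CaiWeights(w=pd.Series(1.0, index=list(RSCU_CODONS)))
        w.w["TTC"] = 0.3
        values = []
        for n_bad in range(0, 11):
            gene = make_gene(["TTC"] * n_bad + ["TTT"] * (10 - n_bad))
            values.append(cai(gene, w))
        assert all(b < a for a, b in zip(values, values[1:]))


class TestGravyAromaticity:
    # Kyte-Doolittle values straight from the published scale
    KD = {"I": 4.5, "F": 2.8, "A": 1.8, "G": -0.4, "K": -3.9, "W": -0.9}

    def test_poly_ile_gravy(self):
        g, _ = gravy_aromaticity(make_gene(["ATT"] * 12))
        assert g == pytest.approx(4.5)

    def test_poly_phe_aromaticity(self):
        _, arom = gravy_aromaticity(make_gene(["TTT"] * 12))
        assert arom == pytest.approx(1.0)

    def test_mixed_peptide_vs_table_lookup(self):
        # IFAGKW peptide, codons chosen accordingly
        codons = ["ATT", "TTT", "GCT", "GGT", "AAA", "TGG"]
        g, arom = gravy_aromaticity(make_gene(codons))
        expected = np.mean([self.KD[a] for a in "IFAGKW"])
        assert g == pytest.approx(expected, abs=1e-9)
        assert arom == pytest.approx(2 / 6)  # F and W aromatic, no Y

    def test_aromatic_fraction_counts_fyw(self):
        codons = ["TTT", "TAT", "TGG", "AAA"]  # F, Y, W, K
        _, arom = gravy_aromaticity(make_gene(codons))
        assert arom == pytest.approx(0.75)


class TestStopUsage:
    def _genome(self, stops):
        genome = GenomeSet("s")
        for i, s in enumerate(stops):
            genome.stops.append(StopRecord(f"g{i}", s))
        return genome

    def test_counting(self):
        usage = stop_usage(self._genome(["TAA", "TAA", "TAG"]))
        assert usage.fractions == pytest.approx({"TAA": 2 / 3, "TAG": 1 / 3, "TGA": 0.0})
        assert usage.n == 3

    def test_empty_flagged(self):
        usage = stop_usage(self._genome([]))
        assert usage.n == 0
        assert sum(usage.fractions.values()) == 0.0

    def test_generator_probabilities_recovered(self):
        from cubtools.synthetic import GeneratorSpec, generate_genome

        genome, _ = generate_genome(
            GeneratorSpec(n_genes=2000, length_mean=35, length_sd=2, seed=11)
        )
        usage = stop_usage(genome)
        for stop, p in {"TAA": 0.6, "TAG": 0.3, "TGA": 0.1}.items():
            se = math.sqrt(p * (1 - p) / 2000)
            assert abs(usage.fractions[stop] - p) < 3 * se


class TestReferenceSelection:
    def test_low_enc_reference_picks_most_biased(self, random_genes):
        reference = low_enc_reference(
            type("G", (), {"genes": random_genes[:40], "label": "x"})(), fraction=0.1
        )
        chosen = {g.gene_id for g in reference}
        encs = sorted((enc(g), g.gene_id) for g in random_genes[:40])
        assert chosen == {gid for _, gid in encs[:4]}
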