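"""Codon-usage indices: RSCU, ENC, the ENC-GC3 null curve, CAI, GRAVY.

RSCU (relative synonymous codon usage) for codon j of a k-fold
synonymous family with family total n is ``k * n_j / n``: 1.0 means the
codon is used exactly as often as expected under equal usage, values
above 1.6 are called over-represented and below 0.6 under-represented.

ENC is Wright's effective number of codons.  For each family the
homozygosity estimator is

    F = (n * sum(p_j^2) - 1) / (n - 1),

and ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 over the degeneracy-class
averages (9 two-fold, 1 three-fold, 5 four-fold and 3 six-fold families
in the standard code), clamped to [20, 61].  Under pure mutation
pressure the expectation given GC3 = s is Wright's null curve

    ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2),

so genes falling clearly below the curve indicate selection on codon
choice beyond nucleotide composition.

CAI is the geometric mean over a gene's codons of relative-adaptiveness
weights w derived from a highly expressed reference gene set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    DEGENERATE_FAMILIES,
    RSCU_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    translate_codons,
)
from .sequence_io import CodingSequence, GenomeSet

__all__ = [
    "RscuVector",
    "CodonIndices",
    "CaiWeights",
    "StopUsage",
    "codon_counts",
    "rscu",
    "classify_representation",
    "enc",
    "enc_expected",
    "cai_weights",
    "cai",
    "gravy_aromaticity",
    "stop_usage",
    "gene_indices",
    "ribosomal_reference",
    "low_enc_reference",
]

OVER_REPRESENTED_THRESHOLD = 1.6
UNDER_REPRESENTED_THRESHOLD = 0.6


@dataclass
class RscuVector:
    """RSCU over the 59 sense codons of degenerate families.

    ``values`` is indexed by :data:`~cubtools.genetic_code.RSCU_CODONS`;
    unobserved families carry 0 and ``family_observed[aa]`` False.
    """

    scope: str
    values: pd.Series
    family_observed: dict[str, bool] = field(default_factory=dict)


@dataclass
class CodonIndices:
    gene_id: str
    enc: float | None
    cai: float | None
    gc3: float
    gravy: float
    aromaticity: float


@dataclass
class CaiWeights:
    """Relative adaptiveness per sense codon (max within each family = 1)."""

    w: pd.Series
    reference_label: str = ""


@dataclass
class StopUsage:
    label: str
    counts: dict[str, int]
    fractions: dict[str, float]
    n: int


def codon_counts(obj) -> Counter:
    """Pooled sense-codon counts of a gene, genome set or iterable of genes.

    Plain mappings pass through unchanged (after a copy).
    """
    if isinstance(obj, Mapping):
        return Counter(obj)
    if isinstance(obj, CodingSequence):
        return Counter(obj.codons)
    counts: Counter = Counter()
    genes = obj.genes if isinstance(obj, GenomeSet) else obj
    for gene in genes:
        counts.update(gene.codons)
    return counts


def rscu(counts, scope: str = "") -> RscuVector:
    """RSCU vector from per-codon counts.

    RSCU_j = count_j / (family_total / k) for a k-fold family; all 0 for
    unobserved families.  Negative counts are a programming error and
    raise ``ValueError``.
    """
    counts = codon_counts(counts)
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative codon counts")
    values = pd.Series(0.0, index=list(RSCU_CODONS))
    observed: dict[str, bool] = {}
    for aa, codons in DEGENERATE_FAMILIES.items():
        total = sum(counts[c] for c in codons)
        observed[aa] = total > 0
        if total > 0:
            k = len(codons)
            for c in codons:
                values[c] = counts[c] * k / total
    return RscuVector(scope=scope, values=values, family_observed=observed)


def classify_representation(vec: RscuVector) -> pd.Series:
    """Per-codon representation class: over / under / unbiased.

    The thresholds 1.6 and 0.6 are strict; boundary values are unbiased.
    """
    def _cls(v: float) -> str:
        if v > OVER_REPRESENTED_THRESHOLD:
            return "over"
        if v < UNDER_REPRESENTED_THRESHOLD:
            return "under"
        return "unbiased"

    return vec.values.map(_cls)


def _family_homozygosity(counts: Counter) -> dict[int, list[float]]:
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in DEGENERATE_FAMILIES.items():
        n = sum(counts[c] for c in codons)
        if n < 2:
            continue
        p_sq = sum((counts[c] / n) ** 2 for c in codons)
        f_hat = (n * p_sq - 1.0) / (n - 1.0)
        if f_hat <= 0:
            continue
        by_class[len(codons)].append(f_hat)
    return by_class


def enc(counts) -> float | None:
    """Wright's effective number of codons for one gene.

    Families with fewer than 2 counted codons or non-positive F are
    omitted from their class average; an empty three-fold class is
    imputed from the mean of the two- and four-fold averages, any other
    empty class from the mean F of all computable families (Wright's
    conventions).  Result clamped to [20, 61]; ``None`` when no family
    is computable.
    """
    counts = codon_counts(counts)
    by_class = _family_homozygosity(counts)
    all_f = [f for fs in by_class.values() for f in fs]
    if not all_f:
        return None
    means: dict[int, float | None] = {
        k: (float(np.mean(v)) if v else None) for k, v in by_class.items()
    }
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2.0
    grand = float(np.mean(all_f))
    for k in means:
        if means[k] is None:
            means[k] = grand
    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return float(min(61.0, max(20.0, value)))


def enc_expected(gc3: float) -> float:
    """Wright's expected ENC under pure mutation pressure at GC3 = s."""
    s = float(gc3)
    if not 0.0 <= s <= 1.0:
        raise ValueError("gc3 must be in [0, 1]")
    value = 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)
    return min(61.0, value)


def cai_weights(reference: Iterable[CodingSequence] | Mapping, reference_label: str = "") -> CaiWeights:
    """Relative adaptiveness from a pooled reference gene set.

    Within each family a pseudocount of 0.5 is added to every codon's
    pooled count before normalising by the family maximum, so every
    weight is strictly positive even for codons absent from the
    reference.
    """
    counts = codon_counts(reference)
    if sum(counts.values()) == 0:
        raise ValueError("empty reference set")
    w = pd.Series(1.0, index=list(RSCU_CODONS))
    for aa, codons in DEGENERATE_FAMILIES.items():
        smoothed = {c: counts[c] + 0.5 for c in codons}
        top = max(smoothed.values())
        for c in codons:
            w[c] = smoothed[c] / top
    return CaiWeights(w=w, reference_label=reference_label)


def cai(gene, weights: CaiWeights) -> float | None:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Single-codon families (ATG, TGG) are excluded, as are stop codons.
    """
    counts = codon_counts(gene)
    total = 0
    log_sum = 0.0
    for codon in RSCU_CODONS:
        n = counts.get(codon, 0)
        if n:
            total += n
            log_sum += n * math.log(weights.w[codon])
    if total == 0:
        return None
    return float(math.exp(log_sum / total))


def gravy_aromaticity(gene: CodingSequence) -> tuple[float, float]:
    """GRAVY (mean Kyte-Doolittle hydropathy) and aromatic fraction
    (Phe+Tyr+Trp) of the translated protein."""
    protein = translate_codons(gene.codons)
    analysis = ProteinAnalysis(protein)
    return float(analysis.gravy()), float(analysis.aromaticity())


def stop_usage(genome: GenomeSet) -> StopUsage:
    """Counts and fractions of TAA/TAG/TGA over the genome's stop records."""
    counts = {s: 0 for s in STOP_CODONS}
    for record in genome.stops:
        if record.stop_codon in counts:
            counts[record.stop_codon] += 1
    n = sum(counts.values())
    fractions = {s: (c / n if n else 0.0) for s, c in counts.items()}
    return StopUsage(label=genome.label, counts=counts, fractions=fractions, n=n)


def gene_indices(
    genome: GenomeSet, weights: CaiWeights | None = None
) -> pd.DataFrame:
    """Per-gene index table: gene_id, ENC, CAI, GC3, GRAVY, aromaticity."""
    from .composition import nucleotide_profile

    if weights is None:
        weights = cai_weights(ribosomal_reference(genome) or low_enc_reference(genome))
    rows = []
    for gene in genome.genes:
        profile = nucleotide_profile(gene)
        g, arom = gravy_aromaticity(gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "enc": enc(gene),
                "cai": cai(gene, weights),
                "gc3": profile.gc3,
                "gravy": g,
                "aromaticity": arom,
                "strand_class": gene.strand_class,
                "family_tag": gene.family_tag or "",
            }
        )
    return pd.DataFrame(rows)


def ribosomal_reference(genome: GenomeSet) -> list[CodingSequence]:
    """Genes whose product annotation mentions a ribosomal protein."""
    return [
        g
        for g in genome.genes
        if g.product and "ribosomal protein" in g.product.lower()
    ]


def low_enc_reference(genome: GenomeSet, fraction: float = 0.05) -> list[CodingSequence]:
    """Fallback CAI reference: the most codon-biased (lowest-ENC) genes."""
    scored = [(enc(g), g) for g in genome.genes]
    scored = [(e, g) for e, g in scored if e is not None]
    scored.sort(key=lambda t: (t[0], t[1].gene_id))
    n = max(1, int(round(len(scored) * fraction)))
    return [g for _, g in scored[:n]]
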