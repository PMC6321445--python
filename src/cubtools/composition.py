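"""Nucleotide and amino-acid composition with Shannon-entropy bias measures.

For every gene we report the overall nucleotide frequencies (N%), the
frequencies at third codon positions (N3%), GC3, and the Shannon
information entropy of each distribution,

    H = -sum_i f_i * log2(f_i),       0*log2(0) := 0,

which is maximal for uniform usage and 0 for single-symbol usage.
Nucleotide entropies are reported in raw bits (maximum 2); the
amino-acid entropy is divided by log2(20) so it lies in [0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .genetic_code import AMINO_ACIDS, CODON_TO_AA, NUCLEOTIDES
from .sequence_io import CodingSequence, GenomeSet

__all__ = [
    "CompositionProfile",
    "shannon_entropy",
    "nucleotide_profile",
    "third_position_profile",
    "amino_acid_profile",
    "pooled_profile",
    "composition_table",
]


@dataclass
class CompositionProfile:
    """Per-gene (or pooled) composition summary."""

    gene_id: str
    n_freq: dict[str, float]
    n3_freq: dict[str, float]
    gc3: float
    entropy_overall: float
    entropy_third: float
    aa_freq: dict[str, float]
    aa_entropy_norm: float


def shannon_entropy(freqs: Iterable[float], *, normalized: bool = False) -> float:
    """Shannon entropy in bits; ``normalized`` divides by log2(k)."""
    f = np.asarray(list(freqs), dtype=float)
    h = float(_scipy_entropy(f, base=2)) if f.sum() > 0 else 0.0
    if normalized and len(f) > 1:
        h /= np.log2(len(f))
    return h


def _freqs(counts: Counter, alphabet: tuple[str, ...] | str) -> dict[str, float]:
    total = sum(counts[s] for s in alphabet)
    if total == 0:
        return {s: 0.0 for s in alphabet}
    return {s: counts[s] / total for s in alphabet}


def _profile_from_codons(codons: Iterable[str], gene_id: str) -> CompositionProfile:
    codons = list(codons)
    all_counts: Counter = Counter()
    third_counts: Counter = Counter()
    aa_counts: Counter = Counter()
    for codon in codons:
        all_counts.update(codon)
        third_counts[codon[2]] += 1
        aa_counts[CODON_TO_AA[codon]] += 1
    n_freq = _freqs(all_counts, NUCLEOTIDES)
    n3_freq = _freqs(third_counts, NUCLEOTIDES)
    aa_freq = _freqs(aa_counts, AMINO_ACIDS)
    return CompositionProfile(
        gene_id=gene_id,
        n_freq=n_freq,
        n3_freq=n3_freq,
        gc3=n3_freq["G"] + n3_freq["C"],
        entropy_overall=shannon_entropy(n_freq.values()),
        entropy_third=shannon_entropy(n3_freq.values()),
        aa_freq=aa_freq,
        aa_entropy_norm=shannon_entropy(aa_freq.values(), normalized=True),
    )


def nucleotide_profile(gene: CodingSequence) -> CompositionProfile:
    """Full composition profile of one validated gene.

    Frequencies are computed from the gene's sense codons (ambiguous
    codons were already excluded at validation).
    """
    return _profile_from_codons(gene.codons, gene.gene_id)


def third_position_profile(gene: CodingSequence) -> tuple[dict[str, float], float, float]:
    """(n3_freq, gc3, entropy_third) over third positions of sense codons."""
    p = nucleotide_profile(gene)
    return p.n3_freq, p.gc3, p.entropy_third


def amino_acid_profile(gene: CodingSequence) -> tuple[dict[str, float], float]:
    """(aa_freq, normalized amino-acid entropy in [0, 1])."""
    p = nucleotide_profile(gene)
    return p.aa_freq, p.aa_entropy_norm


def pooled_profile(genes: Iterable[CodingSequence], label: str = "pooled") -> CompositionProfile:
    """Composition of the pooled codon counts of many genes.

    Equivalent to recounting the concatenation of the genes, i.e. the
    count-weighted combination of the per-gene counts.
    """
    all_codons: list[str] = []
    for gene in genes:
        all_codons.extend(gene.codons)
    if not all_codons:
        raise ValueError("no codons to pool")
    return _profile_from_codons(all_codons, label)


def _mean_sd(values: list[float]) -> str:
    return f"{np.mean(values) * 100:.2f} ± {np.std(values, ddof=1) * 100:.2f}"


def composition_table(
    genomes: Mapping[str, GenomeSet] | Iterable[GenomeSet],
    *,
    normalize_entropy: bool = False,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-genome composition summary, one row per genome.

    N% and N3% columns are "mean +/- sd" over genes, in percent; entropy
    columns are per-gene means in bits, or divided by 2 (= log2 4) when
    ``normalize_entropy`` is set.
    """
    if isinstance(genomes, Mapping):
        items = list(genomes.items())
    else:
        items = [(g.label, g) for g in genomes]
    rows = []
    scale = 2.0 if normalize_entropy else 1.0
    for label, genome in items:
        profiles = [nucleotide_profile(g) for g in genome.genes]
        row: dict[str, object] = {"strain": label, "n_genes": len(profiles)}
        for nt in "TCAG":
            row[f"{nt}%"] = _mean_sd([p.n_freq[nt] for p in profiles])
        for nt in "TCAG":
            row[f"{nt}3%"] = _mean_sd([p.n3_freq[nt] for p in profiles])
        row["GC3%"] = _mean_sd([p.gc3 for p in profiles])
        row["entropy_overall"] = float(np.mean([p.entropy_overall for p in profiles])) / scale
        row["entropy_third"] = float(np.mean([p.entropy_third for p in profiles])) / scale
        row["aa_entropy_norm"] = float(np.mean([p.aa_entropy_norm for p in profiles]))
        rows.append(row)
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
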