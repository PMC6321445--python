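"""Synthetic coding-sequence generator with known ground truth.

Genes are produced under an independent-position codon model (pure
mutation pressure): the three codon positions draw nucleotides from
separate background distributions, with a third-position GC knob
(``gc3_target``) controlling GC3.  Translational selection is emulated
by a mixture: each codon is, with probability ``selection_strength``
(omega), drawn uniformly from a designated optimal-codon set instead of
the background.  Triplets that would be stop codons in sense positions
are resampled (equivalently, the background is renormalised over the 61
sense codons, which leaves within-family conditional distributions
untouched); a terminal stop codon is appended from ``stop_probs``.

Defaults emulate the AT-rich chlamydial coding sequences that motivate
the analysis: ~900 CDS per genome, lengths of 300-3000 nt in multiples
of three, GC3 around 0.34, TAA-biased stop usage with TGA rarest.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .genetic_code import (
    ALL_CODONS,
    DEGENERATE_FAMILIES,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
)
from .sequence_io import CodingSequence, GenomeSet, StopRecord, reverse_complement

__all__ = [
    "FamilySpec",
    "GeneratorSpec",
    "TruthRecord",
    "generate_genome",
    "generate_chlamydia_like",
    "generate_skewed_genome",
    "default_optimal_codons",
    "background_from_gc3",
    "to_fasta",
    "to_genbank",
    "write_truth_tsv",
    "CHLAMYDIA_PRESETS",
]

#: Stop-codon usage: TAA-biased with TGA least used, as in AT-rich
#: intracellular bacteria.
DEFAULT_STOP_PROBS: dict[str, float] = {"TAA": 0.6, "TAG": 0.3, "TGA": 0.1}


def background_from_gc3(gc3: float) -> np.ndarray:
    """Positional nucleotide background (3x4, rows = codon positions,
    columns in A,C,G,T order).

    Positions 1-2 are uniform; the third position splits GC3 evenly
    between G and C (and 1-GC3 between A and T), which is the null in
    which synonymous choice is driven by third-position composition
    alone.
    """
    third = np.array([(1 - gc3) / 2, gc3 / 2, gc3 / 2, (1 - gc3) / 2])
    return np.vstack([np.full(4, 0.25), np.full(4, 0.25), third])


def default_optimal_codons() -> tuple[str, ...]:
    """One 'optimal' codon per degenerate family: prefer a T-ending
    codon, then A-ending, then the alphabetically first (a fixed,
    AT-consistent choice)."""
    chosen = []
    for aa, codons in DEGENERATE_FAMILIES.items():
        by_third = {c[2]: c for c in sorted(codons)}
        chosen.append(by_third.get("T") or by_third.get("A") or sorted(codons)[0])
    return tuple(sorted(chosen))


@dataclass
class FamilySpec:
    """A designated gene-family subset with its own codon distribution
    (stand-in for gene families such as T3SS effectors or Pmps)."""

    tag: str
    n_genes: int
    gc3: float | None = None
    selection_strength: float | None = None
    background: np.ndarray | None = None


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic genome."""

    n_genes: int = 900
    length_mean: float = 330.0  # codons (~990 nt)
    length_sd: float = 150.0
    length_min: int = 30
    length_max: int = 1000
    gc3_target: float = 0.345
    background: np.ndarray | None = None  # overrides gc3_target when given
    selection_strength: float = 0.0
    optimal_codons: tuple[str, ...] = field(default_factory=default_optimal_codons)
    stop_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_STOP_PROBS))
    strand_asymmetry: float = 0.0  # GC-skew amplitude for skewed genomes
    family_specs: tuple[FamilySpec, ...] = ()
    label: str = "synthetic"
    seed: int = 0


@dataclass
class TruthRecord:
    """Ground truth of a generated genome, for parameter-recovery tests."""

    gc3_target: float
    selection_strength: float
    stop_probs: dict[str, float]
    family_truth: dict[str, dict] = field(default_factory=dict)
    ori_position: int | None = None
    ter_position: int | None = None
    strand_labels: dict[str, str] = field(default_factory=dict)


_SENSE_IDX = np.array([ALL_CODONS.index(c) for c in SENSE_CODONS])
_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}


def _sense_distribution(background: np.ndarray) -> np.ndarray:
    """Probabilities over the 61 sense codons implied by a positional
    background, with stop triplets removed and the rest renormalised."""
    background = np.asarray(background, dtype=float)
    if background.shape != (3, 4):
        raise ValueError("background must be 3x4 (codon position x A,C,G,T)")
    if not np.allclose(background.sum(axis=1), 1.0):
        raise ValueError("each background row must sum to 1")
    p64 = np.einsum("i,j,k->ijk", *background).reshape(64)
    order = np.array(
        [16 * _NT_INDEX[c[0]] + 4 * _NT_INDEX[c[1]] + _NT_INDEX[c[2]] for c in ALL_CODONS]
    )
    p_sense = p64[order][_SENSE_IDX]
    total = p_sense.sum()
    if total <= 0:
        raise ValueError("infeasible background: all probability mass on stop codons")
    return p_sense / total


def _sample_gene_codons(
    rng: np.random.Generator,
    length: int,
    sense_p: np.ndarray,
    omega: float,
    optimal: tuple[str, ...],
) -> list[str]:
    body = rng.choice(len(SENSE_CODONS), size=length, p=sense_p)
    codons = [SENSE_CODONS[i] for i in body]
    if omega > 0:
        selected = rng.random(length) < omega
        picks = rng.integers(0, len(optimal), size=length)
        for i in np.nonzero(selected)[0]:
            codons[i] = optimal[picks[i]]
    return codons


def _sample_length(rng: np.random.Generator, spec: GeneratorSpec) -> int:
    while True:
        value = int(round(rng.normal(spec.length_mean, spec.length_sd)))
        if spec.length_min <= value <= spec.length_max:
            return value


def _sample_stop(rng: np.random.Generator, stop_probs: Mapping[str, float]) -> str:
    stops = list(stop_probs)
    p = np.array([stop_probs[s] for s in stops], dtype=float)
    p = p / p.sum()
    return stops[rng.choice(len(stops), p=p)]


def generate_genome(spec: GeneratorSpec) -> tuple[GenomeSet, TruthRecord]:
    """Generate a genome's worth of CDS plus its ground-truth record.

    Every gene starts with ATG, is followed by codons from the mixture
    model, and carries a terminal stop drawn from ``stop_probs``.
    Family subsets defined in ``family_specs`` are appended after the
    main gene set with their own distributions and tags.
    """
    rng = np.random.default_rng(spec.seed)
    sense_p = _sense_distribution(_spec_background(spec))
    genome = GenomeSet(label=spec.label)
    truth = TruthRecord(
        gc3_target=spec.gc3_target,
        selection_strength=spec.selection_strength,
        stop_probs=dict(spec.stop_probs),
    )
    for i in range(spec.n_genes):
        length = _sample_length(rng, spec)
        codons = ["ATG"] + _sample_gene_codons(
            rng, length - 1, sense_p, spec.selection_strength, spec.optimal_codons
        )
        gene_id = f"{spec.label}_{i + 1:05d}"
        genome.add(
            CodingSequence(gene_id=gene_id, codons=tuple(codons)),
            StopRecord(gene_id, _sample_stop(rng, spec.stop_probs)),
        )
    for fam in spec.family_specs:
        if fam.background is not None:
            fam_background = np.asarray(fam.background, dtype=float)
        else:
            fam_background = _calibrate_background(
                background_from_gc3(fam.gc3 if fam.gc3 is not None else spec.gc3_target),
                spec.length_mean,
            )
        fam_p = _sense_distribution(fam_background)
        fam_omega = (
            fam.selection_strength
            if fam.selection_strength is not None
            else spec.selection_strength
        )
        truth.family_truth[fam.tag] = {
            "gc3": fam.gc3 if fam.gc3 is not None else spec.gc3_target,
            "selection_strength": fam_omega,
            "n_genes": fam.n_genes,
        }
        for i in range(fam.n_genes):
            length = _sample_length(rng, spec)
            codons = ["ATG"] + _sample_gene_codons(
                rng, length - 1, fam_p, fam_omega, spec.optimal_codons
            )
            gene_id = f"{spec.label}_{fam.tag}_{i + 1:04d}"
            genome.add(
                CodingSequence(gene_id=gene_id, codons=tuple(codons), family_tag=fam.tag),
                StopRecord(gene_id, _sample_stop(rng, spec.stop_probs)),
            )
    return genome, truth


# Positional backgrounds tuned so realized mean N% / N3% approximate
# published per-strain composition of chlamydial genomes (overall and
# third-position targets, fractions of A,C,G,T).  Positions 1-2 take the
# residual (3*overall - third)/2.
CHLAMYDIA_PRESETS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    # C. trachomatis LGV-biovar-like: T3 36.5, C3 16.6, A3 29.0, G3 17.9
    "L2": {
        "overall": (0.284, 0.200, 0.217, 0.299),
        "third": (0.290, 0.166, 0.179, 0.365),
    },
    # C. avium-like, the most AT-rich: T3 40, C3 13.2, A3 32.8, G3 13.8
    "avium": {
        "overall": (0.309, 0.182, 0.192, 0.317),
        "third": (0.328, 0.132, 0.138, 0.400),
    },
}


def _realized_marginals(background: np.ndarray, length_mean: float) -> np.ndarray:
    """Positional nucleotide marginals actually produced by the sampler.

    Accounts for the renormalisation over sense codons (stop triplets,
    all ending in A or G, shift mass onto the other third-position
    nucleotides) and for the fixed ATG start codon (weight ~1/length)."""
    p_sense = _sense_distribution(background)
    marginals = np.zeros((3, 4))
    for p, codon in zip(p_sense, SENSE_CODONS):
        for k in range(3):
            marginals[k, _NT_INDEX[codon[k]]] += p
    atg = np.zeros((3, 4))
    for k, nt in enumerate("ATG"):
        atg[k, _NT_INDEX[nt]] = 1.0
    w = 1.0 / max(length_mean, 2.0)
    return (1.0 - w) * marginals + w * atg


def _calibrate_background(targets: np.ndarray, length_mean: float) -> np.ndarray:
    """Fixed-point calibration: find a positional background whose
    *realized* marginals (after stop-triplet exclusion and the ATG
    start) equal the target marginals."""
    background = np.asarray(targets, dtype=float).copy()
    for _ in range(200):
        realized = _realized_marginals(background, length_mean)
        if np.abs(realized - targets).max() < 1e-10:
            break
        background = background * (targets / np.maximum(realized, 1e-12))
        background = np.clip(background, 1e-6, None)
        background /= background.sum(axis=1, keepdims=True)
    return background


def _spec_background(spec: "GeneratorSpec") -> np.ndarray:
    """The sampling background of a spec: an explicit background is
    taken literally; the gc3 knob is calibrated so realized GC3 matches
    ``gc3_target``."""
    if spec.background is not None:
        return np.asarray(spec.background, dtype=float)
    return _calibrate_background(background_from_gc3(spec.gc3_target), spec.length_mean)


def _preset_background(
    preset: Mapping[str, tuple[float, ...]], length_mean: float = 330.0
) -> np.ndarray:
    """Positional background calibrated so realized marginals match the
    preset's overall and third-position targets."""
    overall = np.asarray(preset["overall"], dtype=float)
    third = np.asarray(preset["third"], dtype=float)
    overall = overall / overall.sum()
    third = third / third.sum()
    p12 = (3.0 * overall - third) / 2.0
    if (p12 <= 0).any():
        raise ValueError("inconsistent preset targets")
    p12 = p12 / p12.sum()
    return _calibrate_background(np.vstack([p12, p12, third]), length_mean)


def generate_chlamydia_like(
    preset: str = "L2", *, n_genes: int = 900, seed: int = 0
) -> tuple[GenomeSet, TruthRecord, GeneratorSpec]:
    """Generate a genome whose composition approximates a chlamydial
    strain preset (realized mean N%/N3% within ~1 percentage point of
    the preset targets)."""
    if preset not in CHLAMYDIA_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(CHLAMYDIA_PRESETS)}")
    background = _preset_background(CHLAMYDIA_PRESETS[preset])
    third = np.asarray(CHLAMYDIA_PRESETS[preset]["third"], dtype=float)
    third = third / third.sum()
    gc3 = float(third[1] + third[2])  # target C3 + G3
    spec = GeneratorSpec(
        n_genes=n_genes,
        background=background,
        gc3_target=gc3,
        label=f"synthetic_{preset}",
        seed=seed,
    )
    genome, truth = generate_genome(spec)
    return genome, truth, spec


def _skewed_background(background: np.ndarray, amplitude: float, g_rich: bool) -> np.ndarray:
    shifted = np.array(background, dtype=float)
    delta = amplitude / 2.0 if g_rich else -amplitude / 2.0
    shifted[:, _NT_INDEX["G"]] += delta
    shifted[:, _NT_INDEX["C"]] -= delta
    shifted = np.clip(shifted, 0.005, None)
    return shifted / shifted.sum(axis=1, keepdims=True)


def generate_skewed_genome(
    spec: GeneratorSpec,
) -> tuple[str, GenomeSet, TruthRecord]:
    """Generate a full genome sequence with two replichores of opposite
    G/C excess, plus the gene set with true strand labels.

    The origin sits at position 0 and the terminus at the midpoint; the
    published (plus) strand carries a G excess of amplitude
    ``spec.strand_asymmetry`` on the first replichore and a C excess on
    the second.  Genes are placed alternately on the two strands; their
    true class is leading when transcription is co-directional with the
    replication fork (plus strand on the first replichore, minus on the
    second).
    """
    rng = np.random.default_rng(spec.seed)
    base_background = _spec_background(spec)
    amplitude = spec.strand_asymmetry
    genome = GenomeSet(label=spec.label)
    truth = TruthRecord(
        gc3_target=spec.gc3_target,
        selection_strength=spec.selection_strength,
        stop_probs=dict(spec.stop_probs),
    )
    segments: list[str] = []
    position = 0
    n_first = spec.n_genes // 2
    for i in range(spec.n_genes):
        first_replichore = i < n_first
        strand = "+" if rng.random() < 0.5 else "-"
        leading = (strand == "+") == first_replichore
        # leading-strand genes read G-rich in coding orientation, so the
        # published strand shows the right G/C excess either way.
        gene_background = _skewed_background(base_background, amplitude, g_rich=leading)
        sense_p = _sense_distribution(gene_background)
        length = _sample_length(rng, spec)
        codons = ["ATG"] + _sample_gene_codons(
            rng, length - 1, sense_p, spec.selection_strength, spec.optimal_codons
        )
        stop = _sample_stop(rng, spec.stop_probs)
        cds = "".join(codons) + stop
        gene_id = f"{spec.label}_{i + 1:05d}"
        genome.add(
            CodingSequence(
                gene_id=gene_id,
                codons=tuple(codons),
                source_strand=strand,
                start_coord=position,
            ),
            StopRecord(gene_id, stop),
        )
        truth.strand_labels[gene_id] = "leading" if leading else "lagging"
        segments.append(cds if strand == "+" else reverse_complement(cds))
        position += len(cds)
        if i == n_first - 1:
            truth.ter_position = position
    truth.ori_position = 0
    return "".join(segments), genome, truth


def to_fasta(genome: GenomeSet, path: str | Path, stops: bool = True) -> None:
    """Write the genome's CDS as multi-FASTA (terminal stops included by
    default, as in real CDS files)."""
    stop_by_id = {s.gene_id: s.stop_codon for s in genome.stops}
    with open(path, "w") as fh:
        for gene in genome.genes:
            header = f">{gene.gene_id}"
            if gene.family_tag:
                header += f" family={gene.family_tag}"
            if gene.product:
                header += f" product={gene.product.replace(' ', '_')}"
            seq = gene.sequence
            if stops and stop_by_id.get(gene.gene_id):
                seq += stop_by_id[gene.gene_id]
            fh.write(header + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def to_genbank(genome: GenomeSet, path: str | Path, *, genome_sequence: str | None = None) -> None:
    """Write a GenBank flat file with CDS features (for round-tripping
    through the GenBank reader).

    Without an explicit ``genome_sequence``, genes are concatenated on
    the plus strand in order.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    stop_by_id = {s.gene_id: s.stop_codon for s in genome.stops}
    features = []
    if genome_sequence is None:
        parts = []
        position = 0
        for gene in genome.genes:
            seq = gene.sequence + (stop_by_id.get(gene.gene_id) or "")
            features.append((gene, position, position + len(seq), 1))
            parts.append(seq)
            position += len(seq)
        genome_sequence = "".join(parts)
    else:
        for gene in genome.genes:
            if gene.start_coord is None:
                continue
            span = 3 * len(gene.codons) + (3 if stop_by_id.get(gene.gene_id) else 0)
            strand = 1 if gene.source_strand == "+" else -1
            features.append((gene, gene.start_coord, gene.start_coord + span, strand))
    record = SeqRecord(
        Seq(genome_sequence),
        id=genome.label[:16] or "synthetic",
        name=(genome.label or "synthetic")[:16],
        description="synthetic genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for gene, start, end, strand in features:
        quals = {"locus_tag": [gene.gene_id]}
        if gene.product:
            quals["product"] = [gene.product]
        record.features.append(
            SeqFeature(FeatureLocation(start, end, strand=strand), type="CDS", qualifiers=quals)
        )
    from Bio import SeqIO

    SeqIO.write([record], str(path), "genbank")


def write_truth_tsv(truth: TruthRecord, genome: GenomeSet, path: str | Path) -> None:
    """Write per-gene ground truth as TSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "family_tag", "true_strand_class"])
        for gene in genome.genes:
            writer.writerow(
                [
                    gene.gene_id,
                    gene.family_tag or "",
                    truth.strand_labels.get(gene.gene_id, ""),
                ]
            )
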