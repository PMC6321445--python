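"""Reading, validating and annotating bacterial coding sequences.

Coding sequences arrive either as multi-record nucleotide FASTA (one CDS
per record) or as GenBank flat files with CDS features.  Validation
enforces reading-frame sanity (length a multiple of three, no internal
stop codon, a minimum length) and splits the terminal stop codon into a
separate record so downstream statistics operate on sense codons only.

Replication leading/lagging strand classes are inferred from the
genome-wide cumulative GC skew: in most bacteria the leading strand
carries an excess of G over C, so the cumulative sum of (G-C)/(G+C)
reaches its minimum at the replication origin and its maximum at the
terminus.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from .genetic_code import NUCLEOTIDES, STOP_CODONS

__all__ = [
    "CodingSequence",
    "StopRecord",
    "Rejection",
    "GenomeSet",
    "validate_cds",
    "read_cds_fasta",
    "read_cds_genbank",
    "infer_replication_strands",
    "write_validation_report",
]

#: Genes shorter than this many sense codons are rejected: RSCU and ENC
#: are too unstable on shorter genes to be meaningful.
MIN_CODONS_DEFAULT = 30

_VALID_CHARS = set(NUCLEOTIDES)


@dataclass
class CodingSequence:
    """One validated CDS, stored as a list of sense codons.

    The terminal stop codon is never part of ``codons``; see
    :class:`StopRecord`.  ``start_coord`` is a 0-based half-open genome
    offset when the gene came from an annotated genome.
    """

    gene_id: str
    codons: tuple[str, ...]
    strand_class: str = "unknown"  # leading | lagging | unknown
    family_tag: str | None = None
    source_strand: str = "unknown"  # + | - | unknown
    start_coord: int | None = None
    product: str | None = None
    ambiguous_codons: int = 0

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass
class StopRecord:
    gene_id: str
    stop_codon: str | None = None


@dataclass
class Rejection:
    gene_id: str
    reason: str


@dataclass
class GenomeSet:
    """A labelled collection of validated coding sequences."""

    label: str
    genes: list[CodingSequence] = field(default_factory=list)
    stops: list[StopRecord] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)
    ori_position: int | None = None
    ter_position: int | None = None
    low_confidence_strands: bool = False

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.genes)

    def add(self, gene: CodingSequence, stop: StopRecord | None = None) -> None:
        if any(g.gene_id == gene.gene_id for g in self.genes):
            self.rejections.append(Rejection(gene.gene_id, "duplicate_id"))
            return
        self.genes.append(gene)
        if stop is not None:
            self.stops.append(stop)

    def family(self, tag: str) -> list[CodingSequence]:
        return [g for g in self.genes if g.family_tag == tag]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def validate_cds(
    raw: str,
    gene_id: str = "gene",
    *,
    min_codons: int = MIN_CODONS_DEFAULT,
    family_tag: str | None = None,
    product: str | None = None,
) -> tuple[CodingSequence, StopRecord] | Rejection:
    """Validate a raw nucleotide CDS string.

    Returns a ``(CodingSequence, StopRecord)`` pair on success, or a
    :class:`Rejection` with a machine-readable reason code:
    ``length_not_multiple_of_3``, ``internal_stop``, ``too_short`` or
    ``empty``.  Codons containing characters outside A/C/G/T are dropped
    from the codon list but counted in ``ambiguous_codons``.
    """
    seq = raw.strip().upper().replace("U", "T")
    if not seq:
        return Rejection(gene_id, "empty")
    if len(seq) % 3 != 0:
        return Rejection(gene_id, "length_not_multiple_of_3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stop_codon = None
    if codons and codons[-1] in STOP_CODONS:
        stop_codon = codons.pop()
    kept: list[str] = []
    ambiguous = 0
    for c in codons:
        if set(c) <= _VALID_CHARS:
            kept.append(c)
        else:
            ambiguous += 1
    if any(c in STOP_CODONS for c in kept):
        return Rejection(gene_id, "internal_stop")
    if len(kept) < min_codons:
        return Rejection(gene_id, "too_short")
    gene = CodingSequence(
        gene_id=gene_id,
        codons=tuple(kept),
        family_tag=family_tag,
        product=product,
        ambiguous_codons=ambiguous,
    )
    return gene, StopRecord(gene_id, stop_codon)


def _parse_description_tags(description: str) -> dict[str, str]:
    # key=value tokens in a FASTA description, e.g. "family=T3ss product=..."
    tags = {}
    for token in description.split():
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value.replace("_", " ")
    return tags


def read_cds_fasta(
    path: str | Path,
    family_tag: str | None = None,
    *,
    label: str | None = None,
    min_codons: int = MIN_CODONS_DEFAULT,
) -> GenomeSet:
    """Read a multi-record nucleotide FASTA of coding sequences.

    Individual records that fail validation are recorded as rejections,
    never aborting the load.  Per-record ``family=`` and ``product=``
    tokens in the description are honoured; ``family_tag`` applies to
    every record when given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome = GenomeSet(label=label or path.stem)
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        tags = _parse_description_tags(record.description)
        result = validate_cds(
            str(record.seq),
            gene_id=record.id,
            min_codons=min_codons,
            family_tag=family_tag or tags.get("family"),
            product=tags.get("product"),
        )
        if isinstance(result, Rejection):
            genome.rejections.append(result)
        else:
            genome.add(*result)
    if n_records == 0:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def read_cds_genbank(
    path: str | Path,
    *,
    label: str | None = None,
    min_codons: int = MIN_CODONS_DEFAULT,
) -> GenomeSet:
    """Extract CDS features from a GenBank flat file.

    Features are extracted in coding orientation (minus-strand features
    reverse-complemented, compound locations concatenated in feature
    order by Biopython).  Pseudo-genes are skipped; features whose
    sequence fails validation are recorded as rejections.  GenBank
    1-based closed coordinates become 0-based half-open internally.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    genome = GenomeSet(label=label or records[0].id)
    counter = 0
    for record in records:
        for feature in record.features:
            if feature.type != "CDS":
                continue
            if "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers:
                continue
            counter += 1
            quals = feature.qualifiers
            gene_id = (
                quals.get("locus_tag", quals.get("gene", quals.get("protein_id", [f"cds_{counter}"])))
            )[0]
            product = quals.get("product", [None])[0]
            seq = str(feature.extract(record.seq))
            result = validate_cds(
                seq, gene_id=gene_id, min_codons=min_codons, product=product
            )
            if isinstance(result, Rejection):
                genome.rejections.append(result)
                continue
            gene, stop = result
            gene.source_strand = {1: "+", -1: "-"}.get(feature.location.strand, "unknown")
            gene.start_coord = int(feature.location.start)
            genome.add(gene, stop)
    return genome


def _window_skew(genome_sequence: str, window: int) -> np.ndarray:
    arr = np.frombuffer(genome_sequence.upper().encode(), dtype=np.uint8)
    n_win = len(arr) // window
    arr = arr[: n_win * window].reshape(n_win, window)
    g = (arr == ord("G")).sum(axis=1).astype(float)
    c = (arr == ord("C")).sum(axis=1).astype(float)
    total = g + c
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(total > 0, (g - c) / total, 0.0)
    return skew


def infer_replication_strands(
    genome_sequence: str,
    genome: GenomeSet,
    *,
    window: int | None = None,
    min_amplitude: float = 0.01,
) -> GenomeSet:
    """Assign leading/lagging strand classes from cumulative GC skew.

    The cumulative sum of per-window (G-C)/(G+C) is minimal at the
    replication origin and maximal at the terminus.  A plus-strand gene
    whose start lies on the ori->ter arc (increasing coordinates, with
    circular wrap-around) is leading; minus-strand genes are inverted.
    When the normalized amplitude of the cumulative curve falls below
    ``min_amplitude`` the labels are still assigned but the genome is
    flagged ``low_confidence_strands``.
    """
    length = len(genome_sequence)
    if window is None:
        window = max(length // 500, 1000)
    n_win = length // window
    if n_win < 10:
        warnings.warn(
            f"genome of {length} nt gives only {n_win} skew windows; "
            "strand classes left unknown",
            stacklevel=2,
        )
        for gene in genome.genes:
            gene.strand_class = "unknown"
        return genome

    skew = _window_skew(genome_sequence, window)
    cumulative = np.concatenate([[0.0], np.cumsum(skew)])
    ori_idx = int(np.argmin(cumulative))
    ter_idx = int(np.argmax(cumulative))
    ori = (ori_idx * window) % length
    ter = (ter_idx * window) % length
    amplitude = (cumulative[ter_idx] - cumulative[ori_idx]) / n_win
    genome.ori_position = ori
    genome.ter_position = ter
    genome.low_confidence_strands = bool(amplitude < min_amplitude)

    def on_forward_replichore(pos: int) -> bool:
        if ori <= ter:
            return ori <= pos < ter
        return pos >= ori or pos < ter

    for gene in genome.genes:
        if gene.start_coord is None or gene.source_strand not in "+-":
            gene.strand_class = "unknown"
            continue
        forward = on_forward_replichore(gene.start_coord % length)
        if gene.source_strand == "+":
            gene.strand_class = "leading" if forward else "lagging"
        else:
            gene.strand_class = "lagging" if forward else "leading"
    return genome


def write_validation_report(genome: GenomeSet, path: str | Path) -> None:
    """Write a TSV load report: gene_id, status, reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "status", "reason"])
        for gene in genome.genes:
            writer.writerow([gene.gene_id, "ok", ""])
        for rej in genome.rejections:
            writer.writerow([rej.gene_id, "rejected", rej.reason])


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]
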