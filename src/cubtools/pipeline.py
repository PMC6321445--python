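"""Full-analysis orchestration over one or more genomes.

``run_pipeline`` loads each input (FASTA or GenBank), tags gene
families by product annotation, and emits the complete report bundle:
per-genome composition, RSCU tables, per-gene indices, ENC-GC3 data
with the mutation-pressure null curve, stop-codon usage; and across
genomes, PCA of codon and amino-acid usage, ENC~GC3 and CAI~ENC
Spearman correlation tables, and the family-adaptation table.  Stages
fail independently: any error is recorded in the run manifest and the
remaining stages continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_indices import (
    CaiWeights,
    cai_weights,
    classify_representation,
    codon_counts,
    enc_expected,
    gene_indices,
    low_enc_reference,
    ribosomal_reference,
    rscu,
    stop_usage,
)
from .composition import composition_table, nucleotide_profile
from .genetic_code import ALL_CODONS, CODON_TO_AA, STOP_CODONS
from .multivariate import pca, spearman
from .sequence_io import GenomeSet, read_cds_fasta, read_cds_genbank
from .similarity import family_adaptation

logger = logging.getLogger("cubtools")

#: Default product-annotation patterns for the two chlamydial gene
#: families of interest; membership is configurable because published
#: family gene lists vary by annotation release.
DEFAULT_FAMILY_PATTERNS: dict[str, str] = {
    "Pmps": r"polymorphic membrane protein",
    "T3ss": r"type III secretion|T3SS|\bSct",
}


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    inputs: list[dict] = field(default_factory=list)  # {label, path, format}
    family_patterns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FAMILY_PATTERNS))
    cai_reference: str = "ribosomal"  # ribosomal | low_enc
    normalize_entropy: bool = False
    pca_level: str = "genome"  # genome | gene
    output_dir: str = "cubtools_out"
    make_figures: bool = True
    min_codons: int = 30
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def tag_families(genome: GenomeSet, patterns: dict[str, str]) -> GenomeSet:
    """Tag genes whose product annotation matches a family regex."""
    compiled = {tag: re.compile(pat, re.IGNORECASE) for tag, pat in patterns.items()}
    for gene in genome.genes:
        if gene.family_tag:
            continue
        if gene.product:
            for tag, rx in compiled.items():
                if rx.search(gene.product):
                    gene.family_tag = tag
                    break
    return genome


def _load_input(entry: dict, min_codons: int) -> GenomeSet:
    path = Path(entry["path"])
    fmt = entry.get("format") or ("genbank" if path.suffix in {".gb", ".gbk", ".genbank"} else "fasta")
    reader = read_cds_genbank if fmt == "genbank" else read_cds_fasta
    return reader(path, label=entry.get("label"), min_codons=min_codons)


def rscu_table(genome: GenomeSet) -> pd.DataFrame:
    """64-row codon table: codon, amino acid, count, RSCU, class.

    Stop codons report counts from stop records; ATG/TGG report counts
    with blank RSCU (single-codon families carry no usage signal).
    """
    counts = codon_counts(genome)
    stop_counts = {s: 0 for s in STOP_CODONS}
    for record in genome.stops:
        if record.stop_codon:
            stop_counts[record.stop_codon] += 1
    vec = rscu(counts, scope=genome.label)
    classes = classify_representation(vec)
    rows = []
    for codon in ALL_CODONS:
        if codon in STOP_CODONS:
            rows.append({"codon": codon, "amino_acid": "*", "count": stop_counts[codon],
                         "rscu": np.nan, "class": ""})
        elif codon in vec.values.index:
            rows.append({"codon": codon, "amino_acid": CODON_TO_AA[codon],
                         "count": counts.get(codon, 0),
                         "rscu": round(float(vec.values[codon]), 4),
                         "class": classes[codon]})
        else:  # ATG / TGG
            rows.append({"codon": codon, "amino_acid": CODON_TO_AA[codon],
                         "count": counts.get(codon, 0), "rscu": np.nan, "class": ""})
    return pd.DataFrame(rows)


def _cai_weights_for(genome: GenomeSet, policy: str) -> CaiWeights:
    reference = ribosomal_reference(genome) if policy == "ribosomal" else []
    label = "ribosomal proteins"
    if not reference:
        reference = low_enc_reference(genome)
        label = "lowest-ENC 5% of genes"
    return cai_weights(reference, reference_label=label)


def _enc_gc3_figure(indices: pd.DataFrame, label: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(indices["gc3"], indices["enc"], s=6, alpha=0.5, label="genes")
    s = np.linspace(0.01, 0.99, 200)
    ax.plot(s, [enc_expected(v) for v in s], "r-", label="expected (mutation pressure)")
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.set_title(label)
    ax.set_ylim(15, 63)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _pca_figure(result, title: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.coords[:, 0], result.coords[:, 1], s=20)
    for label, (x, y) in zip(result.labels, result.coords[:, :2]):
        ax.annotate(label, (x, y), fontsize=6)
    fx, fy = result.explained_fraction[:2] * 100
    ax.set_xlabel(f"f'1 ({fx:.1f}%)")
    ax.set_ylabel(f"f'2 ({fy:.1f}%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _family_figure(table: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    pivot = table.pivot(index="genome", columns="family", values="d_ab")
    pivot.plot.bar(ax=ax)
    ax.axhline(0.1, color="grey", linestyle="--", linewidth=0.8)
    ax.set_ylabel("D(A,B)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cubtools_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, fn):
        try:
            fn()
            manifest["stages"][stage] = "ok"
        except Exception as exc:  # stage isolation is deliberate
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = f"error: {exc}"

    def emit(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    genomes: dict[str, GenomeSet] = {}
    for entry in config.inputs:
        label = entry.get("label") or Path(entry["path"]).stem
        try:
            genome = _load_input(entry, config.min_codons)
            genome.label = label
            tag_families(genome, config.family_patterns)
            genomes[label] = genome
            manifest["stages"][f"load:{label}"] = "ok"
        except Exception as exc:
            logger.error("failed to load %s: %s", entry, exc)
            manifest["stages"][f"load:{label}"] = f"error: {exc}"
    if not genomes:
        raise ValueError("no readable inputs")

    # stable gene order inside each genome so outputs are input-order free
    for genome in genomes.values():
        genome.genes.sort(key=lambda g: g.gene_id)
        genome.stops.sort(key=lambda s: s.gene_id)

    record(
        "composition",
        lambda: emit(
            "composition.tsv",
            composition_table(genomes, normalize_entropy=config.normalize_entropy),
        ),
    )

    indices_by_genome: dict[str, pd.DataFrame] = {}
    for label, genome in genomes.items():
        def per_genome(label=label, genome=genome):
            emit(f"rscu_{label}.tsv", rscu_table(genome))
            weights = _cai_weights_for(genome, config.cai_reference)
            indices = gene_indices(genome, weights)
            indices_by_genome[label] = indices
            emit(f"indices_{label}.tsv", indices)
            usage = stop_usage(genome)
            emit(
                f"stop_usage_{label}.tsv",
                pd.DataFrame(
                    [
                        {"stop_codon": s, "count": usage.counts[s], "fraction": usage.fractions[s]}
                        for s in sorted(usage.counts)
                    ]
                ),
            )
            enc_gc3 = indices[["gene_id", "gc3", "enc"]].copy()
            enc_gc3["enc_expected"] = enc_gc3["gc3"].map(enc_expected)
            emit(f"enc_gc3_{label}.tsv", enc_gc3)
            if config.make_figures:
                _enc_gc3_figure(indices, label, outdir / f"enc_gc3_{label}.png")
                manifest["outputs"].append(f"enc_gc3_{label}.png")

        record(f"indices:{label}", per_genome)

    def correlations():
        rows_enc, rows_cai = [], []
        for label, idx in indices_by_genome.items():
            sub = idx.dropna(subset=["enc", "gc3"])
            res = spearman(sub["enc"], sub["gc3"])
            rows_enc.append({"strain": label, "r": res.r, "p": res.p, "n": res.n})
            sub = idx.dropna(subset=["cai", "enc"])
            res = spearman(sub["cai"], sub["enc"])
            rows_cai.append({"strain": label, "r": res.r, "p": res.p, "n": res.n})
        emit("correlation_enc_gc3.tsv", pd.DataFrame(rows_enc))
        emit("correlation_cai_enc.tsv", pd.DataFrame(rows_cai))

    record("correlations", correlations)

    def pca_stage():
        if config.pca_level == "gene":
            rows, labels = [], []
            for label, genome in genomes.items():
                for gene in genome.genes:
                    rows.append(rscu(gene).values.to_numpy())
                    labels.append(f"{label}:{gene.gene_id}")
            rscu_matrix = pd.DataFrame(rows, index=labels)
        else:
            rscu_matrix = pd.DataFrame(
                {label: rscu(codon_counts(g), scope=label).values for label, g in genomes.items()}
            ).T
        aa_matrix = pd.DataFrame(
            {
                label: pd.Series(nucleotide_profile_pooled_aa(genome))
                for label, genome in genomes.items()
            }
        ).T
        if len(rscu_matrix) >= 2:
            res = pca(rscu_matrix)
            coords = pd.DataFrame(
                res.coords[:, :2], columns=["f1", "f2"], index=res.labels
            ).reset_index(names="label")
            coords["explained_f1"] = res.explained_fraction[0]
            coords["explained_f2"] = (
                res.explained_fraction[1] if len(res.explained_fraction) > 1 else 0.0
            )
            emit("pca_rscu.tsv", coords)
            if config.make_figures:
                _pca_figure(res, "codon usage (RSCU) PCA", outdir / "pca_rscu.png")
                manifest["outputs"].append("pca_rscu.png")
        if len(aa_matrix) >= 2:
            res = pca(aa_matrix)
            coords = pd.DataFrame(
                res.coords[:, :2], columns=["f1", "f2"], index=res.labels
            ).reset_index(names="label")
            coords["explained_f1"] = res.explained_fraction[0]
            coords["explained_f2"] = (
                res.explained_fraction[1] if len(res.explained_fraction) > 1 else 0.0
            )
            emit("pca_aa.tsv", coords)
            if config.make_figures:
                _pca_figure(res, "amino-acid usage PCA", outdir / "pca_aa.png")
                manifest["outputs"].append("pca_aa.png")

    record("pca", pca_stage)

    def families():
        rows = []
        for label, genome in genomes.items():
            tags = sorted({g.family_tag for g in genome.genes if g.family_tag})
            if not tags:
                warnings.warn(f"no family-tagged genes in {label}", stacklevel=2)
            for tag in tags:
                res = family_adaptation(genome, tag)
                rows.append(
                    {
                        "genome": label,
                        "family": tag,
                        "n_genes": res.n_genes,
                        "r_ab": res.r_ab,
                        "d_ab": res.d_ab,
                    }
                )
        table = pd.DataFrame(rows, columns=["genome", "family", "n_genes", "r_ab", "d_ab"])
        emit("family_adaptation.tsv", table)
        if config.make_figures and len(table):
            _family_figure(table, outdir / "family_adaptation.png")
            manifest["outputs"].append("family_adaptation.png")

    record("families", families)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def nucleotide_profile_pooled_aa(genome: GenomeSet) -> dict[str, float]:
    """Pooled amino-acid frequencies of a genome (PCA input rows)."""
    from .composition import pooled_profile

    return pooled_profile(genome.genes, label=genome.label).aa_freq
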