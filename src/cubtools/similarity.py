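"""Codon-usage adaptation between gene families and their genome.

R(A,B) is the cosine of the angle between two 59-dimensional RSCU
vectors; since RSCU values are non-negative it lies in [0, 1].  The
distance transform D(A,B) = (1 - R)/2 therefore lies in [0, 0.5]: 0 for
identical codon usage, 0.5 for orthogonal usage.  Small D (below ~0.1)
indicates that a gene family's codon usage is adapted to that of the
genome as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_indices import RscuVector, codon_counts, rscu
from .sequence_io import GenomeSet

__all__ = ["SimilarityResult", "r_ab", "d_ab", "family_adaptation"]


@dataclass
class SimilarityResult:
    label_a: str
    label_b: str
    r_ab: float
    d_ab: float
    n_genes: int | None = None


def _as_array(vec) -> np.ndarray:
    if isinstance(vec, RscuVector):
        return vec.values.to_numpy(dtype=float)
    return np.asarray(vec, dtype=float)


def r_ab(a, b) -> float:
    """Cosine similarity of two RSCU vectors on the 59-codon universe."""
    va, vb = _as_array(a), _as_array(b)
    if va.shape != vb.shape:
        raise ValueError("RSCU vectors must share the same codon universe")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero RSCU vector")
    return float(np.dot(va, vb) / (na * nb))


def d_ab(a, b) -> float:
    """Codon-usage distance (1 - R(A,B)) / 2, in [0, 0.5]."""
    return (1.0 - r_ab(a, b)) / 2.0


def family_adaptation(genome: GenomeSet, family_tag: str) -> SimilarityResult:
    """Adaptation of a tagged gene family's codon usage to the genome's.

    The family RSCU vector is computed from the pooled counts of the
    tagged genes (robust to short genes), the genome vector from the
    pooled counts of all genes.
    """
    members = genome.family(family_tag)
    if not members:
        raise ValueError(f"no genes tagged {family_tag!r} in {genome.label}")
    vec_family = rscu(codon_counts(members), scope=family_tag)
    vec_genome = rscu(codon_counts(genome), scope=genome.label)
    r = r_ab(vec_family, vec_genome)
    return SimilarityResult(
        label_a=family_tag,
        label_b=genome.label,
        r_ab=r,
        d_ab=(1.0 - r) / 2.0,
        n_genes=len(members),
    )
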