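"""Rcodon: random genomes of IID codons, and toy GenBank fixtures.

An Rcodon genome is a sequence of independent, identically distributed
codons drawn from a codon usage, matching the length of the genome it
emulates (truncated down to a whole number of codons). By definition its
frame +1 ORFs — as found by the standard scanner — are its "annotated"
genes; no gene set is planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._codons import CODON_NT, _DECODE_LUT
from .codon_model import CodonUsage


@dataclass(frozen=True)
class RcodonSpec:
    usage: CodonUsage
    length_bp: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 3:
            raise ValueError("length_bp must be >= 3")


def simulate(spec: RcodonSpec | None = None, *, usage: CodonUsage | None = None,
             length_bp: int | None = None, seed: int = 0) -> str:
    """Draw floor(length_bp / 3) IID codons from the usage and concatenate.

    Deterministic for a given (usage, length_bp, seed). Accepts either an
    :class:`RcodonSpec` or the individual keyword arguments.
    """
    if spec is None:
        if usage is None or length_bp is None:
            raise TypeError("simulate needs an RcodonSpec or usage= and length_bp=")
        spec = RcodonSpec(usage=usage, length_bp=length_bp, seed=seed)
    n_codons = spec.length_bp // 3
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(64, size=n_codons, p=spec.usage.probabilities)
    nts = CODON_NT[draws].reshape(-1)
    return _DECODE_LUT[nts].tobytes().decode()


def synthetic_usage(
    gc_content: float = 0.5, bias: float = 0.4, seed: int = 0
) -> CodonUsage:
    """A bacterial-like codon usage for simulation studies.

    Bacterial codon usage is dominated by positional nucleotide composition
    (overall GC content, with mild position-specific skews such as
    purine-rich first codon positions) modulated by a moderate
    codon-preference bias. This generator mirrors that structure: a
    product of per-position nucleotide frequencies set by ``gc_content``,
    multiplied by log-normal codon-level noise of scale ``bias``.

    ``bias = 0`` gives an exact product-form usage (all six frames then
    share one codon distribution); ``bias`` around 0.4 gives codon
    preference ratios typical of bacterial genomes. Strictly positive for
    any ``gc_content`` in (0, 1).
    """
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_content) / 2
    gc = gc_content / 2
    base = np.array([at, gc, gc, at])  # A, C, G, T
    f1 = base * np.array([1.3, 0.9, 1.2, 0.7])  # purine-rich first position
    f2 = base * np.array([1.2, 0.9, 0.8, 1.1])
    f3 = base
    p = np.einsum("a,b,c->abc", f1 / f1.sum(), f2 / f2.sum(), f3 / f3.sum())
    p = p.reshape(64) * np.exp(bias * rng.standard_normal(64))
    return CodonUsage(p / p.sum(), source=f"synthetic gc={gc_content} bias={bias}")


def make_fixture(
    genes: list[tuple[str, str] | str],
    spacers: list[str] | None = None,
    path: str | Path | None = None,
    accession: str = "TOY0001",
):
    """Write a minimal valid GenBank file with CDS features.

    ``genes`` is a list of codon strings (start codon + body + stop codon,
    given 5'->3' on the coding strand), optionally paired with a strand
    ('+' or '-'). ``spacers`` are nucleotide strings placed before each
    gene (and, if one longer than the gene list, after the last).
    Coordinates are emitted so the file round-trips through read_genome.
    """
    norm: list[tuple[str, str]] = []
    for g in genes:
        if isinstance(g, str):
            norm.append((g, "+"))
        else:
            norm.append((g[0], g[1]))
    spacers = list(spacers or [])
    while len(spacers) < len(norm):
        spacers.append("")

    seq_parts: list[str] = []
    features: list[SeqFeature] = []
    pos = 0
    from ._codons import reverse_complement

    for i, (gene, strand) in enumerate(norm):
        gene = gene.replace(" ", "").upper()
        if len(gene) % 3:
            raise ValueError(f"gene spec {gene!r} not divisible by 3")
        seq_parts.append(spacers[i].upper())
        pos += len(spacers[i])
        start = pos  # 0-based
        if strand == "-":
            seq_parts.append(reverse_complement(gene))
        else:
            seq_parts.append(gene)
        pos += len(gene)
        features.append(
            SeqFeature(
                SimpleLocation(start, pos, strand=-1 if strand == "-" else 1),
                type="CDS",
                qualifiers={"locus_tag": [f"toy_{i + 1:04d}"]},
            )
        )
    if len(spacers) > len(norm):
        seq_parts.append(spacers[len(norm)].upper())

    record = SeqRecord(
        Seq("".join(seq_parts)),
        id=accession,
        name=accession,
        description="synthetic toy genome fixture",
        annotations={"molecule_type": "DNA", "topology": "linear"},
        features=features,
    )
    if path is not None:
        SeqIO.write(record, str(path), "genbank")
    return record


__all__ = ["RcodonSpec", "simulate", "make_fixture"]
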