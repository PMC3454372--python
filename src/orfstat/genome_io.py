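"""Genome and annotation input.

Reads GenBank flat files (or FASTA plus a tab-delimited gene table),
resolves IUPAC ambiguity symbols to concrete nucleotides with a seeded
uniform choice, and applies the gene filters used throughout the model:
a gene is kept only if its span is a multiple of three and its terminal
(start/stop) codon regions were fully determined in the raw sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

logger = logging.getLogger(__name__)

#: IUPAC ambiguity symbols and their possible concrete substitutions.
AMBIGUITY_TABLE: dict[str, str] = {
    "R": "AG",
    "Y": "CT",
    "M": "AC",
    "K": "GT",
    "S": "CG",
    "W": "AT",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "AGCT",
}

IUPAC_ALPHABET = frozenset("ACGT") | frozenset(AMBIGUITY_TABLE)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: 1-based inclusive coordinates on the forward strand."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid gene coordinates {self.start}..{self.end} for {self.gene_id}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A fully determined A/C/G/T genome sequence plus its gene annotations.

    ``sequence`` has all ambiguity symbols resolved; ``raw_sequence`` keeps
    the original characters so that the undetermined-position gene filter
    can still see them.
    """

    accession: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    topology: str = "linear"
    raw_sequence: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError("genome sequence must be at least 3 bp")
        if self.raw_sequence is None:
            self.raw_sequence = self.sequence
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} extends past the sequence end "
                    f"({g.end} > {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def substitute_ambiguous(sequence: str, seed: int = 0) -> str:
    """Replace every IUPAC ambiguity symbol by a uniformly chosen member of
    its substitution set; A/C/G/T positions pass through unchanged.

    Deterministic for a given ``(sequence, seed)`` pair.
    """
    seq = sequence.upper()
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    rng = np.random.default_rng(seed)
    for symbol, choices in AMBIGUITY_TABLE.items():
        positions = np.flatnonzero(arr == ord(symbol))
        if positions.size:
            picks = rng.integers(0, len(choices), size=positions.size)
            repl = np.frombuffer(choices.encode(), dtype=np.uint8)
            arr[positions] = repl[picks]
    return arr.tobytes().decode()


def _genes_from_genbank(record) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    n = len(record.seq)
    for feat in record.features:
        if feat.type != "CDS":
            continue
        qualifiers = feat.qualifiers
        gene_id = (
            qualifiers.get("locus_tag", qualifiers.get("gene", ["?"]))[0]
        )
        if "pseudo" in qualifiers or "pseudogene" in qualifiers:
            logger.warning("skipping pseudo-gene %s", gene_id)
            continue
        if isinstance(feat.location, CompoundLocation):
            logger.warning(
                "skipping gene %s with compound/wrap-around location", gene_id
            )
            continue
        start = int(feat.location.start) + 1  # to 1-based inclusive
        end = int(feat.location.end)
        if not 1 <= start <= end <= n:
            logger.warning("skipping gene %s outside sequence bounds", gene_id)
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        genes.append(GeneAnnotation(gene_id, start, end, strand))
    return genes


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a TSV gene table with header gene_id / start / end / strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "strand": str})
    required = {"gene_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    return [
        GeneAnnotation(r.gene_id, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


def read_genome(
    path: str | Path,
    format: str | None = None,
    seed: int = 0,
    gene_table: str | Path | None = None,
) -> GenomeRecord:
    """Load a genome with annotations from GenBank or FASTA (+ gene table).

    ``format`` is "genbank" or "fasta"; inferred from the file suffix when
    omitted. Ambiguity symbols are resolved with :func:`substitute_ambiguous`
    using ``seed``; the raw sequence is retained for gene filtering. Only
    the first record of a multi-record file is analyzed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "genbank" if suffix in {".gb", ".gbk", ".gbff", ".genbank"} else "fasta"
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc
    if not records:
        raise ValueError(f"no records found in {path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; analyzing only the first", path, len(records)
        )
    rec = records[0]
    raw = str(rec.seq).upper()
    if not raw:
        raise ValueError(f"empty sequence in {path}")
    if format == "genbank":
        genes = _genes_from_genbank(rec)
        topology = rec.annotations.get("topology", "linear")
    else:
        genes = read_gene_table(gene_table) if gene_table is not None else []
        topology = "linear"
    return GenomeRecord(
        accession=rec.id,
        sequence=substitute_ambiguous(raw, seed=seed),
        genes=genes,
        topology=topology,
        raw_sequence=raw,
    )


def filter_genes(record: GenomeRecord) -> list[GeneAnnotation]:
    """Apply the model's gene filters.

    A gene is kept only when its span is a multiple of three and neither of
    its terminal codon regions (first and last triplet of the span) carried
    an ambiguity symbol in the raw, pre-substitution sequence. Order is
    preserved; removals are logged.
    """
    raw = record.raw_sequence or record.sequence
    kept: list[GeneAnnotation] = []
    acgt = frozenset("ACGT")
    for g in record.genes:
        if g.span % 3 != 0:
            logger.info("filtered gene %s: span %d not a multiple of 3", g.gene_id, g.span)
            continue
        first = raw[g.start - 1 : g.start + 2]
        last = raw[g.end - 3 : g.end]
        if set(first + last) - acgt:
            logger.info(
                "filtered gene %s: undetermined position in terminal codon region",
                g.gene_id,
            )
            continue
        kept.append(g)
    return kept


def write_fasta(record: GenomeRecord, path: str | Path) -> None:
    """Write the resolved sequence as FASTA."""
    with open(path, "w") as fh:
        fh.write(f">{record.accession}\n")
        seq = record.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


__all__ = [
    "AMBIGUITY_TABLE",
    "GeneAnnotation",
    "GenomeRecord",
    "substitute_ambiguous",
    "read_genome",
    "read_gene_table",
    "filter_genes",
    "write_fasta",
]
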