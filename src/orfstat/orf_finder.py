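"""Six-frame ORF scanning and relative reading-frame assignment.

An ORF is the longest run of in-frame triplets from a start codon (NTG by
default) to the next in-frame stop codon: per (frame, stop) exactly one ORF
is emitted, beginning at the first start codon after the previous in-frame
stop. Runs reaching the sequence end without a stop are discarded. All
coordinates are reported 1-based inclusive on the forward strand.

Relative reading frames are labelled {+1,+2,+3,-1,-2,-3} with +1 the frame
of the annotated gene at a locus and -1 the antiparallel in-register frame
(codons occupying the same forward triplets, read on the other strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._codons import (
    COMPLEMENT,
    DEFAULT_START_CODONS,
    DEFAULT_STOP_CODONS,
    codon_indices,
    codon_set_mask,
    encode_sequence,
    reverse_complement,
)
from .genome_io import GeneAnnotation, GenomeRecord

logger = logging.getLogger(__name__)

ORF_COLUMNS = [
    "frame_absolute",
    "strand",
    "start_bp",
    "end_bp",
    "length_bp",
    "length_codons",
    "is_annotated",
    "frame_relative",
]

# forward phase of the first nt of the codon grid -> minus-frame label
_MINUS_FRAME_BY_PHASE = {0: -1, 2: -2, 1: -3}


class Orf(NamedTuple):
    frame_absolute: int
    strand: str
    start_bp: int
    end_bp: int
    length_bp: int
    length_codons: int
    is_annotated: bool
    frame_relative: object  # int or None when unassigned


@dataclass
class OrfSet:
    """A set of ORFs held as a DataFrame with :data:`ORF_COLUMNS` columns."""

    df: pd.DataFrame
    source: str = ""
    start_set: frozenset[str] = frozenset(DEFAULT_START_CODONS)
    stop_set: frozenset[str] = frozenset(DEFAULT_STOP_CODONS)

    def __post_init__(self) -> None:
        self.df = self.df.reindex(columns=ORF_COLUMNS)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Orf(*row)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        """BED6 export: 0-based half-open, name = frame label."""
        bed = pd.DataFrame(
            {
                "chrom": self.source or "genome",
                "start": self.df["start_bp"] - 1,
                "end": self.df["end_bp"],
                "name": [
                    f"frame{f:+d}" for f in self.df["frame_absolute"]
                ],
                "score": self.df["length_codons"],
                "strand": self.df["strand"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


def _scan_strand(codons_by_offset, start_mask, stop_mask):
    """Longest-per-stop ORFs on one strand.

    Yields (offset, start_codon_idx, stop_codon_idx) triples, with codon
    indices counted within each frame's triplet grid.
    """
    for offset, cods in enumerate(codons_by_offset):
        stops = np.flatnonzero(stop_mask[cods])
        starts = np.flatnonzero(start_mask[cods])
        if stops.size == 0 or starts.size == 0:
            continue
        prev = np.concatenate(([-1], stops[:-1]))
        first = np.searchsorted(starts, prev + 1, side="left")
        ok = first < starts.size
        first_clip = np.minimum(first, starts.size - 1)
        ok &= starts[first_clip] < stops
        if ok.any():
            yield offset, starts[first_clip[ok]], stops[ok]


def find_orfs(
    sequence: str,
    start_set: frozenset[str] | set[str] = DEFAULT_START_CODONS,
    stop_set: frozenset[str] | set[str] = DEFAULT_STOP_CODONS,
    source: str = "",
) -> OrfSet:
    """Scan all six frames of ``sequence`` for ORFs.

    The sequence is treated as linear; ORFs without a terminating stop are
    not emitted. Minus-strand frames are labelled by the forward phase of
    their codon grid so that -1 is in-register with absolute frame +1.
    """
    if not sequence:
        raise ValueError("empty sequence")
    enc = encode_sequence(sequence)
    n = len(enc)
    start_mask = codon_set_mask(start_set)
    stop_mask = codon_set_mask(stop_set)
    if (start_mask & stop_mask).any():
        raise ValueError("start and stop codon sets must be disjoint")

    parts = []
    fwd = [codon_indices(enc, off) for off in range(3)]
    for off, a, b in _scan_strand(fwd, start_mask, stop_mask):
        parts.append(
            pd.DataFrame(
                {
                    "frame_absolute": off + 1,
                    "strand": "+",
                    "start_bp": off + 3 * a + 1,
                    "end_bp": off + 3 * b + 3,
                    "length_codons": b - a,
                }
            )
        )

    rc = COMPLEMENT[enc][::-1]
    rev = [codon_indices(rc, off) for off in range(3)]
    for off, a, b in _scan_strand(rev, start_mask, stop_mask):
        # map reverse-complement coordinates back to the forward strand
        start_bp = n - (off + 3 * b + 3) + 1
        end_bp = n - (off + 3 * a + 1) + 1
        frames = np.vectorize(_MINUS_FRAME_BY_PHASE.get)((start_bp - 1) % 3)
        parts.append(
            pd.DataFrame(
                {
                    "frame_absolute": frames,
                    "strand": "-",
                    "start_bp": start_bp,
                    "end_bp": end_bp,
                    "length_codons": b - a,
                }
            )
        )

    if parts:
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["frame_absolute", "strand", "start_bp", "end_bp", "length_codons"]
        )
    df["length_bp"] = df["end_bp"] - df["start_bp"] + 1
    df["is_annotated"] = False
    df["frame_relative"] = None
    df = df.sort_values(["start_bp", "end_bp", "frame_absolute"], kind="stable")
    df = df.reset_index(drop=True)
    return OrfSet(df, source=source, start_set=frozenset(start_set), stop_set=frozenset(stop_set))


def extract_aorfs(
    record: GenomeRecord,
    filtered_genes: list[GeneAnnotation],
    stop_set: frozenset[str] | set[str] = DEFAULT_STOP_CODONS,
) -> OrfSet:
    """One annotated ORF per gene, spanning exactly the annotated range.

    The annotated start codon is taken as the beginning (upstream starts are
    ignored). Genes whose final triplet is not in ``stop_set`` are kept but
    logged — some annotations lack the stop codon or use read-through.
    """
    n = len(record.sequence)
    rows = []
    for g in filtered_genes:
        if g.end > n:
            raise ValueError(f"gene {g.gene_id} outside sequence")
        if g.strand == "+":
            frame = (g.start - 1) % 3 + 1
            last = record.sequence[g.end - 3 : g.end]
        else:
            frame = _MINUS_FRAME_BY_PHASE[(g.start - 1) % 3]
            last = reverse_complement(record.sequence[g.start - 1 : g.start + 2])
        if last not in stop_set:
            logger.info("gene %s does not end in a stop codon (%s)", g.gene_id, last)
        rows.append((frame, g.strand, g.start, g.end, g.span // 3 - 1))
    df = pd.DataFrame(
        rows, columns=["frame_absolute", "strand", "start_bp", "end_bp", "length_codons"]
    )
    df["length_bp"] = df["end_bp"] - df["start_bp"] + 1
    df["is_annotated"] = True
    df["frame_relative"] = 1
    return OrfSet(df, source=record.accession, stop_set=frozenset(stop_set))


def _orientation_phase(start_bp: np.ndarray, end_bp: np.ndarray, n: int, plus_frame: bool):
    """Codon-grid phase of ORFs, measured in a chosen orientation.

    ``plus_frame`` selects the forward orientation ((start-1) mod 3) or the
    reverse orientation ((n - end) mod 3).
    """
    return (start_bp - 1) % 3 if plus_frame else (n - end_bp) % 3


# d = (phase_na - phase_a) mod 3 in the aORF's orientation
_SAME_STRAND_FRAME = {0: 1, 1: 2, 2: 3}
_OPPOSITE_STRAND_FRAME = {0: -1, 1: -3, 2: -2}


def relative_frame(
    na_start: int, na_end: int, na_strand: str,
    a_start: int, a_end: int, a_strand: str,
    genome_bp: int,
) -> int:
    """Reading frame of one ORF relative to an annotated ORF (its frame = +1)."""
    a_plus = a_strand == "+"
    phase_a = _orientation_phase(np.int64(a_start), np.int64(a_end), genome_bp, a_plus)
    phase_na = _orientation_phase(np.int64(na_start), np.int64(na_end), genome_bp, a_plus)
    d = int((phase_na - phase_a) % 3)
    if na_strand == a_strand:
        return _SAME_STRAND_FRAME[d]
    return _OPPOSITE_STRAND_FRAME[d]


def assign_naorf_frames(all_orfs: OrfSet, aorfs: OrfSet, genome_bp: int | None = None) -> OrfSet:
    """Assign relative frames to non-annotated ORFs by overlap with aORFs.

    Every naORF overlapping at least one aORF by >= 1 bp gets the relative
    frame implied by the dominant overlapped aORF (largest overlap in bp;
    ties to the longer aORF, then the lower start coordinate). naORFs in
    gene-free gaps stay unassigned (frame_relative None). Annotated ORFs
    present in ``all_orfs`` (same frame, start and end as an aORF) are
    marked annotated with frame_relative +1.
    """
    df = all_orfs.df.copy()
    a = aorfs.df
    if genome_bp is None:
        genome_bp = int(
            max(df["end_bp"].max() if len(df) else 3, a["end_bp"].max() if len(a) else 3)
        )
    if len(a) == 0:
        return OrfSet(df, source=all_orfs.source, start_set=all_orfs.start_set,
                      stop_set=all_orfs.stop_set)

    tree = IntervalTree()
    for i, r in enumerate(a.itertuples(index=False)):
        tree.addi(r.start_bp, r.end_bp + 1, i)  # half-open on 1-based inclusive

    # a scanned ORF "is" an annotated gene when it shares the gene's stop
    # codon (the scanner may start upstream of the annotated start)
    annotated_keys = {
        (r.strand, r.end_bp if r.strand == "+" else r.start_bp)
        for r in a.itertuples(index=False)
    }

    rel = np.empty(len(df), dtype=object)
    ann = np.zeros(len(df), dtype=bool)
    a_start = a["start_bp"].to_numpy()
    a_end = a["end_bp"].to_numpy()
    a_strand = a["strand"].to_numpy()
    a_len = a_end - a_start

    for j, r in enumerate(df.itertuples(index=False)):
        stop_key = (r.strand, r.end_bp if r.strand == "+" else r.start_bp)
        if stop_key in annotated_keys:
            ann[j] = True
            rel[j] = 1
            continue
        hits = tree.overlap(r.start_bp, r.end_bp + 1)
        if not hits:
            rel[j] = None
            continue
        best = None
        for h in hits:
            i = h.data
            ov = min(r.end_bp, a_end[i]) - max(r.start_bp, a_start[i]) + 1
            key = (ov, a_len[i], -a_start[i])
            if best is None or key > best[0]:
                best = (key, i)
        i = best[1]
        rel[j] = relative_frame(
            r.start_bp, r.end_bp, r.strand,
            int(a_start[i]), int(a_end[i]), str(a_strand[i]), genome_bp,
        )
    df["frame_relative"] = rel
    df["is_annotated"] = ann
    return OrfSet(df, source=all_orfs.source, start_set=all_orfs.start_set,
                  stop_set=all_orfs.stop_set)


def orf_statistics(orfs: OrfSet) -> dict:
    """Count, mean/max length, lower nearest-rank 75% quantile, per-frame counts."""
    if len(orfs) == 0:
        raise ValueError("empty ORF set")
    lengths = orfs.df["length_codons"].to_numpy()
    frame_key = (
        orfs.df["frame_relative"].where(orfs.df["frame_relative"].notna(),
                                        orfs.df["frame_absolute"])
    )
    return {
        "count": int(lengths.size),
        "mean_length_codons": float(lengths.mean()),
        "quantile75_codons": int(nearest_rank_quantile(lengths, 0.75)),
        "max_length_codons": int(lengths.max()),
        "per_frame_counts": frame_key.value_counts().to_dict(),
    }


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Lower nearest-rank quantile: the ceil(q*n)-th smallest value."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("empty data")
    rank = max(1, int(np.ceil(q * v.size)))
    return v[rank - 1]


__all__ = [
    "Orf",
    "OrfSet",
    "ORF_COLUMNS",
    "find_orfs",
    "extract_aorfs",
    "assign_naorf_frames",
    "relative_frame",
    "orf_statistics",
    "nearest_rank_quantile",
]
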