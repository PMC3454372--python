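"""Pipeline orchestration: genome -> usage -> model -> Rcodon -> comparison.

``compare`` reproduces the global-statistics comparison between a natural
genome, its Rcodon random counterpart and the analytical mixture model;
``shadow_candidates`` lists non-annotated ORFs too long to be explained by
the per-frame geometric null (overlapping-gene candidates).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_model import (
    FRAMES,
    CodonUsage,
    GeneticCodeConfig,
    codon_usage,
    frame_probabilities,
)
from .genome_io import GenomeRecord, filter_genes
from .mixture_model import MixtureModel, build_model
from .orf_finder import (
    OrfSet,
    assign_naorf_frames,
    extract_aorfs,
    find_orfs,
    nearest_rank_quantile,
)
from .rcodon import RcodonSpec, simulate

logger = logging.getLogger(__name__)


@dataclass
class SourceSummary:
    total_orfs: float
    annotated_orfs: float
    non_annotated_orfs: float
    mean_length_codons: float
    quantile75_codons: float
    max_length_codons: float | None
    ratio_annotated_to_non_annotated: float
    per_frame_counts: dict = field(default_factory=dict)


@dataclass
class ComparisonReport:
    genome: SourceSummary
    rcodon: SourceSummary
    model: SourceSummary
    accession: str
    genome_bp: int
    unassigned_naorfs: int
    longest_naorf_survival: dict = field(default_factory=dict)
    model_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def enc(s: SourceSummary) -> dict:
            d = dict(s.__dict__)
            d["per_frame_counts"] = {str(k): float(v) for k, v in s.per_frame_counts.items()}
            return d

        return {
            "accession": self.accession,
            "genome_bp": self.genome_bp,
            "unassigned_naorfs": self.unassigned_naorfs,
            "genome": enc(self.genome),
            "rcodon": enc(self.rcodon),
            "model": enc(self.model),
            "longest_naorf_survival": self.longest_naorf_survival,
            "model_params": self.model_params,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")

    def to_text(self) -> str:
        rows = []
        header = f"{'':34s}{'genome':>12s}{'Rcodon':>12s}{'model':>12s}"
        rows.append(f"# {self.accession} ({self.genome_bp} bp)")
        rows.append(header)
        for label, attr, fmt in [
            ("total ORFs", "total_orfs", "{:.0f}"),
            ("annotated ORFs (frame +1)", "annotated_orfs", "{:.0f}"),
            ("non-annotated ORFs", "non_annotated_orfs", "{:.0f}"),
            ("mean length [codons]", "mean_length_codons", "{:.2f}"),
            ("75% quantile [codons]", "quantile75_codons", "{:.0f}"),
            ("aORF/naORF ratio", "ratio_annotated_to_non_annotated", "{:.4f}"),
        ]:
            vals = [
                fmt.format(getattr(s, attr))
                for s in (self.genome, self.rcodon, self.model)
            ]
            rows.append(f"{label:34s}" + "".join(f"{v:>12s}" for v in vals))
        return "\n".join(rows)


def _summarize_scan(orfs: OrfSet, annotated_mask: np.ndarray) -> SourceSummary:
    lengths = orfs.df["length_codons"].to_numpy()
    n_ann = int(annotated_mask.sum())
    n_na = int(len(orfs) - n_ann)
    frame_key = orfs.df["frame_relative"].where(
        orfs.df["frame_relative"].notna(), orfs.df["frame_absolute"]
    )
    return SourceSummary(
        total_orfs=len(orfs),
        annotated_orfs=n_ann,
        non_annotated_orfs=n_na,
        mean_length_codons=float(lengths.mean()),
        quantile75_codons=float(nearest_rank_quantile(lengths, 0.75)),
        max_length_codons=float(lengths.max()),
        ratio_annotated_to_non_annotated=n_ann / n_na if n_na else float("inf"),
        per_frame_counts=frame_key.value_counts().to_dict(),
    )


def _summarize_model(model: MixtureModel) -> SourceSummary:
    counts = dict(zip(model.frames, model.counts))
    n1 = counts[1]
    n_na = model.total_count - n1
    return SourceSummary(
        total_orfs=model.total_count,
        annotated_orfs=n1,
        non_annotated_orfs=n_na,
        mean_length_codons=model.average_orf_length(),
        quantile75_codons=float(model.quantile(0.75)),
        max_length_codons=None,
        ratio_annotated_to_non_annotated=n1 / n_na,
        per_frame_counts=counts,
    )


def _frame1_as_annotated(orfs: OrfSet) -> np.ndarray:
    """Rcodon convention: absolute frame +1 ORFs are the annotated set."""
    mask = (orfs.df["frame_absolute"] == 1).to_numpy()
    df = orfs.df
    df["is_annotated"] = mask
    df["frame_relative"] = df["frame_absolute"]
    return mask


def build_genome_model(
    record: GenomeRecord,
    code: GeneticCodeConfig | None = None,
    gene_subset: set[str] | None = None,
) -> tuple[MixtureModel, CodonUsage, OrfSet]:
    """Fit the mixture model to a genome: filter genes, extract aORFs,
    estimate codon usage (optionally from a gene-ID subset), derive frame
    probabilities, and build the model."""
    code = code or GeneticCodeConfig()
    genes = filter_genes(record)
    if gene_subset is not None:
        genes = [g for g in genes if g.gene_id in gene_subset]
    if not genes:
        raise ValueError("no genes left after filtering; codon usage undefined")
    aorfs = extract_aorfs(record, genes, stop_set=code.stop_set)
    usage = codon_usage(aorfs, record.sequence)
    fp = frame_probabilities(usage, code)
    model = build_model(fp, len(record.sequence))
    return model, usage, aorfs


def compare(
    record: GenomeRecord,
    seed: int = 0,
    gene_subset: set[str] | None = None,
    code: GeneticCodeConfig | None = None,
) -> ComparisonReport:
    """Full genome / Rcodon / model comparison of global ORF statistics."""
    code = code or GeneticCodeConfig()
    t0 = time.perf_counter()
    model, usage, aorfs = build_genome_model(record, code, gene_subset)
    logger.info("model built in %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    scanned = find_orfs(
        record.sequence, code.start_set, code.stop_set, source=record.accession
    )
    scanned = assign_naorf_frames(scanned, aorfs, genome_bp=len(record.sequence))
    logger.info("genome scan: %d ORFs in %.2fs", len(scanned), time.perf_counter() - t0)

    t0 = time.perf_counter()
    rseq = simulate(RcodonSpec(usage, len(record.sequence), seed))
    rorfs = find_orfs(rseq, code.start_set, code.stop_set, source="Rcodon")
    rmask = _frame1_as_annotated(rorfs)
    logger.info("Rcodon scan: %d ORFs in %.2fs", len(rorfs), time.perf_counter() - t0)

    genome_summary = _summarize_scan(scanned, scanned.df["is_annotated"].to_numpy())
    rcodon_summary = _summarize_scan(rorfs, rmask)
    model_summary = _summarize_model(model)

    na = scanned.df[~scanned.df["is_annotated"]]
    unassigned = int(na["frame_relative"].isna().sum())
    longest: dict[str, dict] = {}
    for f in FRAMES:
        if f == 1:
            continue
        sub = na[na["frame_relative"] == f]
        if len(sub):
            lmax = int(sub["length_codons"].max())
            sr = model.survival(lmax, frame=f)
            longest[f"{f:+d}"] = {
                "length_codons": lmax,
                "survival": sr.survival,
                "N_frame": float(model.counts[model.frame_index(f)]),
            }

    return ComparisonReport(
        genome=genome_summary,
        rcodon=rcodon_summary,
        model=model_summary,
        accession=record.accession,
        genome_bp=len(record.sequence),
        unassigned_naorfs=unassigned,
        longest_naorf_survival=longest,
        model_params=model.to_dict(),
    )


def shadow_candidates(
    record: GenomeRecord,
    pvalue: float = 0.01,
    code: GeneticCodeConfig | None = None,
    model: MixtureModel | None = None,
) -> pd.DataFrame:
    """Non-annotated ORFs whose per-frame survival probability <= pvalue.

    The survival of each naORF's length is evaluated under its relative
    frame's geometric tail with that frame's expected trial count N_i; no
    multiple-testing correction is applied (N_i columns let users apply
    their own). Sorted ascending by survival.
    """
    if not 0 <= pvalue <= 1:
        raise ValueError("pvalue must be in [0, 1]")
    code = code or GeneticCodeConfig()
    if model is None:
        model, _, aorfs = build_genome_model(record, code)
    else:
        genes = filter_genes(record)
        aorfs = extract_aorfs(record, genes, stop_set=code.stop_set)
    scanned = find_orfs(
        record.sequence, code.start_set, code.stop_set, source=record.accession
    )
    scanned = assign_naorf_frames(scanned, aorfs, genome_bp=len(record.sequence))
    na = scanned.df[~scanned.df["is_annotated"]].copy()
    na = na[na["frame_relative"].notna() & (na["frame_relative"] != 1)]

    survs = np.empty(len(na))
    trials = np.empty(len(na))
    for k, r in enumerate(na.itertuples(index=False)):
        f = int(r.frame_relative)
        sr = model.survival(int(r.length_codons), frame=f)
        survs[k] = sr.survival
        trials[k] = sr.trials
    na["survival"] = survs
    na["N_frame"] = trials
    out = na[na["survival"] <= pvalue].sort_values("survival", kind="stable")
    cols = [
        "frame_relative", "strand", "start_bp", "end_bp",
        "length_codons", "survival", "N_frame",
    ]
    return out[cols].reset_index(drop=True)


__all__ = [
    "SourceSummary",
    "ComparisonReport",
    "build_genome_model",
    "compare",
    "shadow_candidates",
]
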