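"""Codon usage and per-reading-frame start/stop codon probabilities.

The model's only fitted input is the codon usage pi: the frequency of each
of the 64 codons in the concatenation of all annotated ORFs (terminal stop
codons included). From pi the six relative reading frames get their stop
probability rho_i and start probability tau_i:

* frame +1 reads the IID codon stream directly, so rho and tau are sums of
  pi over the stop/start sets;
* frame -1 reads the same triplets on the other strand, i.e. the usage
  q(c) = pi(revcomp(c));
* frames +2/+3 read triplets straddling two consecutive +1 codons. Over an
  IID codon stream this frame-shifted triplet process is a 64-state Markov
  chain with memory one; its stationary distribution supplies rho and tau.
  Frames -2/-3 apply the same construction to the -1 usage.

For frame +2 the state is (last 2 nt of codon k, first nt of codon k+1) and

    Q((a,b,c) -> (d,e,f)) = pi(c,d,e)/m1(c) * m1(f),

with m1 the first-position nucleotide marginal of pi; for +3 the state is
(last nt of codon k, first 2 nt of codon k+1) and

    Q((a,b,c) -> (d,e,f)) = pi(b,c,d)/m12(b,c) * m12(e,f),

with m12 the first-two-position marginal. These are the unique memory-one
laws of the shifted triplet process and have the product-form stationary
distributions m23 x m1 (frame +2) and m3 x m12 (frame +3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from ._codons import (
    CODONS,
    CODON_INDEX,
    DEFAULT_START_CODONS,
    DEFAULT_STOP_CODONS,
    MOLLICUTE_STOP_CODONS,
    RC_PERMUTATION,
    codon_indices,
    codon_set_mask,
    encode_sequence,
    reverse_complement,
)
from .orf_finder import OrfSet

FRAMES = (1, 2, 3, -1, -2, -3)

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class GeneticCodeConfig:
    """Start and stop codon sets; the mollicute variant drops TGA."""

    stop_set: frozenset[str] = frozenset(DEFAULT_STOP_CODONS)
    start_set: frozenset[str] = frozenset(DEFAULT_START_CODONS)

    def __post_init__(self) -> None:
        if not self.stop_set or not self.start_set:
            raise ValueError("start and stop sets must be non-empty")
        if self.stop_set & self.start_set:
            raise ValueError("start and stop sets must be disjoint")

    @classmethod
    def standard(cls) -> "GeneticCodeConfig":
        return cls()

    @classmethod
    def mollicute(cls) -> "GeneticCodeConfig":
        return cls(stop_set=frozenset(MOLLICUTE_STOP_CODONS))


@dataclass
class CodonUsage:
    """Probability vector over the 64 codons (alphabetical AAA..TTT)."""

    probabilities: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (64,):
            raise ValueError("codon usage must have 64 entries")
        if (p < 0).any():
            raise ValueError("codon usage probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"codon usage must sum to 1, got {p.sum()}")
        self.probabilities = p / p.sum()

    def __getitem__(self, codon: str) -> float:
        return float(self.probabilities[CODON_INDEX[codon.upper()]])

    @classmethod
    def uniform(cls, source: str = "uniform") -> "CodonUsage":
        return cls(np.full(64, 1 / 64), source=source)

    @classmethod
    def from_counts(cls, counts: np.ndarray, source: str = "") -> "CodonUsage":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("no codons counted")
        return cls(counts / total, source=source)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"codon": CODONS, "probability": self.probabilities}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "CodonUsage":
        df = pd.read_csv(path, sep="\t")
        p = np.zeros(64)
        for codon, prob in zip(df["codon"], df["probability"]):
            p[CODON_INDEX[str(codon).upper()]] = float(prob)
        return cls(p, source=source if source is not None else str(path))


@dataclass
class TransitionMatrix:
    """Row-stochastic 64x64 transition law of a frame-shifted codon chain."""

    matrix: np.ndarray
    frame: int

    def __post_init__(self) -> None:
        q = np.asarray(self.matrix, dtype=float)
        if q.shape != (64, 64):
            raise ValueError("transition matrix must be 64x64")
        if (q < -_SUM_TOL).any():
            raise ValueError("negative transition probability")
        if np.abs(q.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("rows must sum to 1")
        self.matrix = q


@dataclass
class FrameProbabilities:
    """Per relative frame: stop probability rho_i, start probability tau_i."""

    rho: dict[int, float]
    tau: dict[int, float]
    distributions: dict[int, np.ndarray] = field(default_factory=dict)
    code: GeneticCodeConfig = field(default_factory=GeneticCodeConfig)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(rho, tau) arrays ordered like :data:`FRAMES`."""
        return (
            np.array([self.rho[f] for f in FRAMES]),
            np.array([self.tau[f] for f in FRAMES]),
        )


def codon_usage(aorfs: OrfSet, sequence: str) -> CodonUsage:
    """Codon usage from the concatenated annotated ORFs.

    Counts every triplet of every annotated ORF on its coding strand,
    including the terminal stop codon, and normalizes by the total.
    """
    counts = np.zeros(64)
    total = 0
    for r in aorfs.df.itertuples(index=False):
        sub = sequence[r.start_bp - 1 : r.end_bp]
        if len(sub) % 3:
            raise ValueError("annotated ORF span not a multiple of 3")
        if r.strand == "-":
            sub = reverse_complement(sub)
        idx = codon_indices(encode_sequence(sub))
        counts += np.bincount(idx, minlength=64)
        total += idx.size
    if total == 0:
        raise ValueError("no codons in annotated ORFs; usage undefined")
    return CodonUsage.from_counts(counts, source=aorfs.source)


def frame_minus1_usage(usage: CodonUsage) -> CodonUsage:
    """Codon distribution of the antiparallel in-register frame:
    q(c) = pi(reverse_complement(c))."""
    return CodonUsage(usage.probabilities[RC_PERMUTATION], source=f"{usage.source}:-1")


def _marginals(pi: np.ndarray):
    p3 = pi.reshape(4, 4, 4)
    m1 = p3.sum(axis=(1, 2))  # first nt
    m12 = p3.sum(axis=2)  # first two nt
    m23 = p3.sum(axis=0)  # last two nt
    m3 = p3.sum(axis=(0, 1))  # last nt
    return p3, m1, m12, m23, m3


def frame_shift_stationary(usage: CodonUsage, frame: int) -> np.ndarray:
    """Closed-form stationary codon distribution of the shifted frame.

    Frame +2: d(a,b,c) = m23(a,b) * m1(c); frame +3: d(a,b,c) = m3(a) *
    m12(b,c). Negative frames use the -1 usage. Serves as the frame's
    unconditional codon distribution for unreachable-row filling and as an
    independent cross-check of the linear-solve stationary distribution.
    """
    if frame in (-2, -3):
        return frame_shift_stationary(frame_minus1_usage(usage), -frame)
    p3, m1, m12, m23, m3 = _marginals(usage.probabilities)
    if frame == 2:
        d = m23[:, :, None] * m1[None, None, :]
    elif frame == 3:
        d = m3[:, None, None] * m12[None, :, :]
    else:
        raise ValueError(f"frame must be one of +2,+3,-2,-3, got {frame:+d}")
    return d.reshape(64)


def transition_matrix(usage: CodonUsage, frame: int) -> TransitionMatrix:
    """Memory-one transition law of the frame-shifted triplet process.

    Rows belonging to states whose conditioning context has zero marginal
    mass are unreachable; they are filled with the frame's unconditional
    codon distribution so the matrix stays stochastic without affecting the
    stationary law on the reachable class.
    """
    if frame in (-2, -3):
        tm = transition_matrix(frame_minus1_usage(usage), -frame)
        return TransitionMatrix(tm.matrix, frame)
    if frame not in (2, 3):
        raise ValueError(f"frame must be one of +2,+3,-2,-3, got {frame:+d}")

    p3, m1, m12, m23, m3 = _marginals(usage.probabilities)
    uncond = frame_shift_stationary(usage, frame)
    Q = np.zeros((64, 64))
    if frame == 2:
        # state (a,b,c): c is the first nt of the current +1 codon
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(m1[:, None, None] > 0, p3 / m1[:, None, None], 0.0)
        # next[(c); d,e,f] = cond[c,d,e] * m1[f]
        nxt = np.einsum("cde,f->cdef", cond, m1).reshape(4, 64)
        for s in range(64):
            c = s & 3
            if m1[c] > 0:
                Q[s] = nxt[c]
            else:
                if uncond[s] > 0:
                    raise ValueError(
                        f"degenerate usage: zero first-nt marginal for context "
                        f"{'ACGT'[c]!r} with nonzero inbound mass"
                    )
                Q[s] = uncond
    else:
        # state (a,b,c): (b,c) are the first two nt of the current +1 codon
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(m12[:, :, None] > 0, p3 / m12[:, :, None], 0.0)
        nxt = np.einsum("bcd,ef->bcdef", cond, m12).reshape(16, 64)
        for s in range(64):
            bc = s & 15
            b, c = bc >> 2, bc & 3
            if m12[b, c] > 0:
                Q[s] = nxt[bc]
            else:
                if uncond[s] > 0:
                    raise ValueError(
                        f"degenerate usage: zero first-two-nt marginal for context "
                        f"{'ACGT'[b]}{'ACGT'[c]!r} with nonzero inbound mass"
                    )
                Q[s] = uncond
    return TransitionMatrix(Q, frame)


def stationary_distribution(matrix: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution d with d Q = d, by direct linear solve.

    Raises on a reducible chain with more than one closed communicating
    class (the ergodicity premise of the model is then violated). States
    outside the unique closed class receive zero mass.
    """
    Q = matrix.matrix if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    n = Q.shape[0]
    n_comp, labels = connected_components(Q > 1e-15, directed=True, connection="strong")
    # a class is closed iff no positive transition leaves it
    closed = []
    for k in range(n_comp):
        members = labels == k
        if not (Q[members][:, ~members] > 1e-15).any():
            closed.append(k)
    if len(closed) > 1:
        classes = [sorted(np.flatnonzero(labels == k).tolist()) for k in closed]
        raise ValueError(f"reducible chain with multiple closed classes: {classes}")
    members = labels == closed[0]
    sub = Q[np.ix_(members, members)]
    m = sub.shape[0]
    A = np.vstack([sub.T - np.eye(m), np.ones((1, m))])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    d_sub, *_ = np.linalg.lstsq(A, b, rcond=None)
    d_sub = np.clip(d_sub, 0.0, None)
    d_sub /= d_sub.sum()
    resid = np.abs(d_sub @ sub - d_sub).sum()
    if resid > 1e-10:
        # fall back to power iteration
        d_sub = np.full(m, 1 / m)
        for _ in range(100_000):
            nxt = d_sub @ sub
            if np.abs(nxt - d_sub).sum() < 1e-14:
                d_sub = nxt
                break
            d_sub = nxt
        d_sub /= d_sub.sum()
    d = np.zeros(n)
    d[members] = d_sub
    return d


def frame_probabilities(
    usage: CodonUsage, code: GeneticCodeConfig | None = None
) -> FrameProbabilities:
    """Stop/start codon probabilities (rho_i, tau_i) for all six frames."""
    if code is None:
        code = GeneticCodeConfig()
    stop_mask = codon_set_mask(code.stop_set)
    start_mask = codon_set_mask(code.start_set)

    dists: dict[int, np.ndarray] = {1: usage.probabilities}
    dists[-1] = frame_minus1_usage(usage).probabilities
    for f in (2, 3, -2, -3):
        dists[f] = stationary_distribution(transition_matrix(usage, f))

    rho = {f: float(d[stop_mask].sum()) for f, d in dists.items()}
    tau = {f: float(d[start_mask].sum()) for f, d in dists.items()}
    return FrameProbabilities(rho=rho, tau=tau, distributions=dists, code=code)


__all__ = [
    "FRAMES",
    "GeneticCodeConfig",
    "CodonUsage",
    "TransitionMatrix",
    "FrameProbabilities",
    "codon_usage",
    "frame_minus1_usage",
    "frame_shift_stationary",
    "transition_matrix",
    "stationary_distribution",
    "frame_probabilities",
]
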