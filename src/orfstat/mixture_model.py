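"""The six-component geometric mixture of ORF lengths.

Per relative reading frame i with start probability tau_i and stop
probability rho_i, ORF occupancy along the codon stream is modelled by a
two-state Markov chain (enter an ORF on a start codon, leave it on a stop
codon), whose stationary law gives the in-ORF fraction

    alpha_i = tau_i / (tau_i + rho_i).

With n_i = floor(genome_bp / 3) codon positions per frame and an expected
in-ORF dwell of 1/rho_i codons, the expected ORF count per frame is

    N_i = n_i * alpha_i * rho_i = n_i * tau_i * rho_i / (tau_i + rho_i),

and the mixture weights are w_i = N_i / sum_j N_j. ORF length L (in codons,
start counted, stop excluded) is geometric per frame on support {1, 2, ...}:

    P(L = l) = sum_i w_i (1 - rho_i)^(l-1) rho_i,
    P(L >= l) = sum_i w_i (1 - rho_i)^(l-1),      E[L] = sum_i w_i / rho_i.

The survival probability of a length l among N trials,
S(l) = 1 - (1 - P(L >= l))^N, acts as a p-value against the random-genome
null and yields the p-value length limit by monotone bisection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_model import FRAMES, FrameProbabilities, GeneticCodeConfig


@dataclass(frozen=True)
class SurvivalResult:
    length: int
    tail: float  # P(L >= length)
    survival: float  # P(at least one ORF of length >= l in `trials` trials)
    trials: float


@dataclass
class MixtureModel:
    """Weighted mixture of six geometric ORF-length distributions."""

    rho: np.ndarray  # per frame, ordered like FRAMES
    tau: np.ndarray
    genome_bp: int
    frames: tuple[int, ...] = FRAMES
    code: GeneticCodeConfig = field(default_factory=GeneticCodeConfig)
    #: offset added to the (min_len - 1) tail exponent of the constrained
    #: gene-count prediction; frozen at 0 for the {1,2,...} support.
    tail_exponent_offset: int = 0

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.rho.shape != (len(self.frames),) or self.tau.shape != self.rho.shape:
            raise ValueError("rho/tau must have one entry per frame")
        if ((self.rho < 0) | (self.rho >= 1) | (self.tau < 0) | (self.tau >= 1)).any():
            raise ValueError("stop/start probabilities must lie in [0, 1)")
        if ((self.rho + self.tau) <= 0).any():
            raise ValueError("degenerate frame: tau_i + rho_i = 0")
        if (self.rho == 0).any() or (self.tau == 0).any():
            logging.getLogger(__name__).warning(
                "zero stop/start probability in some frame; "
                "survival quantities are degenerate there"
            )
        if self.genome_bp < 3:
            raise ValueError("genome_bp must be >= 3")

    @classmethod
    def from_frame_probabilities(
        cls, fp: FrameProbabilities, genome_bp: int, **kwargs
    ) -> "MixtureModel":
        rho, tau = fp.as_arrays()
        return cls(rho=rho, tau=tau, genome_bp=genome_bp, code=fp.code, **kwargs)

    # ---- derived parameters ------------------------------------------------

    @property
    def n_codon_positions(self) -> int:
        return self.genome_bp // 3

    @property
    def alpha(self) -> np.ndarray:
        """Stationary in-ORF fraction per frame."""
        return self.tau / (self.tau + self.rho)

    @property
    def counts(self) -> np.ndarray:
        """Expected ORF count N_i per frame."""
        return self.n_codon_positions * self.tau * self.rho / (self.tau + self.rho)

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def weights(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def frame_index(self, frame: int) -> int:
        return self.frames.index(frame)

    # ---- length distribution ----------------------------------------------

    def length_pmf(self, l) -> np.ndarray | float:
        """P(L = l) on the support l in {1, 2, ...} (codons)."""
        scalar = np.ndim(l) == 0
        l = np.atleast_1d(np.asarray(l))
        if (l < 1).any():
            raise ValueError("ORF length must be >= 1 codon")
        per_frame = (1 - self.rho[:, None]) ** (l[None, :] - 1) * self.rho[:, None]
        p = self.weights @ per_frame
        return float(p[0]) if scalar else p

    def tail_probability(self, l, frame: int | None = None) -> np.ndarray | float:
        """P(L >= l); restricted to one frame's geometric tail if given."""
        scalar = np.ndim(l) == 0
        l = np.atleast_1d(np.asarray(l))
        if (l < 1).any():
            raise ValueError("ORF length must be >= 1 codon")
        if frame is not None:
            rho = self.rho[self.frame_index(frame)]
            out = (1 - rho) ** (l.astype(float) - 1)
        else:
            out = self.weights @ (1 - self.rho[:, None]) ** (l[None, :] - 1)
        return float(out[0]) if scalar else out

    def average_orf_length(self) -> float:
        """E[L] in codons; independent of the genome length."""
        return float((self.weights / self.rho).sum())

    def quantile(self, q: float) -> int:
        """Smallest l with P(L <= l) >= q."""
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        lo, hi = 1, 2
        while 1 - self.tail_probability(hi + 1) < q:
            hi *= 2
        while lo < hi:
            mid = (lo + hi) // 2
            if 1 - self.tail_probability(mid + 1) >= q:
                hi = mid
            else:
                lo = mid + 1
        return lo

    # ---- survival ----------------------------------------------------------

    def survival(
        self,
        l: int,
        trials: float | None = None,
        frame: int | None = None,
        continuous: bool = False,
    ) -> SurvivalResult:
        """Probability of observing >= 1 ORF of length >= l among N trials.

        ``trials`` defaults to the model's total expected ORF count (or the
        frame's N_i when ``frame`` is given), rounded to the nearest integer
        unless ``continuous`` allows fractional-trial exponentiation.
        """
        if trials is None:
            trials = (
                self.total_count if frame is None else float(self.counts[self.frame_index(frame)])
            )
        if trials < 0:
            raise ValueError("trials must be >= 0")
        if not continuous:
            trials = round(trials)
        tail = self.tail_probability(l, frame=frame)
        s = 1.0 - (1.0 - tail) ** trials
        return SurvivalResult(length=int(l), tail=float(tail), survival=float(s), trials=trials)

    def survival_limit(self, pvalue: float, frame: int | None = None) -> int:
        """Smallest length l with survival(l) <= pvalue (bisection)."""
        if not 0 < pvalue < 1:
            raise ValueError("pvalue must be in (0, 1)")
        lo, hi = 1, 2
        while self.survival(hi, frame=frame).survival > pvalue:
            hi *= 2
            if hi > 10**9:
                raise RuntimeError("survival limit search diverged")
        while lo < hi:
            mid = (lo + hi) // 2
            if self.survival(mid, frame=frame).survival <= pvalue:
                hi = mid
            else:
                lo = mid + 1
        return lo

    # ---- expected counts ---------------------------------------------------

    def expected_histogram(self, l_max: int, frame: int | None = None) -> np.ndarray:
        """Expected ORF count per length 1..l_max (index 0 = length 1)."""
        if l_max < 1:
            raise ValueError("l_max must be >= 1")
        ls = np.arange(1, l_max + 1)
        if frame is None:
            return self.total_count * self.length_pmf(ls)
        i = self.frame_index(frame)
        return float(self.counts[i]) * (1 - self.rho[i]) ** (ls - 1) * self.rho[i]

    def predicted_gene_count(self, min_len: int | None = None) -> float:
        """Expected number of annotated ORFs: N_{+1}, optionally constrained
        to genes of at least ``min_len`` codons via the frame +1 tail."""
        n1 = float(self.counts[self.frame_index(1)])
        if min_len is None or min_len <= 1:
            return n1
        rho1 = self.rho[self.frame_index(1)]
        return n1 * (1 - rho1) ** (min_len - 1 + self.tail_exponent_offset)

    # ---- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genome_bp": self.genome_bp,
            "code": {
                "start_set": sorted(self.code.start_set),
                "stop_set": sorted(self.code.stop_set),
            },
            "tail_exponent_offset": self.tail_exponent_offset,
            "frames": {
                f"{f:+d}": {
                    "rho": float(self.rho[i]),
                    "tau": float(self.tau[i]),
                    "alpha": float(self.alpha[i]),
                    "N": float(self.counts[i]),
                    "w": float(self.weights[i]),
                }
                for i, f in enumerate(self.frames)
            },
            "N_total": self.total_count,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureModel":
        d = json.loads(Path(path).read_text())
        frames = tuple(int(k) for k in d["frames"])
        return cls(
            rho=np.array([d["frames"][f"{f:+d}"]["rho"] for f in frames]),
            tau=np.array([d["frames"][f"{f:+d}"]["tau"] for f in frames]),
            genome_bp=int(d["genome_bp"]),
            frames=frames,
            code=GeneticCodeConfig(
                stop_set=frozenset(d["code"]["stop_set"]),
                start_set=frozenset(d["code"]["start_set"]),
            ),
            tail_exponent_offset=int(d.get("tail_exponent_offset", 0)),
        )


def build_model(
    fp: FrameProbabilities, genome_bp: int, tail_exponent_offset: int = 0
) -> MixtureModel:
    """Construct the geometric mixture from frame probabilities."""
    return MixtureModel.from_frame_probabilities(
        fp, genome_bp, tail_exponent_offset=tail_exponent_offset
    )


__all__ = ["MixtureModel", "SurvivalResult", "build_model"]
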