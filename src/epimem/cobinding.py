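"""Transcription-factor co-binding statistics and PWM positional density.

Covers two questions about a pioneer-factor relationship (RUNX3 pre-binding
EOMES sites): what fraction of EOMES-bound regions carries a RUNX3 peak in
either cell state, and in the naive state specifically; and where the best
motif match sits relative to the peak center, summarised as a positional
histogram over a ±250 bp window.

The scanner is deliberately minimal: log2-odds scoring of a probability
PWM against a background, best single hit per sequence over both strands.
No enrichment statistics, no thresholding by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import IntervalSet, overlap_fraction

__all__ = [
    "Pwm",
    "MotifHit",
    "PositionalDensity",
    "read_jaspar_pfm",
    "cobinding_fractions",
    "pwm_best_hit",
    "positional_density",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pwm:
    """Position probability matrix with background and a log-odds view.

    ``matrix`` is L x 4 (A, C, G, T) of base probabilities; a pseudo
    probability is added and rows renormalised before taking log2-odds, so
    zero entries (common in JASPAR matrices) stay finite. N in a sequence
    scores 0 (background).
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudo: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 log2-odds table; column 4 (N) contributes 0."""
        m = self.matrix + self.pseudo
        m = m / m.sum(axis=1, keepdims=True)
        lo = np.log2(m / self.background)
        return np.column_stack([lo, np.zeros(len(self))])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudo=self.pseudo,
        )


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based match start on the forward sequence
    strand: str
    score: float  # log2-odds (bits)


@dataclass
class PositionalDensity:
    bin_edges: np.ndarray  # bp relative to sequence center
    counts: np.ndarray
    window: int


def read_jaspar_pfm(path: str | Path) -> Pwm:
    """Read a plain-text JASPAR PFM (counts) into a probability PWM."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array(
        [motif.counts[b] for b in "ACGT"], dtype=float
    ).T  # L x 4
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("PFM column with zero total count")
    return Pwm(motif_id=motif.matrix_id or motif.name or Path(path).stem,
               matrix=counts / totals)


def cobinding_fractions(
    eomes_regions: IntervalSet,
    runx3_naive: IntervalSet,
    runx3_tim: IntervalSet,
) -> Tuple[float, float]:
    """(fraction of EOMES regions with RUNX3 in either state,
    fraction pre-bound by RUNX3 in the naive state)."""
    if len(eomes_regions) == 0:
        raise ValueError("EOMES region set is empty")
    union = IntervalSet(
        label="runx3_any",
        intervals=list(runx3_naive.intervals) + list(runx3_tim.intervals),
    )
    frac_any = overlap_fraction(eomes_regions, union) if len(union) else 0.0
    frac_naive = (
        overlap_fraction(eomes_regions, runx3_naive) if len(runx3_naive) else 0.0
    )
    return frac_any, frac_naive


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN base {exc.args[0]!r}") from exc


def _scan_scores(code: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset of one strand."""
    L = lom.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    return lom[np.arange(L), windows].sum(axis=1)


def pwm_best_hit(sequence: str, pwm: Pwm, seq_id: str = "") -> MotifHit:
    """Best log2-odds match over all offsets and both strands.

    The reverse strand is scanned via the reverse-complement matrix so hit
    offsets always refer to the forward sequence. Ties prefer the smaller
    offset and the + strand.
    """
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif length {L}"
        )
    code = _encode(sequence)
    fwd = _scan_scores(code, pwm.log_odds)
    rev = _scan_scores(code, pwm.reverse_complement().log_odds)
    best_f = int(fwd.argmax())  # argmax returns the first (smallest) offset
    best_r = int(rev.argmax())
    if rev[best_r] > fwd[best_f]:
        return MotifHit(seq_id, best_r, "-", float(rev[best_r]))
    return MotifHit(seq_id, best_f, "+", float(fwd[best_f]))


def positional_density(
    sequences: Dict[str, str] | Sequence[Tuple[str, str]],
    pwm: Pwm,
    window: int = 250,
    bin_width: int = 10,
    min_score: float | None = None,
) -> PositionalDensity:
    """Histogram of best-hit centers relative to sequence centers.

    Each sequence contributes its single best hit; the hit position is the
    center of the matched L-mer, measured from the sequence midpoint. Hits
    outside ±window, or below ``min_score`` when given, are discarded.
    """
    items = sequences.items() if isinstance(sequences, dict) else sequences
    edges = np.arange(-window, window + bin_width, bin_width, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    L = len(pwm)
    for seq_id, seq in items:
        hit = pwm_best_hit(seq, pwm, seq_id=seq_id)
        if min_score is not None and hit.score < min_score:
            continue
        rel = (hit.offset + L / 2.0) - len(seq) / 2.0
        idx = np.searchsorted(edges, rel, side="right") - 1
        if 0 <= idx < len(counts):
            counts[idx] += 1
    return PositionalDensity(bin_edges=edges, counts=counts, window=window)


def density_table(d: PositionalDensity) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_start": d.bin_edges[:-1].astype(int),
            "bin_end": d.bin_edges[1:].astype(int),
            "count": d.counts,
        }
    )
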