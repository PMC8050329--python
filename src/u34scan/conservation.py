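"""Shannon-entropy conservation of motif windows across ortholog alignments.

Each ortholog family is a multiple alignment (typically 10 mammalian
species) with a designated human reference row. A 5-residue window on the
reference is mapped to its alignment columns; each column's Shannon entropy
H = −Σ p·log2 p (in bits, gaps excluded from the distribution) measures
variability, and the window's conservation score is the mean of
(log2 20 − H) over its columns, so larger means more conserved. Motif
windows are compared against random 5-contiguous reference windows with a
two-sided Mann–Whitney test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .stats import TestResult, mann_whitney, t_test_two_sided

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
MAX_COLUMN_BITS = math.log2(20)


@dataclass
class OrthologAlignment:
    """Equal-length aligned ortholog sequences with a reference row."""

    family_id: str
    species: list[str]
    rows: list[str]
    ref_index: int = 0
    ref_to_col: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.family_id}: empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError(f"{self.family_id}: ragged alignment rows")
        if not 0 <= self.ref_index < len(self.rows):
            raise ValueError(f"{self.family_id}: ref_index {self.ref_index} out of range")
        # bijection from ungapped reference positions to alignment columns
        self.ref_to_col = [
            col for col, ch in enumerate(self.rows[self.ref_index]) if ch not in GAP_CHARS
        ]

    @property
    def ref_length(self) -> int:
        return len(self.ref_to_col)

    def column(self, col: int) -> list[str]:
        return [row[col] for row in self.rows]


def read_alignment(
    path: str | Path,
    fmt: Literal["clustal", "fasta"] = "fasta",
    family_id: str | None = None,
    ref_index: int = 0,
) -> OrthologAlignment:
    """Read a Clustal or aligned-FASTA ortholog alignment."""
    path = Path(path)
    aln = AlignIO.read(str(path), fmt)
    return OrthologAlignment(
        family_id=family_id or path.stem,
        species=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
        ref_index=ref_index,
    )


def column_entropy(column: Sequence[str]) -> float:
    """Shannon entropy of one alignment column in bits.

    Gap characters are excluded and the residue distribution renormalized; a
    column of only gaps is undefined and raises.
    """
    residues = [c for c in column if c not in GAP_CHARS]
    if not column:
        raise ValueError("empty column")
    if not residues:
        raise ValueError("column is entirely gaps; entropy undefined")
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class WindowConservation:
    start: int  # reference coordinates
    entropies: tuple[float, ...]
    score: float  # mean of (log2 20 − H) over retained columns
    n_dropped_columns: int = 0


def window_scores(
    aln: OrthologAlignment,
    windows: Sequence[int],
    width: int = 5,
    max_gap_fraction: float = 0.5,
) -> list[WindowConservation]:
    """Conservation of reference-coordinate windows of the given width.

    Each window start maps through the reference→column map; columns where
    more than ``max_gap_fraction`` of rows are gaps are dropped from the
    window mean with a logged flag.
    """
    results = []
    n_rows = len(aln.rows)
    for start in windows:
        if not 0 <= start <= aln.ref_length - width:
            raise ValueError(
                f"{aln.family_id}: window {start} out of range for reference length {aln.ref_length}"
            )
        entropies: list[float] = []
        retained: list[float] = []
        dropped = 0
        for offset in range(width):
            col = aln.column(aln.ref_to_col[start + offset])
            gap_frac = sum(c in GAP_CHARS for c in col) / n_rows
            h = column_entropy(col)
            entropies.append(h)
            if gap_frac > max_gap_fraction:
                dropped += 1
                logger.warning(
                    "%s: window %d column %d is >%d%% gaps; dropped from mean",
                    aln.family_id, start, offset, int(100 * max_gap_fraction),
                )
                continue
            retained.append(MAX_COLUMN_BITS - h)
        score = float(np.mean(retained)) if retained else float("nan")
        results.append(
            WindowConservation(
                start=start, entropies=tuple(entropies), score=score, n_dropped_columns=dropped
            )
        )
    return results


def motif_vs_random(
    alignments: Sequence[OrthologAlignment],
    motif_windows: Mapping[str, Sequence[int]],
    n_random: int = 100,
    seed: int = 0,
    width: int = 5,
    test: Literal["mw", "t"] = "mw",
) -> TestResult:
    """Compare conservation of motif windows against random windows.

    Motif-window scores are pooled across families; for each family,
    ``n_random`` random 5-contiguous reference windows (excluding the motif
    windows themselves) are sampled with replacement and pooled into the
    background sample. The two samples are compared with a two-sided
    Mann–Whitney test (t-test optional).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    motif_scores: list[float] = []
    random_scores: list[float] = []
    for aln in alignments:
        fam_windows = list(motif_windows.get(aln.family_id, ()))
        if fam_windows:
            motif_scores.extend(w.score for w in window_scores(aln, fam_windows, width=width))
        candidates = np.setdiff1d(
            np.arange(aln.ref_length - width + 1), np.asarray(fam_windows, dtype=int)
        )
        if candidates.size == 0:
            continue
        picks = rng.choice(candidates, size=n_random, replace=True)
        random_scores.extend(w.score for w in window_scores(aln, picks.tolist(), width=width))
    if not motif_scores:
        raise ValueError("no motif windows supplied")
    if test == "t":
        return t_test_two_sided(motif_scores, random_scores)
    return mann_whitney(motif_scores, random_scores)
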