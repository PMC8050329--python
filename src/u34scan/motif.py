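"""Consensus-motif scanning and the combined direct-target predictor.

The consensus motif [EKR]-[EKR]-[EKR]-R-[DEKR] is the charged/ampholytic
pentamer shared by the hydrophilic pentasequences over-represented in
proteins that aggregate and are degraded upon loss of U34-tRNA modification
(e.g. ERRRK in KIF4A). A gene is predicted to be a *direct* target of the
pathway when it is both U34-codon-enriched and carries the motif; enrichment
without the motif marks candidate indirect targets (the NUF2-like case).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: the default consensus: one set of allowed residues per motif position
CONSENSUS_MOTIF: tuple[frozenset[str], ...] = (
    frozenset("EKR"),
    frozenset("EKR"),
    frozenset("EKR"),
    frozenset("R"),
    frozenset("DEKR"),
)

MotifPattern = Sequence[frozenset[str]]


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    start: int  # 0-based
    pentamer: str


@dataclass(frozen=True)
class TargetPrediction:
    gene_id: str
    codon_enriched: bool
    has_motif: bool

    @property
    def predicted_direct_target(self) -> bool:
        return self.codon_enriched and self.has_motif

    @property
    def codon_only(self) -> bool:
        """Enriched but motif-free: a candidate indirect target."""
        return self.codon_enriched and not self.has_motif


def parse_pattern(spec: str) -> tuple[frozenset[str], ...]:
    """Parse a comma-separated pattern like ``"EKR,EKR,EKR,R,DEKR"``."""
    sets = tuple(frozenset(tok.strip()) for tok in spec.split(","))
    if any(not s for s in sets):
        raise ValueError(f"empty position in motif pattern {spec!r}")
    return sets


def scan_motif(
    seq: str,
    pattern: MotifPattern = CONSENSUS_MOTIF,
    protein_id: str = "",
) -> list[MotifHit]:
    """All (overlapping) windows of the sequence matching the pattern,
    in position order."""
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if all(aa in allowed for aa, allowed in zip(window, pattern)):
            hits.append(MotifHit(protein_id=protein_id, start=i, pentamer=window))
    return hits


def has_motif(seq: str, pattern: MotifPattern = CONSENSUS_MOTIF) -> bool:
    k = len(pattern)
    return any(
        all(aa in allowed for aa, allowed in zip(seq[i : i + k], pattern))
        for i in range(len(seq) - k + 1)
    )


def proteome_motif_prevalence(
    proteins: Sequence[str], pattern: MotifPattern = CONSENSUS_MOTIF
) -> float:
    """Fraction of proteins carrying at least one motif hit."""
    if not proteins:
        raise ValueError("empty protein list")
    return sum(has_motif(p, pattern) for p in proteins) / len(proteins)


def edit_motif(
    seq: str,
    mode: Literal["delete_at", "insert_at", "substitute"],
    position: int,
    payload: str = "",
) -> str:
    """Sequence edits mirroring the motif perturbation constructs: deletion
    of a 5-residue motif (KIF4A-Del), insertion of a whole motif instance
    (KIF5B-Penta), or a single-residue substitution that creates one
    (KIF5B-A516R)."""
    if mode == "delete_at":
        if not 0 <= position <= len(seq) - 5:
            raise ValueError(f"cannot delete 5 residues at {position} in length-{len(seq)} sequence")
        return seq[:position] + seq[position + 5 :]
    if mode == "insert_at":
        if not 0 <= position <= len(seq):
            raise ValueError(f"insert position {position} out of range")
        if not payload:
            raise ValueError("insert_at requires a payload")
        return seq[:position] + payload + seq[position:]
    if mode == "substitute":
        if not 0 <= position < len(seq):
            raise ValueError(f"substitute position {position} out of range")
        if len(payload) != 1:
            raise ValueError("substitute requires a single-residue payload")
        return seq[:position] + payload + seq[position + 1 :]
    raise ValueError(f"unknown edit mode {mode!r}")


def consensus_from_pentamers(
    pentamers: Sequence[str], threshold: float = 0.90
) -> tuple[frozenset[str], ...]:
    """Build a per-position residue-set consensus from equal-length ungapped
    pentasequences.

    At each position, residues are added in decreasing frequency until they
    jointly cover at least ``threshold`` of the sequences. Length-5 ungapped
    input needs no alignment step.
    """
    if not pentamers:
        raise ValueError("no pentasequences supplied")
    k = len(pentamers[0])
    if any(len(p) != k for p in pentamers):
        raise ValueError("pentasequences must be equal length")
    pattern = []
    n = len(pentamers)
    for pos in range(k):
        counts = Counter(p[pos] for p in pentamers)
        allowed: set[str] = set()
        covered = 0
        for aa, c in counts.most_common():
            allowed.add(aa)
            covered += c
            if covered / n >= threshold:
                break
        pattern.append(frozenset(allowed))
    return tuple(pattern)


def predict_u34_targets(
    gscu_results: pd.DataFrame,
    motif_flags: Mapping[str, bool],
    rule: Literal["all_q", "any_q", "cum"] = "all_q",
) -> list[TargetPrediction]:
    """Combine codon enrichment with motif presence into the direct-target
    prediction.

    ``rule`` selects the enrichment definition: ``all_q`` (all three per-codon
    q-values < threshold, the strong-enrichment set), ``any_q``, or ``cum``
    (cumulative U34 frequency above the 0.088 threshold). Genes present in
    only one input are dropped with a warning.
    """
    col = {"all_q": "enriched_all", "any_q": "enriched_any", "cum": "above_cum"}[rule]
    predictions = []
    for row in gscu_results.itertuples():
        gid = row.gene_id
        if gid not in motif_flags:
            logger.warning("gene %s has no motif flag; dropped from prediction", gid)
            continue
        predictions.append(
            TargetPrediction(
                gene_id=gid,
                codon_enriched=bool(getattr(row, col)),
                has_motif=bool(motif_flags[gid]),
            )
        )
    return predictions
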