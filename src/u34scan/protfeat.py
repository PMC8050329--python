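"""Protein-level features: residue classes, pentasequence patterns, and the
composite aggregation-propensity score.

The central quantity is the Zyggregator-style composite

    log(k) = α0 + αhydr + αss + αch + αpat

where α0 encodes pH/temperature (0 here), αhydr is the sum of per-residue
hydropathy values over the protein, αss the number of annotated secondary-
structure segments (helices + strands), αch the net charge (+1 per K/R, −1
per D/E), and αpat the number of pentasequences — overlapping 5-residue
windows made entirely of hydrophilic or entirely of hydrophobic residues.

Hydrophilic pentasequences are also a feature in their own right: they are
the signal that separates proteins downregulated upon loss of U34-tRNA
modification from equally codon-enriched proteins that stay unchanged.

The default residue-class scheme is built on the Kyte–Doolittle hydropathy
scale, with hydrophilic = {R,K,N,D,E,Q,H} (hydropathy <= −3.2) and
hydrophobic = {A,M,C,F,L,V,I} (>= +1.8); it is swappable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from .gscu import positional_bin_profile
from .seqio import AMINO_ACIDS, CodingSequence

logger = logging.getLogger(__name__)

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

WindowClass = Literal["hydrophilic", "hydrophobic"]


@dataclass(frozen=True)
class ResidueClassScheme:
    """Hydropathy values, charges and hydrophilic/hydrophobic residue sets."""

    hydropathy: Mapping[str, float]
    charge: Mapping[str, int]
    hydrophilic_set: frozenset[str]
    hydrophobic_set: frozenset[str]

    def __post_init__(self) -> None:
        for table, name in ((self.hydropathy, "hydropathy"), (self.charge, "charge")):
            missing = AMINO_ACIDS - set(table)
            if missing:
                raise ValueError(f"{name} table missing residues {sorted(missing)}")
        if self.hydrophilic_set & self.hydrophobic_set:
            raise ValueError("hydrophilic and hydrophobic sets must be disjoint")
        # motif residues must be hydrophilic so every consensus-motif hit is
        # also a hydrophilic pentasequence
        if not {"K", "R", "D", "E"} <= self.hydrophilic_set:
            raise ValueError("K, R, D and E must be in the hydrophilic set")

    def classify(self, residue: str) -> str:
        if residue in self.hydrophilic_set:
            return "philic"
        if residue in self.hydrophobic_set:
            return "phobic"
        return "neutral"


def default_scheme() -> ResidueClassScheme:
    charge = {aa: 0 for aa in AMINO_ACIDS}
    charge.update({"K": 1, "R": 1, "D": -1, "E": -1})
    return ResidueClassScheme(
        hydropathy=dict(KYTE_DOOLITTLE),
        charge=charge,
        hydrophilic_set=frozenset("RKNDEQH"),
        hydrophobic_set=frozenset("AMCFLVI"),
    )


@dataclass(frozen=True)
class PentaWindow:
    start: int  # 0-based
    window_class: WindowClass
    pentamer: str


@dataclass
class PentaPatternSet:
    """All same-class 5-residue windows of one protein."""

    protein_id: str
    windows: list[PentaWindow] = field(default_factory=list)

    @property
    def n_hydrophilic(self) -> int:
        return sum(w.window_class == "hydrophilic" for w in self.windows)

    @property
    def n_hydrophobic(self) -> int:
        return sum(w.window_class == "hydrophobic" for w in self.windows)


@dataclass(frozen=True)
class SecondaryStructureAnnotation:
    protein_id: str
    n_helix: int = 0
    n_strand: int = 0

    def __post_init__(self) -> None:
        if self.n_helix < 0 or self.n_strand < 0:
            raise ValueError("secondary-structure counts must be non-negative")


@dataclass(frozen=True)
class AggregationScore:
    """The α-components of the composite aggregation score and their sum."""

    alpha0: float
    alpha_hydr: float
    alpha_ss: float
    alpha_ch: float
    alpha_pat: float

    @property
    def log_k(self) -> float:
        return self.alpha0 + self.alpha_hydr + self.alpha_ss + self.alpha_ch + self.alpha_pat


def _check_residues(seq: str, scheme: ResidueClassScheme) -> None:
    for i, aa in enumerate(seq):
        if aa not in scheme.hydropathy:
            raise ValueError(f"non-standard residue {aa!r} at position {i}")


def classify_residues(seq: str, scheme: ResidueClassScheme | None = None) -> list[str]:
    """Per-residue class labels: 'philic', 'phobic' or 'neutral'."""
    scheme = scheme or default_scheme()
    _check_residues(seq, scheme)
    return [scheme.classify(aa) for aa in seq]


def penta_patterns(
    seq: str,
    scheme: ResidueClassScheme | None = None,
    protein_id: str = "",
    mode: Literal["sliding", "runs"] = "sliding",
) -> PentaPatternSet:
    """Count hydrophilic and hydrophobic pentasequences.

    ``sliding`` (default): every position i whose residues i..i+4 all belong
    to one class contributes one window, so a maximal same-class run of
    length L >= 5 yields L−4 windows. ``runs`` counts each maximal run >= 5
    once (sensitivity-analysis mode).
    """
    scheme = scheme or default_scheme()
    _check_residues(seq, scheme)
    result = PentaPatternSet(protein_id=protein_id)
    classes = [scheme.classify(aa) for aa in seq]
    for cls, label in (("philic", "hydrophilic"), ("phobic", "hydrophobic")):
        i = 0
        n = len(seq)
        while i < n:
            if classes[i] != cls:
                i += 1
                continue
            run_start = i
            while i < n and classes[i] == cls:
                i += 1
            run_len = i - run_start
            if run_len < 5:
                continue
            if mode == "runs":
                result.windows.append(
                    PentaWindow(run_start, label, seq[run_start : run_start + 5])
                )
            else:
                for s in range(run_start, run_start + run_len - 4):
                    result.windows.append(PentaWindow(s, label, seq[s : s + 5]))
    result.windows.sort(key=lambda w: w.start)
    return result


def net_charge(seq: str, scheme: ResidueClassScheme | None = None) -> int:
    """Sum of residue charges: K/R count +1, D/E count −1, others 0."""
    scheme = scheme or default_scheme()
    _check_residues(seq, scheme)
    return sum(scheme.charge[aa] for aa in seq)


def hydropathy_sum(seq: str, scheme: ResidueClassScheme | None = None) -> float:
    """Sum of per-residue hydropathy values under the configured scale."""
    scheme = scheme or default_scheme()
    _check_residues(seq, scheme)
    return float(sum(scheme.hydropathy[aa] for aa in seq))


def aggregation_score(
    seq: str,
    ss: SecondaryStructureAnnotation | None = None,
    scheme: ResidueClassScheme | None = None,
    alpha0: float = 0.0,
) -> AggregationScore:
    """Composite aggregation propensity log(k) = α0 + αhydr + αss + αch + αpat.

    αss is the number of annotated secondary-structure segments; with no
    annotation it is 0.
    """
    scheme = scheme or default_scheme()
    pat = penta_patterns(seq, scheme)
    n_ss = (ss.n_helix + ss.n_strand) if ss is not None else 0
    return AggregationScore(
        alpha0=alpha0,
        alpha_hydr=hydropathy_sum(seq, scheme),
        alpha_ss=float(n_ss),
        alpha_ch=float(net_charge(seq, scheme)),
        alpha_pat=float(pat.n_hydrophilic + pat.n_hydrophobic),
    )


def build_feature_table(
    cds_list: Sequence[CodingSequence],
    proteins: Mapping[str, str],
    gscu_results: pd.DataFrame,
    expression: pd.DataFrame,
    ss: Mapping[str, SecondaryStructureAnnotation] | None = None,
    scheme: ResidueClassScheme | None = None,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Assemble the per-gene feature table used to contrast downregulated and
    unchanged proteins.

    One row per gene, joined on gene id across the CDS set, the protein set,
    the GSCU results and the expression table: mRNA length, expression
    log2 fold-change and label, the U34 codon frequencies, a positional-bin
    summary (mean bin position of U34 codons), amino-acid composition, the
    secondary-structure counts, net charge, hydropathy sum, pentasequence
    counts and log(k). Genes missing from any input are dropped with a
    warning.
    """
    scheme = scheme or default_scheme()
    ss = ss or {}
    expr = expression.set_index("gene_id")
    gscu = gscu_results.set_index("gene_id")
    rows = []
    for cds in cds_list:
        gid = cds.gene_id
        if gid not in proteins or gid not in expr.index or gid not in gscu.index:
            logger.warning("gene %s missing from protein/expression/GSCU inputs; dropped", gid)
            continue
        seq = proteins[gid]
        pat = penta_patterns(seq, scheme, protein_id=gid)
        ann = ss.get(gid)
        score = aggregation_score(seq, ann, scheme)
        profile = positional_bin_profile(cds, n_bins=n_bins)
        total = profile.sum()
        mean_bin = float((profile * range(n_bins)).sum() / total) if total > 0 else float("nan")
        row: dict[str, object] = {
            "gene_id": gid,
            "mrna_length_nt": len(cds.nt),
            "log2fc": expr.at[gid, "log2fc"],
            "label": expr.at[gid, "label"],
            "f_aaa": gscu.at[gid, "f_aaa"],
            "f_gaa": gscu.at[gid, "f_gaa"],
            "f_caa": gscu.at[gid, "f_caa"],
            "f_cum": gscu.at[gid, "f_cum"],
            "u34_mean_bin": mean_bin,
            "n_helix": ann.n_helix if ann else 0,
            "n_strand": ann.n_strand if ann else 0,
            "net_charge": score.alpha_ch,
            "hydropathy_sum": score.alpha_hydr,
            "n_penta_philic": pat.n_hydrophilic,
            "n_penta_phobic": pat.n_hydrophobic,
            "log_k": score.log_k,
        }
        for aa in sorted(AMINO_ACIDS):
            row[f"comp_{aa}"] = seq.count(aa) / len(seq) if seq else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
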