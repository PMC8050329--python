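"""Synthetic inputs with the statistical structure the pipeline assumes.

Generators for every input the analysis consumes: an orfeome with a planted
subset of U34-codon-enriched genes, a proteome with planted consensus-motif
instances, expression tables in which downregulation depends on the
(enriched AND motif) conjunction, ortholog families with designated
slow-evolving 5-residue windows, and secondary-structure annotation tables.

Every generator is a pure function of its configuration and seed, and each
returns a truth table sufficient to score downstream classifiers exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import OrthologAlignment
from .motif import CONSENSUS_MOTIF, MotifPattern, has_motif
from .seqio import AMINO_ACIDS, STOP_CODONS, CodingSequence, SequenceRecord

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

_AA_LIST = tuple(sorted(AMINO_ACIDS))

#: human codon usage, occurrences per thousand codons (Kazusa-style table);
#: the non-uniform alternative to the uniform default baseline
HUMAN_CODON_USAGE_PER_1000: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "CAT": 10.9, "CAC": 15.1,
    "CAA": 12.3, "CAG": 34.2, "AAT": 17.0, "AAC": 19.1,
    "AAA": 24.4, "AAG": 31.9, "GAT": 21.8, "GAC": 25.1,
    "GAA": 29.0, "GAG": 39.6, "TGT": 10.6, "TGC": 12.6,
    "TGG": 13.2, "CGT": 4.5, "CGC": 10.4, "CGA": 6.2,
    "CGG": 11.4, "AGT": 12.1, "AGC": 19.5, "AGA": 12.2,
    "AGG": 12.0, "GGT": 10.8, "GGC": 22.2, "GGA": 16.5,
    "GGG": 16.5,
}


def uniform_codon_usage() -> dict[str, float]:
    return {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}


def human_codon_usage() -> dict[str, float]:
    total = sum(HUMAN_CODON_USAGE_PER_1000.values())
    return {c: HUMAN_CODON_USAGE_PER_1000[c] / total for c in SENSE_CODONS}


@dataclass
class OrfeomeConfig:
    """Conditions for the synthetic orfeome.

    A fraction of genes is planted with elevated AAA/GAA/CAA usage: their
    three U34-codon probabilities are multiplied and the distribution
    renormalized.
    """

    n_genes: int = 1000
    length_mean: float = 500.0  # codons, excluding start and stop
    length_sd: float = 100.0
    min_length: int = 30
    baseline_codon_usage: dict[str, float] = field(default_factory=uniform_codon_usage)
    enriched_fraction: float = 0.05
    enrichment_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array([self.baseline_codon_usage.get(c, 0.0) for c in SENSE_CODONS])
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("baseline codon usage must be a distribution over the 61 sense codons")
        if self.enrichment_multiplier < 1:
            raise ValueError("enrichment multiplier must be >= 1")
        if not 0 <= self.enriched_fraction <= 1:
            raise ValueError("enriched fraction must lie in [0, 1]")


def _boost_u34(probs: np.ndarray, multiplier: float) -> np.ndarray:
    boosted = probs.copy()
    for codon in ("AAA", "GAA", "CAA"):
        boosted[SENSE_CODONS.index(codon)] *= multiplier
    return boosted / boosted.sum()


def generate_orfeome(cfg: OrfeomeConfig) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Synthetic orfeome and its planted-enrichment truth table.

    Each gene is ATG + i.i.d. sense codons from its usage distribution + one
    stop codon; planted genes draw from the multiplied-renormalized usage.
    """
    rng = np.random.default_rng(cfg.seed)
    base = np.array([cfg.baseline_codon_usage[c] for c in SENSE_CODONS])
    boosted = _boost_u34(base, cfg.enrichment_multiplier)
    n_planted = int(round(cfg.n_genes * cfg.enriched_fraction))
    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[rng.choice(cfg.n_genes, size=n_planted, replace=False)] = True
    lengths = np.maximum(
        cfg.min_length,
        np.round(rng.normal(cfg.length_mean, cfg.length_sd, size=cfg.n_genes)).astype(int),
    )
    codon_arr = np.array(SENSE_CODONS)
    stop_arr = np.array(sorted(STOP_CODONS))
    genes: list[CodingSequence] = []
    truth_rows = []
    for i in range(cfg.n_genes):
        gid = f"g{i:05d}"
        usage = boosted if planted[i] else base
        body = codon_arr[rng.choice(len(SENSE_CODONS), size=lengths[i], p=usage)]
        stop = stop_arr[rng.integers(0, len(stop_arr))]
        genes.append(CodingSequence(gene_id=gid, nt="ATG" + "".join(body) + stop))
        truth_rows.append({"gene_id": gid, "planted_enriched": bool(planted[i]), "n_codons": int(lengths[i])})
    return genes, pd.DataFrame(truth_rows)


def _pattern_instance(pattern: MotifPattern, rng: np.random.Generator) -> str:
    return "".join(sorted(allowed)[rng.integers(0, len(allowed))] for allowed in pattern)


def generate_proteome(
    n: int,
    length_mean: float = 400.0,
    length_sd: float = 80.0,
    min_length: int = 20,
    motif_prevalence: float = 0.5,
    pattern: MotifPattern = CONSENSUS_MOTIF,
    seed: int = 0,
    ids: list[str] | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Synthetic proteome with planted consensus-motif instances.

    Background residues are i.i.d. uniform over the 20 standard amino acids;
    a ``motif_prevalence`` fraction of proteins has one random instance of
    the consensus pattern written over a uniform random position. The truth
    table records both the planted flag and the scan-verified ``has_motif``
    (planting guarantees a hit; background windows may also match by chance).
    """
    rng = np.random.default_rng(seed)
    if ids is not None and len(ids) != n:
        raise ValueError("ids, when given, must have length n")
    lengths = np.maximum(
        min_length, np.round(rng.normal(length_mean, length_sd, size=n)).astype(int)
    )
    planted = rng.random(n) < motif_prevalence
    records: list[SequenceRecord] = []
    truth_rows = []
    aa_arr = np.array(_AA_LIST)
    width = len(pattern)
    for i in range(n):
        pid = ids[i] if ids is not None else f"p{i:05d}"
        seq = "".join(aa_arr[rng.integers(0, 20, size=lengths[i])])
        if planted[i]:
            pos = int(rng.integers(0, lengths[i] - width + 1))
            seq = seq[:pos] + _pattern_instance(pattern, rng) + seq[pos + width :]
        records.append(SequenceRecord(id=pid, seq=seq))
        truth_rows.append(
            {
                "protein_id": pid,
                "motif_planted": bool(planted[i]),
                "has_motif": has_motif(seq, pattern),
            }
        )
    return records, pd.DataFrame(truth_rows)


@dataclass
class EffectModelConfig:
    """Generative link from (codon enrichment AND motif) to protein fate.

    Encodes the pathway's central claim as a sampling rule: a gene whose mRNA
    is U34-codon-enriched and whose protein carries the hydrophilic motif is
    downregulated with high probability upon loss of U34 enzymes; all other
    genes with low background probability. Aggregate membership requires both
    downregulation and the motif.
    """

    p_down_given_enriched_and_motif: float = 0.9
    p_down_otherwise: float = 0.05
    log2fc_down_mean: float = -1.5
    log2fc_down_sd: float = 0.4
    log2fc_null_mean: float = 0.0
    log2fc_null_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_down_given_enriched_and_motif, self.p_down_otherwise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def generate_expression_table(
    orfeome_truth: pd.DataFrame,
    proteome_truth: pd.DataFrame,
    cfg: EffectModelConfig,
) -> pd.DataFrame:
    """Expression/proteomics table (gene_id, log2fc, label, aggregate_member)
    drawn from the effect model over the two truth tables.

    The proteome truth is joined on gene id (protein ids must equal gene
    ids); unmatched genes are dropped.
    """
    rng = np.random.default_rng(cfg.seed)
    prot = proteome_truth.rename(columns={"protein_id": "gene_id"})
    merged = orfeome_truth.merge(prot, on="gene_id", how="inner")
    p_down = np.where(
        merged["planted_enriched"] & merged["has_motif"],
        cfg.p_down_given_enriched_and_motif,
        cfg.p_down_otherwise,
    )
    down = rng.random(len(merged)) < p_down
    log2fc = np.where(
        down,
        rng.normal(cfg.log2fc_down_mean, cfg.log2fc_down_sd, size=len(merged)),
        rng.normal(cfg.log2fc_null_mean, cfg.log2fc_null_sd, size=len(merged)),
    )
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "log2fc": log2fc,
            "label": np.where(down, "down", "unchanged"),
            "aggregate_member": down & merged["has_motif"].to_numpy(),
        }
    )


def generate_ortholog_families(
    n_families: int = 50,
    n_species: int = 10,
    length_mean: float = 120.0,
    length_sd: float = 20.0,
    min_length: int = 30,
    background_sub_rate: float = 0.5,
    conserved_window_rate: float = 0.05,
    window_width: int = 5,
    seed: int = 0,
) -> tuple[list[OrthologAlignment], pd.DataFrame]:
    """Ortholog families with one designated slow-evolving window each.

    An ancestral sequence (uniform over 20 residues) seeds each family; row 0
    is the unmutated reference and every other species row substitutes each
    site independently (to one of the 19 other residues) at the background
    rate, except inside the designated window, which substitutes at the
    conserved rate. No indels, so the alignment is exact and gap-free.
    """
    for rate in (background_sub_rate, conserved_window_rate):
        if not 0 <= rate <= 1:
            raise ValueError("substitution rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    families: list[OrthologAlignment] = []
    truth_rows = []
    for i in range(n_families):
        fam_id = f"fam{i:04d}"
        length = max(min_length, int(round(rng.normal(length_mean, length_sd))))
        ancestral = rng.integers(0, 20, size=length)
        win_start = int(rng.integers(0, length - window_width + 1))
        rates = np.full(length, background_sub_rate)
        rates[win_start : win_start + window_width] = conserved_window_rate
        rows = ["".join(_AA_LIST[a] for a in ancestral)]
        for _ in range(n_species - 1):
            subst = rng.random(length) < rates
            derived = ancestral.copy()
            # substitute to a uniformly chosen *different* residue
            shift = rng.integers(1, 20, size=length)
            derived[subst] = (ancestral[subst] + shift[subst]) % 20
            rows.append("".join(_AA_LIST[a] for a in derived))
        species = ["human"] + [f"sp{j}" for j in range(1, n_species)]
        families.append(
            OrthologAlignment(family_id=fam_id, species=species, rows=rows, ref_index=0)
        )
        truth_rows.append({"family_id": fam_id, "window_start": win_start, "length": length})
    return families, pd.DataFrame(truth_rows)


def generate_ss_annotations(protein_ids: list[str], seed: int = 0) -> pd.DataFrame:
    """Secondary-structure annotation table: Poisson helix/strand segment
    counts per protein (means 10 and 6)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "protein_id": protein_ids,
            "n_helix": rng.poisson(10, size=len(protein_ids)),
            "n_strand": rng.poisson(6, size=len(protein_ids)),
        }
    )
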