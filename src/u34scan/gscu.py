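"""Gene-specific codon usage (GSCU) statistics for the U34 codons.

The mcm5s2 modification of wobble uridine (U34) in tRNA anticodons is required
for efficient decoding of the AA-ending codons AAA (Lys), GAA (Glu) and CAA
(Gln). This module quantifies, per gene, how biased the coding sequence is
toward those three codons:

* per-gene codon frequencies and their cumulative U34 frequency ``f_cum``;
* a resampling enrichment p-value — the probability that a randomly picked
  gene from the orfeome has a strictly higher frequency of the codon than the
  gene of interest — in both an exact (rank-proportion) form and the
  Monte-Carlo form with a configurable number of draws;
* FDR q-values (Storey or Benjamini–Hochberg), computed per codon across
  genes, and the resulting enrichment classification (q < 0.05, and the
  cumulative-frequency rule f_cum > 0.088);
* synonymous recoding of the U34 codons to their G-ending counterparts
  (AAA→AAG, CAA→CAG, GAA→GAG), which preserves the protein exactly;
* positional 100-bin U34-codon distribution profiles along the CDS.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .seqio import STOP_CODONS, CodingSequence

U34_CODONS: tuple[str, str, str] = ("AAA", "GAA", "CAA")
RECODE_MAP = {"AAA": "AAG", "CAA": "CAG", "GAA": "GAG"}

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_CUM_THRESHOLD = 0.088
DEFAULT_N_DRAWS = 10_000

QMethod = Literal["storey", "bh"]


@dataclass
class CodonUsageProfile:
    """Exact codon counts and frequencies for one gene."""

    gene_id: str
    counts: dict[str, int]
    total: int

    @property
    def freq(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / self.total for c, n in self.counts.items()}

    def codon_freq(self, codon: str) -> float:
        if self.total == 0:
            return 0.0
        return self.counts.get(codon, 0) / self.total

    @property
    def f_cum(self) -> float:
        """Cumulative frequency of the three U34 codons."""
        return sum(self.codon_freq(c) for c in U34_CODONS)


@dataclass
class GscuResult:
    """Per-gene U34 enrichment statistics and classification flags."""

    gene_id: str
    f_aaa: float
    f_gaa: float
    f_caa: float
    f_cum: float
    p_aaa: float = np.nan
    p_gaa: float = np.nan
    p_caa: float = np.nan
    q_aaa: float = np.nan
    q_gaa: float = np.nan
    q_caa: float = np.nan
    enriched_any: bool = False
    enriched_all: bool = False
    above_cum: bool = False


def count_codons(cds: CodingSequence, include_stop: bool = False) -> CodonUsageProfile:
    """Count every codon in the CDS, start to stop.

    With ``include_stop=False`` (default) a terminal stop codon is excluded
    from both counts and the frequency denominator.
    """
    codons = cds.codons
    if not include_stop and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    return CodonUsageProfile(gene_id=cds.gene_id, counts=counts, total=len(codons))


def gscu_pvalue_exact(f: float, orfeome_freqs: Sequence[float]) -> float:
    """Exact resampling p-value: the proportion of other genes whose codon
    frequency is strictly greater than ``f``.

    This is the large-draw limit of the Monte-Carlo estimator and serves as
    its oracle. Ties are not "higher" and do not count.
    """
    arr = np.asarray(orfeome_freqs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty comparison set")
    return float(np.count_nonzero(arr > f) / arr.size)


def gscu_pvalue_mc(
    f: float,
    orfeome_freqs: Sequence[float],
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo resampling p-value with ``n_draws`` uniform draws (with
    replacement) from the other genes' frequencies.

    Uses the add-one estimator p = (1 + #greater) / (n_draws + 1) so the
    p-value is never exactly 0 and downstream q-values stay well-defined.
    """
    arr = np.asarray(orfeome_freqs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty comparison set")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=n_draws)
    greater = int(np.count_nonzero(arr[idx] > f))
    return (1 + greater) / (n_draws + 1)


def _substream(seed: int, gene_id: str, codon: str) -> np.random.Generator:
    # keyed by gene id + codon so per-gene draws are independent of
    # gene processing order
    return np.random.default_rng(
        [seed, zlib.crc32(gene_id.encode()), zlib.crc32(codon.encode())]
    )


def storey_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Storey q-values with the smoothed λ-grid π0 estimate.

    π0(λ) = #{p > λ} / (m (1−λ)) is evaluated on λ = 0.05, 0.10, …, 0.90 and
    smoothed with a cubic fit; π0 is the smoothed value at the largest λ,
    clipped to (0, 1]. q-values are the step-down cumulative minima of
    π0·m·p/rank.
    """
    p = np.asarray(pvalues, dtype=float)
    _check_p(p)
    m = p.size
    if m == 0:
        return p.copy()
    lam = np.arange(0.05, 0.95, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if m < 30 or np.all(p <= lam[0]):
        pi0 = 1.0  # too few p-values for a stable smoother; conservative
    else:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam[-1]))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p)[::-1]  # largest p first
    q = np.empty(m)
    ranks = np.arange(m, 0, -1)  # rank of the largest p is m
    q_ordered = pi0 * m * p[order] / ranks
    q_ordered = np.minimum.accumulate(np.minimum(q_ordered, 1.0))
    q[order] = q_ordered
    return q


def _check_p(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")


def qvalues(pvalues: Sequence[float], method: QMethod = "storey") -> np.ndarray:
    """FDR q-values, same length and order as the input p-values."""
    p = np.asarray(pvalues, dtype=float)
    _check_p(p)
    if p.size == 0:
        return p.copy()
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return storey_qvalues(p)
    raise ValueError(f"unknown q-value method {method!r}")


def recode_u34(cds: CodingSequence) -> CodingSequence:
    """Recode every U34 codon to its synonymous G-ending codon.

    AAA→AAG, CAA→CAG, GAA→GAG at codon boundaries; all other codons are
    untouched, so the translated protein is identical and the recoded gene's
    U34-codon content is zero. Idempotent.
    """
    recoded = "".join(RECODE_MAP.get(c, c) for c in cds.codons)
    return CodingSequence(gene_id=cds.gene_id, nt=recoded)


def positional_bin_profile(
    cds: CodingSequence,
    n_bins: int = 100,
    include_stop: bool = False,
    codons: Sequence[str] = U34_CODONS,
) -> np.ndarray:
    """Positional distribution of U34 codons along the CDS in ``n_bins`` bins.

    Codon index i (of L counted codons) falls in bin floor(i·n_bins/L); each
    bin's value is the fraction of its codons that are U34 codons (0 for an
    empty bin).
    """
    cods = cds.codons
    if not include_stop and cods[-1] in STOP_CODONS:
        cods = cods[:-1]
    L = len(cods)
    profile = np.zeros(n_bins)
    if L == 0:
        return profile
    target = frozenset(codons)
    idx = np.arange(L) * n_bins // L
    hits = np.fromiter((c in target for c in cods), dtype=float, count=L)
    denom = np.bincount(idx, minlength=n_bins).astype(float)
    num = np.bincount(idx, weights=hits, minlength=n_bins)
    np.divide(num, denom, out=profile, where=denom > 0)
    return profile


def compute_frequencies(cds_list: Sequence[CodingSequence], include_stop: bool = False) -> pd.DataFrame:
    """Per-gene U34 codon frequencies for an orfeome."""
    rows = []
    for cds in cds_list:
        prof = count_codons(cds, include_stop=include_stop)
        rows.append(
            {
                "gene_id": cds.gene_id,
                "f_aaa": prof.codon_freq("AAA"),
                "f_gaa": prof.codon_freq("GAA"),
                "f_caa": prof.codon_freq("CAA"),
                "f_cum": prof.f_cum,
                "n_codons": prof.total,
            }
        )
    return pd.DataFrame(rows)


def run_gscu(
    cds_list: Sequence[CodingSequence],
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    q_method: QMethod = "storey",
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    cum_threshold: float = DEFAULT_CUM_THRESHOLD,
    include_stop: bool = False,
    exact: bool = False,
) -> pd.DataFrame:
    """Full GSCU analysis of an orfeome.

    For each gene and each of AAA/GAA/CAA, computes the resampling enrichment
    p-value against all other genes (Monte-Carlo with ``n_draws`` draws, or
    the exact rank proportion with ``exact=True``), converts p-values to
    q-values per codon across genes, and sets the enrichment flags.

    Each (gene, codon) pair uses its own RNG substream keyed on the gene id,
    so results do not depend on input order.
    """
    if len(cds_list) < 2:
        raise ValueError("orfeome must contain at least 2 genes")
    df = compute_frequencies(cds_list, include_stop=include_stop)
    freq_cols = {"AAA": "f_aaa", "GAA": "f_gaa", "CAA": "f_caa"}
    n = len(df)
    for codon, col in freq_cols.items():
        freqs = df[col].to_numpy()
        pvals = np.empty(n)
        for i in range(n):
            # sorted so the draw sequence is independent of input order
            others = np.sort(np.delete(freqs, i))
            if exact:
                pvals[i] = gscu_pvalue_exact(freqs[i], others)
            else:
                rng = _substream(seed, df["gene_id"].iat[i], codon)
                pvals[i] = gscu_pvalue_mc(freqs[i], others, n_draws=n_draws, seed=rng)
        df[f"p_{codon.lower()}"] = pvals
        df[f"q_{codon.lower()}"] = qvalues(pvals, method=q_method)
    return classify_enrichment(df, q_threshold=q_threshold, cum_threshold=cum_threshold)


def classify_enrichment(
    results: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    cum_threshold: float = DEFAULT_CUM_THRESHOLD,
) -> pd.DataFrame:
    """Set the enrichment flags from populated q-values and f_cum.

    ``enriched_any``: the smallest of the three per-codon q-values is below
    the threshold; ``enriched_all``: all three are; ``above_cum``: f_cum is
    strictly greater than the cumulative-frequency threshold.
    """
    df = results.copy()
    qcols = ["q_aaa", "q_gaa", "q_caa"]
    df["enriched_any"] = df[qcols].min(axis=1) < q_threshold
    df["enriched_all"] = df[qcols].max(axis=1) < q_threshold
    df["above_cum"] = df["f_cum"] > cum_threshold
    return df
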