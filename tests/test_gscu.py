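import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from u34scan.gscu import (
    classify_enrichment,
    count_codons,
    gscu_pvalue_exact,
    gscu_pvalue_mc,
    positional_bin_profile,
    qvalues,
    recode_u34,
    run_gscu,
)
from u34scan.seqio import CodingSequence, translate_cds

codon_lists = st.lists(
    st.sampled_from(["ATG", "AAA", "GAA", "CAA", "AAG", "TGG", "CTG", "CCC", "GGG"]),
    min_size=2,
    max_size=200,
)


def make_cds(codons, gene_id="g", stop=True):
    return CodingSequence(gene_id, "".join(codons) + ("TAA" if stop else ""))


class TestCountCodons:
    def test_direct_count_excluding_stop(self):
        prof = count_codons(CodingSequence("g", "ATGAAAGAACAATAA"))
        assert prof.counts == {"ATG": 1, "AAA": 1, "GAA": 1, "CAA": 1}
        assert prof.total == 4
        assert prof.f_cum == pytest.approx(0.75)

    def test_include_stop_flag(self):
        prof = count_codons(CodingSequence("g", "ATGAAAGAACAATAA"), include_stop=True)
        assert prof.total == 5
        assert prof.counts["TAA"] == 1

    def test_no_u34_codons(self):
        prof = count_codons(CodingSequence("g", "ATGATG"))
        assert prof.counts == {"ATG": 2}
        assert prof.f_cum == 0.0


class TestExactPvalue:
    def test_maximum_element(self):
        assert gscu_pvalue_exact(0.5, [0.2, 0.1]) == 0.0

    def test_minimum_element(self):
        assert gscu_pvalue_exact(0.1, [0.5, 0.2]) == 1.0

    def test_ties_are_not_higher(self):
        assert gscu_pvalue_exact(0.5, [0.5, 0.5]) == 0.0

    def test_empty_comparison_set_raises(self):
        with pytest.raises(ValueError):
            gscu_pvalue_exact(0.5, [])

    @given(st.integers(3, 50), st.integers(0, 2**31 - 1))
    def test_rank_law_on_distinct_frequencies(self, n, seed):
        """With all-distinct frequencies the exact p-values are exactly the
        rank proportions {0, 1/(n-1), ..., (n-1)/(n-1)}."""
        rng = np.random.default_rng(seed)
        freqs = rng.permutation(np.linspace(0.01, 0.5, n))
        ps = sorted(gscu_pvalue_exact(f, np.delete(freqs, i)) for i, f in enumerate(freqs))
        expected = sorted(k / (n - 1) for k in range(n))
        assert ps == pytest.approx(expected)


class TestMonteCarloPvalue:
    def test_pseudocount_floor(self):
        assert gscu_pvalue_mc(0.9, [0.1, 0.2], n_draws=100, seed=0) == pytest.approx(1 / 101)

    def test_single_draw_always_greater(self):
        assert gscu_pvalue_mc(0.1, [0.9], n_draws=1, seed=0) == 1.0

    def test_reproducible_under_seed(self):
        args = (0.3, np.linspace(0, 1, 20), 500)
        assert gscu_pvalue_mc(*args, seed=42) == gscu_pvalue_mc(*args, seed=42)

    @given(st.integers(0, 2**31 - 1))
    def test_binomial_consistency_with_exact(self, seed):
        """MC estimate lies within the 3-sigma binomial bound of the exact
        proportion (plus the pseudocount shift)."""
        rng = np.random.default_rng(seed)
        others = rng.random(30)
        f = rng.random()
        n_draws = 2000
        p_exact = gscu_pvalue_exact(f, others)
        p_mc = gscu_pvalue_mc(f, others, n_draws=n_draws, seed=rng)
        bound = 3 * np.sqrt(p_exact * (1 - p_exact) / n_draws) + 1 / n_draws
        assert abs(p_mc - p_exact) <= bound


class TestQvalues:
    def test_bh_hand_executed(self):
        # step-up: q3 = 0.03, q2 = min(0.02*3/2, q3) = 0.03, q1 = min(0.01*3, q2) = 0.03
        assert qvalues([0.01, 0.02, 0.03], method="bh") == pytest.approx([0.03, 0.03, 0.03])

    @pytest.mark.parametrize("method", ["bh", "storey"])
    def test_all_ones(self, method):
        assert qvalues([1.0, 1.0], method=method) == pytest.approx([1.0, 1.0])

    @pytest.mark.parametrize("method", ["bh", "storey"])
    def test_bounds_and_rank_monotonicity(self, method):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        q = qvalues(p, method=method)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in the p ranking

    def test_storey_no_larger_than_bh_on_mixed_panel(self):
        # Storey's pi0 <= 1 can only shrink BH q-values
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.random(500), rng.random(100) * 1e-4])
        assert np.all(qvalues(p, "storey") <= qvalues(p, "bh") + 1e-12)

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestClassifyEnrichment:
    def make_df(self, q3, f_cum=0.05):
        return pd.DataFrame(
            [{"gene_id": "g", "f_cum": f_cum, "q_aaa": q3[0], "q_gaa": q3[1], "q_caa": q3[2]}]
        )

    def test_any_but_not_all(self):
        row = classify_enrichment(self.make_df((0.01, 0.2, 0.2))).iloc[0]
        assert row.enriched_any and not row.enriched_all

    def test_all(self):
        row = classify_enrichment(self.make_df((0.01, 0.01, 0.01))).iloc[0]
        assert row.enriched_all and row.enriched_any

    def test_cumulative_threshold_is_strict(self):
        assert not classify_enrichment(self.make_df((1, 1, 1), f_cum=0.088)).iloc[0].above_cum
        assert classify_enrichment(self.make_df((1, 1, 1), f_cum=0.0881)).iloc[0].above_cum


class TestRecode:
    def test_table_substitution(self):
        assert recode_u34(CodingSequence("g", "AAACAAGAA")).nt == "AAGCAGGAG"

    def test_translation_preserved_example(self):
        cds = CodingSequence("g", "ATGAAATAA")
        rec = recode_u34(cds)
        assert rec.nt == "ATGAAGTAA"
        assert translate_cds(cds) == translate_cds(rec) == "MK"

    @given(codon_lists)
    def test_laws_zero_u34_idempotent_translation_invariant(self, codons):
        cds = make_cds([c for c in codons if c not in ("TAA", "TAG", "TGA")] or ["ATG"])
        rec = recode_u34(cds)
        assert count_codons(rec).f_cum == 0.0
        assert recode_u34(rec) == rec
        assert translate_cds(cds) == translate_cds(rec)


class TestBinProfile:
    def test_all_u34(self):
        cds = make_cds(["AAA"] * 100, stop=True)
        assert positional_bin_profile(cds) == pytest.approx(np.ones(100))

    def test_front_loaded(self):
        cds = make_cds(["AAA"] * 100 + ["TGG"] * 100)
        profile = positional_bin_profile(cds)
        assert profile[:50] == pytest.approx(np.ones(50))
        assert profile[50:] == pytest.approx(np.zeros(50))

    def test_zero_u34_gives_zero_profile(self):
        assert positional_bin_profile(make_cds(["TGG"] * 30)) == pytest.approx(np.zeros(100))

    @given(codon_lists, st.integers(1, 120))
    def test_mass_conservation(self, codons, n_bins):
        """Sum over bins of bin value x codons-in-bin = total U34 codons."""
        cds = make_cds([c for c in codons if c not in ("TAA", "TAG", "TGA")] or ["ATG"])
        counted = len(cds.codons) - 1  # terminal stop excluded
        profile = positional_bin_profile(cds, n_bins=n_bins)
        idx = np.arange(counted) * n_bins // counted
        per_bin = np.bincount(idx, minlength=n_bins)
        total_u34 = sum(c in ("AAA", "GAA", "CAA") for c in cds.codons[:-1])
        assert (profile * per_bin).sum() == pytest.approx(total_u34)


class TestRunGscu:
    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        genes = [
            make_cds(list(rng.choice(["AAA", "TGG", "CTG", "GAA", "CAA"], size=60)), gene_id=f"g{i}")
            for i in range(12)
        ]
        a = run_gscu(genes, n_draws=200, seed=9, q_method="bh").sort_values("gene_id").reset_index(drop=True)
        b = run_gscu(genes[::-1], n_draws=200, seed=9, q_method="bh").sort_values("gene_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_exact_mode_matches_per_gene_oracle(self):
        rng = np.random.default_rng(11)
        genes = [
            make_cds(list(rng.choice(["AAA", "TGG", "CTG"], size=40)), gene_id=f"g{i}")
            for i in range(10)
        ]
        df = run_gscu(genes, exact=True, q_method="bh")
        freqs = df["f_aaa"].to_numpy()
        expected = [gscu_pvalue_exact(f, np.delete(freqs, i)) for i, f in enumerate(freqs)]
        assert df["p_aaa"].to_numpy() == pytest.approx(expected)

    def test_requires_two_genes(self):
        with pytest.raises(ValueError):
            run_gscu([make_cds(["ATG"])])
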