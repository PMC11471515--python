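"""Instrument selection, clumping, palindrome handling, harmonization, F-statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.instruments import (
    DROPPED_MISSING,
    FLIPPED,
    KEPT,
    LDLookup,
    compute_instrument_strength,
    drop_palindromes,
    exclude_listed_snps,
    greedy_clump,
    harmonize,
    select_by_pvalue,
)
from mrmediate.summstats import SummaryStatsError

from conftest import make_dataset


class TestPvalueSelection:
    @pytest.mark.parametrize("p,kept", [(1e-6, True), (2e-5, False), (1e-5, False)])
    def test_strict_threshold(self, p, kept):
        ds = make_dataset("x", [0.1], pvals=[p])
        out = select_by_pvalue(ds, 1e-5)
        assert (len(out) == 1) is kept

    def test_empty_result_allowed(self):
        ds = make_dataset("x", [0.1], pvals=[0.5])
        assert len(select_by_pvalue(ds, 1e-5)) == 0


class TestClumping:
    def _pair(self, dist_bp=5_000, pvals=(1e-8, 1e-6)):
        return make_dataset("x", [0.2, 0.15], pvals=list(pvals),
                            chroms=["1", "1"], positions=[1_000_000, 1_000_000 + dist_bp])

    def test_correlated_pair_keeps_best_p(self):
        ds = self._pair()
        ld = LDLookup({("rs1", "rs2"): 0.5})
        out = greedy_clump(ds, ld, r2_max=0.001, window_kb=10_000)
        assert list(out.df["variant_id"]) == ["rs1"]

    def test_uncorrelated_pair_kept(self):
        ds = self._pair()
        ld = LDLookup({("rs1", "rs2"): 0.0005})
        assert len(greedy_clump(ds, ld, r2_max=0.001, window_kb=10_000)) == 2

    def test_different_chromosomes_ignore_ld(self):
        ds = make_dataset("x", [0.2, 0.15], pvals=[1e-8, 1e-6],
                          chroms=["1", "2"], positions=[1_000_000, 1_000_000])
        assert len(greedy_clump(ds, LDLookup(), r2_max=0.001, window_kb=10_000)) == 2

    def test_missing_ld_policies(self):
        ds = self._pair()
        assert len(greedy_clump(ds, LDLookup(), missing_policy="correlated")) == 1
        assert len(greedy_clump(ds, LDLookup(), missing_policy="independent")) == 2

    def test_order_invariance(self):
        ds = self._pair()
        shuffled = make_dataset("x", [0.15, 0.2], pvals=[1e-6, 1e-8],
                                chroms=["1", "1"], positions=[1_005_000, 1_000_000])
        ld = LDLookup({("rs1", "rs2"): 0.5})
        a = greedy_clump(ds, ld)
        b = greedy_clump(shuffled, ld)
        # rs1 in `shuffled` is the worse SNP; the survivor is the p=1e-8 SNP both times
        assert a.df["pval"].tolist() == b.df["pval"].tolist() == [1e-8]

    def test_greedy_matches_enumeration_oracle(self, rng):
        """On small instances the greedy pick must be a valid, maximal subset
        and the p-ordered-lexicographic-first one among all such subsets."""
        for trial in range(25):
            k = int(rng.integers(3, 8))
            pvals = rng.uniform(1e-10, 1e-6, k)
            ds = make_dataset("x", rng.normal(0.2, 0.02, k), pvals=pvals,
                              chroms=["1"] * k,
                              positions=sorted(rng.integers(1, 5_000_000, k).tolist()))
            pairs = {}
            ids = ds.df["variant_id"].tolist()
            for a, b in itertools.combinations(ids, 2):
                pairs[(a, b)] = float(rng.choice([0.0, 0.9], p=[0.5, 0.5]))
            ld = LDLookup(pairs)
            got = set(greedy_clump(ds, ld, r2_max=0.001, window_kb=10_000).df["variant_id"])

            pos = dict(zip(ids, ds.df["pos"]))
            pv = dict(zip(ids, ds.df["pval"]))

            def conflict(a, b):
                return (abs(pos[a] - pos[b]) <= 10_000_000
                        and ld.get(a, b) is not None and ld.get(a, b) > 0.001)

            valid = [set(sub) for r in range(k + 1)
                     for sub in itertools.combinations(ids, r)
                     if not any(conflict(a, b) for a, b in itertools.combinations(sub, 2))]
            maximal = [s for s in valid
                       if not any(set([v]) | s in valid for v in set(ids) - s)]
            # greedy output is valid and maximal
            assert got in maximal
            # and is the one a p-ordered greedy sweep must produce
            expected = set()
            for v in sorted(ids, key=lambda i: pv[i]):
                if not any(conflict(v, u) for u in expected):
                    expected.add(v)
            assert got == expected


class TestPalindromes:
    @pytest.mark.parametrize("alleles,eaf,kept", [
        (("A", "T"), 0.50, False),
        (("A", "T"), 0.10, True),
        (("A", "G"), 0.50, True),
        (("C", "G"), 0.42, False),
        (("C", "G"), 0.41, True),
    ])
    def test_intermediate_band(self, alleles, eaf, kept):
        ds = make_dataset("x", [0.1], eafs=[eaf], alleles=[alleles])
        out = drop_palindromes(ds, (0.42, 0.58))
        assert (len(out) == 1) is kept


class TestExclusionList:
    def test_empty_list_is_identity(self):
        ds = make_dataset("x", [0.1, 0.2])
        assert len(exclude_listed_snps(ds, set())) == 2

    def test_full_list_annihilates(self):
        ds = make_dataset("x", [0.1, 0.2])
        assert len(exclude_listed_snps(ds, {"rs1", "rs2"})) == 0

    def test_partial_set_difference(self):
        ds = make_dataset("x", [0.1] * 22)
        out = exclude_listed_snps(ds, {"rs3", "rs7"})
        assert len(out) == 20


class TestHarmonize:
    def _exp(self):
        return make_dataset("E", [0.1], alleles=[("A", "G")])

    def test_identity_alleles_kept(self):
        out_ds = make_dataset("O", [0.05], alleles=[("A", "G")])
        h = harmonize(self._exp(), out_ds)
        assert h.capital_gamma[0] == pytest.approx(0.05)
        assert h.df["alignment_flag"].iloc[0] == KEPT

    def test_swapped_alleles_flip_sign(self):
        out_ds = make_dataset("O", [-0.05], alleles=[("G", "A")])
        h = harmonize(self._exp(), out_ds)
        assert h.capital_gamma[0] == pytest.approx(0.05)
        assert h.df["alignment_flag"].iloc[0] == FLIPPED

    def test_allele_mismatch_dropped(self):
        exp = make_dataset("E", [0.1, 0.1], alleles=[("A", "G"), ("A", "G")])
        out_ds = make_dataset("O", [0.05, 0.05], alleles=[("A", "C"), ("A", "G")])
        h = harmonize(exp, out_ds)
        assert len(h) == 1
        assert h.dropped is not None
        assert h.dropped["alignment_flag"].iloc[0] == DROPPED_MISSING

    def test_empty_intersection_raises_with_diagnostic(self):
        exp = self._exp()
        out_ds = make_dataset("O", [0.05])
        out_ds.df.loc[:, "variant_id"] = "rs999"
        with pytest.raises(SummaryStatsError, match="rs1"):
            harmonize(exp, out_ds)

    def test_idempotent(self):
        """Re-harmonizing data already on the exposure's alleles changes nothing."""
        exp = make_dataset("E", [0.1, -0.2], alleles=[("A", "G"), ("T", "C")])
        out_ds = make_dataset("O", [-0.05, 0.03], alleles=[("G", "A"), ("T", "C")])
        h1 = harmonize(exp, out_ds)
        aligned = make_dataset("O", list(h1.capital_gamma),
                               alleles=[("A", "G"), ("T", "C")])
        h2 = harmonize(exp, aligned)
        np.testing.assert_allclose(h2.capital_gamma, h1.capital_gamma)
        assert (h2.df["alignment_flag"] == KEPT).all()

    def test_mediator_effects_carried(self):
        exp = self._exp()
        out_ds = make_dataset("O", [0.05], alleles=[("A", "G")])
        med = make_dataset("M", [-0.02], alleles=[("G", "A")])
        h = harmonize(exp, out_ds, med)
        assert h.delta[0] == pytest.approx(0.02)


class TestInstrumentStrength:
    def test_null_effect_gives_zero(self):
        d = compute_instrument_strength(make_dataset("x", [0.0]))[0]
        assert d.r2 == 0.0 and d.f_stat == 0.0

    def test_hand_computed_values(self):
        ds = make_dataset("x", [0.1], eafs=[0.3], ns=[8299.0])
        d = compute_instrument_strength(ds, phenotype_sd=1.0)[0]
        assert d.maf == pytest.approx(0.3)
        assert d.r2 == pytest.approx(0.0042)
        assert d.f_stat == pytest.approx(34.99, abs=0.01)

    def test_weak_flag_at_floor(self):
        ds = make_dataset("x", [0.02, 0.2], eafs=[0.3, 0.3], ns=[8299.0, 8299.0])
        diags = compute_instrument_strength(ds, min_f=10.0)
        assert diags[0].weak and not diags[1].weak

    def test_r2_at_least_one_rejected(self):
        ds = make_dataset("x", [3.0], eafs=[0.5])
        with pytest.raises(SummaryStatsError, match="R"):
            compute_instrument_strength(ds)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(beta=st.floats(0.01, 0.5), bump=st.floats(0.001, 0.2),
           n=st.floats(1000, 100_000), extra_n=st.floats(1, 50_000),
           maf=st.floats(0.01, 0.5))
    def test_f_monotone_in_effect_and_sample_size(self, beta, bump, n, extra_n, maf):
        def f(b, nn):
            ds = make_dataset("x", [b], eafs=[maf], ns=[nn])
            return compute_instrument_strength(ds)[0].f_stat

        assert f(beta + bump, n) > f(beta, n)
        assert f(beta, n + extra_n) > f(beta, n)
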