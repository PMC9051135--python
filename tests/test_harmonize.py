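import numpy as np
import pandas as pd
import pytest

from lifemr.harmonization import (HarmonizationError, assert_independent, clump,
                              clump_multi, harmonize, merge_exposures,
                              select_instruments)
from lifemr.simulate import SimulationConfig, simulate_summary_pair

from conftest import make_summary_table
from oracles import clump_oracle

EMPTY_LD = pd.DataFrame(columns=["variant_a", "variant_b", "r2"])


def _pair(exp_kw, out_kw):
    exposure = make_summary_table(["rs1"], **exp_kw)
    outcome = make_summary_table(["rs1"], **out_kw)
    return exposure, outcome


class TestHarmonize:
    def test_already_aligned(self):
        exp, out = _pair(dict(beta=0.10, se=0.01, ea="A", oa="G"),
                         dict(beta=0.05, se=0.02, ea="A", oa="G"))
        ds = harmonize(exp, out)
        assert ds.beta_y[0] == pytest.approx(0.05)
        assert ds.flags.loc[ds.flags.variant_id == "rs1", "status"].item() == "aligned"

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp, out = _pair(dict(beta=0.10, se=0.01, ea="A", oa="G"),
                         dict(beta=0.05, se=0.02, ea="G", oa="A", eaf=0.30))
        ds = harmonize(exp, out)
        assert ds.beta_y[0] == pytest.approx(-0.05)
        assert ds.flags["status"].item() == "flipped"

    def test_strand_flip_nonpalindromic_resolved(self):
        # outcome reported on the other strand: A/G vs T/C
        exp, out = _pair(dict(beta=0.10, se=0.01, ea="A", oa="G"),
                         dict(beta=0.05, se=0.02, ea="T", oa="C"))
        ds = harmonize(exp, out)
        assert ds.beta_y[0] == pytest.approx(0.05)

    def test_allele_mismatch_dropped(self):
        exp = make_summary_table(["rs1", "rs2"], 0.1, 0.01, ea="A", oa="G")
        out = make_summary_table(["rs1", "rs2"], 0.05, 0.02,
                                 ea=["A", "A"], oa=["G", "C"])
        ds = harmonize(exp, out)
        assert ds.variants == ["rs1"]
        assert (ds.flags.set_index("variant_id").loc["rs2", "status"]
                == "dropped:allele_mismatch")

    def test_missing_variants_dropped_with_reason(self):
        exp = make_summary_table(["rs1", "rs2"], 0.1, 0.01)
        out = make_summary_table(["rs1", "rs3"], 0.05, 0.02)
        ds = harmonize(exp, out)
        flags = ds.flags.set_index("variant_id")["status"]
        assert flags["rs2"] == "dropped:missing_in_outcome"
        assert flags["rs3"] == "dropped:missing_in_exposure"

    def test_empty_intersection_hard_error(self):
        exp = make_summary_table(["rs1"], 0.1, 0.01)
        out = make_summary_table(["rs2"], 0.05, 0.02)
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    @pytest.mark.parametrize("eaf", np.round(np.arange(0.01, 1.0, 0.01), 2))
    def test_palindromic_band_rule_over_eaf_grid(self, eaf):
        """Enumerate the drop rule: same EAF on both sides, band [0.42, 0.58]."""
        exp, out = _pair(dict(beta=0.10, se=0.01, ea="A", oa="T", eaf=eaf),
                         dict(beta=0.05, se=0.02, ea="A", oa="T", eaf=eaf))
        in_band = 0.42 <= eaf <= 0.58
        if in_band:
            with pytest.raises(HarmonizationError):
                harmonize(exp, out)
        else:
            ds = harmonize(exp, out)
            assert ds.flags["status"].item() == "palindromic_resolved"
            assert ds.beta_y[0] == pytest.approx(0.05)

    def test_palindromic_opposite_sides_sign_corrected(self):
        exp, out = _pair(dict(beta=0.10, se=0.01, ea="A", oa="T", eaf=0.20),
                         dict(beta=0.05, se=0.02, ea="A", oa="T", eaf=0.80))
        ds = harmonize(exp, out)
        assert ds.beta_y[0] == pytest.approx(-0.05)

    def test_palindromic_missing_eaf_dropped(self):
        exp, out = _pair(dict(beta=0.10, se=0.01, ea="A", oa="T", eaf=0.2),
                         dict(beta=0.05, se=0.02, ea="A", oa="T"))
        out.loc[0, "eaf"] = np.nan
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_idempotence_on_retained_variants(self):
        config = SimulationConfig(seed=31, frac_palindromic=0.3,
                                  frac_allele_swapped=0.4, n_instruments=(60, 60))
        pair = simulate_summary_pair(config)
        exp = pair.exposure_tables["childhood"]
        first = harmonize(exp, pair.outcome_table)
        aligned_outcome = exp.copy()
        keep = exp["variant_id"].isin(first.variants).to_numpy()
        aligned_outcome = aligned_outcome.loc[keep].reset_index(drop=True)
        order = {v: i for i, v in enumerate(first.variants)}
        aligned_outcome = aligned_outcome.sort_values(
            "variant_id", key=lambda s: s.map(order)).reset_index(drop=True)
        aligned_outcome["beta"] = first.beta_y
        aligned_outcome["se"] = first.se_y
        second = harmonize(exp, aligned_outcome)
        assert second.variants == first.variants
        np.testing.assert_allclose(second.beta_y, first.beta_y, atol=0)

    def test_corrupt_then_harmonize_roundtrip(self):
        """Simulator corruption is exactly inverted for non-palindromic variants."""
        config = SimulationConfig(seed=41, frac_allele_swapped=0.5,
                                  frac_palindromic=0.25, n_instruments=(80, 80))
        pair = simulate_summary_pair(config)
        uncorrupted = simulate_summary_pair(
            SimulationConfig(**{**config.__dict__, "frac_allele_swapped": 0.0}))
        ds = harmonize(pair.exposure_tables["childhood"], pair.outcome_table)
        truth = pair.truth.set_index("variant_id")
        ref = uncorrupted.outcome_table.set_index("variant_id")
        for vid, beta in zip(ds.variants, ds.beta_y):
            assert beta == pytest.approx(ref.loc[vid, "beta"], abs=1e-12), vid
        nonpal = set(truth.index[~truth["palindromic"]])
        assert nonpal <= set(ds.variants)


class TestClump:
    def test_independent_candidates_all_retained(self):
        cand = make_summary_table([f"rs{i}" for i in range(5)], 0.1, 0.01,
                                  pval=[0.01, 0.02, 0.03, 0.04, 0.05])
        assert len(clump(cand, EMPTY_LD, 0.001)) == 5

    def test_dominance_at_full_ld(self):
        cand = make_summary_table(["rsA", "rsB"], 0.1, 0.01, pval=[1e-10, 1e-8])
        ld = pd.DataFrame({"variant_a": ["rsA"], "variant_b": ["rsB"], "r2": [1.0]})
        assert clump(cand, ld, 0.001) == ["rsA"]

    def test_tie_break_lexicographic(self):
        cand = make_summary_table(["rsB", "rsA"], 0.1, 0.01, pval=[1e-8, 1e-8])
        ld = pd.DataFrame({"variant_a": ["rsA"], "variant_b": ["rsB"], "r2": [1.0]})
        assert clump(cand, ld, 0.001) == ["rsA"]

    def test_threshold_validation(self):
        cand = make_summary_table(["rs1"], 0.1, 0.01)
        with pytest.raises(ValueError):
            clump(cand, EMPTY_LD, 0.0)
        with pytest.raises(ValueError):
            clump(cand, EMPTY_LD, 1.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_on_dense_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        ids = [f"rs{i}" for i in range(n)]
        pvals = rng.uniform(1e-12, 1e-6, size=n)
        r2 = rng.uniform(0, 1, size=(n, n)) ** 4
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        rows = [(ids[a], ids[b], r2[a, b]) for a in range(n) for b in range(a + 1, n)]
        ld = pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"])
        cand = make_summary_table(ids, 0.1, 0.01, pval=pvals)
        threshold = float(rng.uniform(0.001, 0.5))
        result = clump(cand, ld, threshold)
        assert result == clump_oracle(ids, pvals, r2, threshold)
        assert_independent(result, ld, threshold)

    def test_clump_multi_disjoint_independent_union(self):
        a = make_summary_table(["rs1", "rs2"], 0.1, 0.01, pval=[1e-9, 1e-8])
        b = make_summary_table(["rs3"], 0.1, 0.01, pval=[1e-10])
        out = clump_multi({"a": a, "b": b}, EMPTY_LD, 0.001)
        assert set(out) == {"rs1", "rs2", "rs3"}

    def test_clump_multi_shared_variant_min_pval_rule(self):
        # rs_shared appears in both sets; rs_a is in LD with it.
        childhood = make_summary_table(["rs_shared", "rs_a"], 0.1, 0.01,
                                       pval=[1e-8, 1e-9])
        adult = make_summary_table(["rs_shared", "rs_b"], 0.1, 0.01,
                                   pval=[1e-12, 1e-7])
        ld = pd.DataFrame({"variant_a": ["rs_shared"], "variant_b": ["rs_a"],
                           "r2": [1.0]})
        out = clump_multi({"childhood": childhood, "adult": adult}, ld, 0.001)
        # shared variant carries min pval 1e-12, beating rs_a's 1e-9
        assert "rs_shared" in out and "rs_a" not in out
        assert set(out) == {"rs_shared", "rs_b"}

    def test_clump_multi_single_set_reduces_to_clump(self):
        cand = make_summary_table([f"rs{i}" for i in range(6)], 0.1, 0.01,
                                  pval=np.linspace(1e-9, 1e-7, 6))
        ld = pd.DataFrame({"variant_a": ["rs0"], "variant_b": ["rs3"], "r2": [0.9]})
        assert clump_multi({"only": cand}, ld, 0.5) == clump(cand, ld, 0.5)


class TestHelpers:
    def test_select_instruments_threshold(self):
        tab = make_summary_table(["rs1", "rs2"], 0.1, 0.01, pval=[1e-9, 1e-6])
        assert list(select_instruments(tab)["variant_id"]) == ["rs1"]

    def test_merge_exposures_builds_k_columns(self):
        config = SimulationConfig(seed=5, n_instruments=(20, 20))
        pair = simulate_summary_pair(config)
        per = {name: harmonize(tab, pair.outcome_table, exposure_label=name)
               for name, tab in pair.exposure_tables.items()}
        ds = merge_exposures(per, per["childhood"].variants)
        assert ds.beta_x.shape == (40, 2)
        assert ds.exposures == ["childhood", "adult"]
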