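"""Enrichment testing: Fisher exactness, BH behaviour, site tables, scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ptmd import enrichment as en
from ptmd import footprints as fp
from ptmd import synthetic as syn
from ptmd.footprints import FootprintSet
from ptmd.genetics import SENSE_CODONS

from oracles import fisher_two_sided_oracle


def _species(rows):
    return pd.DataFrame(rows, columns=fp.FOOTPRINT_COLUMNS)


class TestFisher:
    def test_symmetric_table_p_one(self):
        p = en.fisher_exact_pvalues([1], [1], 10, 10)
        assert p[0] == pytest.approx(1.0)

    def test_against_enumeration_oracle_example(self):
        p = en.fisher_exact_pvalues([5], [1], 100, 1000)
        assert p[0] == pytest.approx(fisher_two_sided_oracle(5, 1, 100, 1000), abs=1e-13)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        r1=st.integers(1, 40), r2=st.integers(1, 40),
        a_frac=st.floats(0, 1), b_frac=st.floats(0, 1),
    )
    def test_matches_scipy_fisher_exact(self, r1, r2, a_frac, b_frac):
        a, b = round(a_frac * r1), round(b_frac * r2)
        ours = en.fisher_exact_pvalues([a], [b], r1, r2)[0]
        _, theirs = stats.fisher_exact([[a, r1 - a], [b, r2 - b]])
        assert ours == pytest.approx(theirs, abs=1e-7)

    def test_large_totals_do_not_overflow(self):
        p = en.fisher_exact_pvalues([150], [40], 200_000, 200_000)
        assert 0.0 < p[0] < 1e-10


class TestFootprintEnrichment:
    def test_direction_contract_under_label_swap(self):
        ip = FootprintSet("ip", _species([("t", i, 29, c) for i, c in
                                          enumerate([50, 5, 30, 4, 80, 10])]))
        inp = FootprintSet("input", _species([("t", i, 29, c) for i, c in
                                              enumerate([5, 50, 4, 30, 10, 80])]))
        res = en.test_footprint_enrichment(ip, inp, alpha=0.05)
        res_swapped = en.test_footprint_enrichment(inp, ip, alpha=0.05)
        key = ["transcript_id", "five_prime_pos", "length"]
        enriched = set(map(tuple, res.loc[res["enriched"], key].to_numpy()))
        swapped = set(map(tuple, res_swapped.loc[res_swapped["enriched"], key].to_numpy()))
        assert enriched and swapped
        assert enriched & swapped == set()

    def test_bh_qvalues_monotone_in_p_rank(self, concentrated_sim):
        res = concentrated_sim["results"].sort_values("p_value")
        assert res["q_value"].is_monotonic_increasing
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()

    def test_all_p_one_means_nothing_enriched(self):
        ip = FootprintSet("ip", _species([("t", i, 29, 5) for i in range(4)]))
        res = en.test_footprint_enrichment(ip, ip, alpha=0.01)
        assert (res["p_value"] == 1.0).all()
        assert not res["enriched"].any()

    def test_zero_total_is_hard_error(self):
        ip = FootprintSet("ip", _species([("t", 0, 29, 5)]))
        empty = FootprintSet("input", pd.DataFrame(columns=fp.FOOTPRINT_COLUMNS))
        with pytest.raises(ValueError):
            en.test_footprint_enrichment(ip, empty)


class TestSiteEnrichment:
    def test_identical_distributions_give_unit_ratios(self, concentrated_sim):
        ia = concentrated_sim["input_annot"]
        table = en.site_codon_enrichment(ia, ia, "P", selection="ip")
        np.testing.assert_allclose(table["ratio"].dropna(), 1.0)

    def test_direct_formula_small_case(self):
        # 10 enriched footprints all P-site CGG; input 100 with 10 CGG
        tx_rec = fp.TranscriptRecord(
            "t", "A" * 20 + "ATG" + "AAA" + "CGG" + "GCA" * 26 + "TAA", 20, 20 + 87
        )
        tx = fp.Transcriptome([tx_rec])
        cgg_fp = ("t", 20 + 6 - 12, 29)
        gca_fp = ("t", 20 + 9 - 12, 29)
        ip = FootprintSet("ip", _species([(*cgg_fp, 10)]))
        inp = FootprintSet("input", _species([(*cgg_fp, 10), (*gca_fp, 90)]))
        results = pd.DataFrame(
            {"transcript_id": ["t"], "five_prime_pos": [cgg_fp[1]], "length": [29],
             "enriched": [True]}
        )
        table = en.site_codon_enrichment(
            fp.annotate_footprints(ip, tx), fp.annotate_footprints(inp, tx), "P",
            results=results, selection="enriched",
        ).set_index("codon")
        assert table.loc["CGG", "ratio"] == pytest.approx(10.0)

    def test_normalization_invariant(self, concentrated_sim):
        table = en.site_codon_enrichment(
            concentrated_sim["ip_annot"], concentrated_sim["input_annot"], "A",
            results=concentrated_sim["results"],
        )
        total = np.nansum(table["ratio"] * table["pct_input"])
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_injected_weight_ranking_recovered(self, concentrated_sim):
        table = en.site_codon_enrichment(
            concentrated_sim["ip_annot"], concentrated_sim["input_annot"], "P",
            results=concentrated_sim["results"],
        ).set_index("codon")
        r = table["ratio"]
        assert r["CGG"] > r["CGA"] > r["AGG"] > r.drop(["CGG", "CGA", "AGG"]).max()

    def test_rank_recovery_of_distinct_weights(self, broad_sim):
        table = en.site_codon_enrichment(
            broad_sim["ip_annot_distinct"], broad_sim["input_annot"], "P", selection="ip"
        )
        weights = broad_sim["distinct_weights"]
        rho = stats.spearmanr(
            table["ratio"], [weights[c] for c in table["codon"]]
        ).statistic
        assert rho >= 0.9

    def test_flat_weights_leave_ratios_near_one(self, broad_sim):
        table = en.site_codon_enrichment(
            broad_sim["ip_annot_flat"], broad_sim["input_annot"], "P", selection="ip"
        )
        log2r = np.log2(table["ratio"].dropna())
        assert (np.abs(log2r) > 0.5).mean() <= 0.05


class TestTripeptides:
    def test_single_tripeptide_dominates(self, concentrated_sim):
        tri, logo = en.tripeptide_enrichment(
            concentrated_sim["ip_annot"], concentrated_sim["input_annot"],
            results=concentrated_sim["results"],
        )
        top = tri.head(20)
        assert (top["p_site_aa"] == "R").mean() >= 0.9
        assert logo.loc["R", "P"] > logo.loc["R", ["E", "A"]].max()

    def test_amino_acid_ratio_is_input_weighted_codon_combination(self, concentrated_sim):
        # algebraic identity: aa ratio = sum(ratio_c * pct_input_c) / sum(pct_input_c)
        table = en.site_codon_enrichment(
            concentrated_sim["ip_annot"], concentrated_sim["input_annot"], "P",
            results=concentrated_sim["results"],
        )
        _, logo = en.tripeptide_enrichment(
            concentrated_sim["ip_annot"], concentrated_sim["input_annot"],
            results=concentrated_sim["results"],
        )
        arg = table[table["amino_acid"] == "R"].dropna(subset=["ratio"])
        expected = (arg["ratio"] * arg["pct_input"]).sum() / arg["pct_input"].sum()
        assert logo.loc["R", "P"] == pytest.approx(expected, rel=1e-6)


def _toy_tx():
    return fp.Transcriptome(
        [fp.TranscriptRecord("t1", "ATGCGGCGAAAATAA", 0, 15),
         fp.TranscriptRecord("t2", "ATGGCAGCATTTTAA", 0, 15)]
    )


class TestWeightedScore:
    @pytest.fixture()
    def toy_tx(self):
        return _toy_tx()

    def test_direct_formula(self, toy_tx):
        scores = en.weighted_codon_score(
            toy_tx, {"CGG": 4.0, "CGA": 3.0, "AGG": 2.0}
        ).set_index("transcript_id")["score"]
        assert scores["t1"] == pytest.approx((4 + 3) / 4)
        assert scores["t2"] == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100))
    def test_linearity_in_weights(self, c):
        tx = _toy_tx()
        base = en.weighted_codon_score(tx, {"CGG": 4.0, "CGA": 3.0})["score"]
        scaled = en.weighted_codon_score(tx, {"CGG": 4.0 * c, "CGA": 3.0 * c})["score"]
        np.testing.assert_allclose(scaled, base * c, rtol=1e-12)

    def test_weights_from_site_table(self, concentrated_sim):
        table = en.site_codon_enrichment(
            concentrated_sim["ip_annot"], concentrated_sim["input_annot"], "P",
            results=concentrated_sim["results"],
        )
        w = en.weights_from_site_table(table)
        assert set(w) == {"CGG", "CGA", "AGG"}
        assert all(v > 1 for v in w.values())


class TestMetricCorrelation:
    def test_self_correlation_is_one(self, broad_sim):
        table = en.site_codon_enrichment(
            broad_sim["ip_annot_distinct"], broad_sim["input_annot"], "A", selection="ip"
        )
        metric = {
            c: np.log2(r) for c, r in zip(table["codon"], table["ratio"]) if r and r > 0
        }
        r, p, n = en.correlate_codon_metric(table, metric)
        assert r == pytest.approx(1.0)
        assert n >= 60

    def test_independent_metric_within_permutation_null(self, broad_sim):
        table = en.site_codon_enrichment(
            broad_sim["ip_annot_distinct"], broad_sim["input_annot"], "A", selection="ip"
        )
        rng = np.random.default_rng(3)
        metric = {c: float(rng.normal()) for c in SENSE_CODONS}
        r, _, n = en.correlate_codon_metric(table, metric)
        log2r = np.log2(table.set_index("codon").loc[list(metric), "ratio"].dropna())
        null = []
        vals = np.array([metric[c] for c in log2r.index])
        for _ in range(10_000):
            null.append(np.corrcoef(log2r, rng.permutation(vals))[0, 1])
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo < r < hi

    def test_pearson_and_spearman_agree_in_sign(self, broad_sim):
        table = en.site_codon_enrichment(
            broad_sim["ip_annot_distinct"], broad_sim["input_annot"], "P", selection="ip"
        )
        metric = broad_sim["distinct_weights"]
        r_p, _, _ = en.correlate_codon_metric(table, metric, method="pearson")
        r_s, _, _ = en.correlate_codon_metric(table, metric, method="spearman")
        assert np.sign(r_p) == np.sign(r_s) == 1.0

    def test_too_few_codons_error(self):
        table = pd.DataFrame({"codon": ["AAA", "AAC"], "ratio": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 3"):
            en.correlate_codon_metric(table, {"AAA": 1.0, "AAC": 2.0})
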