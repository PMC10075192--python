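import numpy as np
import pandas as pd
import pytest
from scipy import stats

from estrkit import estr_mapping as em
from estrkit import str_prep
from estrkit import synthetic_data as sd
from estrkit.containers import IntervalSet
from estrkit.io_core import RunConfig


def nested_ols_lrt_oracle(y, codes):
    """Independent route: dummy-coded OLS via statsmodels, statistic from
    the two exact Gaussian log-likelihoods."""
    import statsmodels.api as sm

    dummies = pd.get_dummies(pd.Series(codes).astype("category"), drop_first=False)
    full = sm.OLS(y, dummies.to_numpy(dtype=float)).fit()
    red = sm.OLS(y, np.ones_like(y)).fit()
    stat = 2.0 * (full.llf - red.llf)
    df = dummies.shape[1] - 1
    return stat, df, stats.chi2.sf(stat, df)


class TestLrt:
    def test_constant_expression_gives_null_result(self):
        y = np.full(30, 2.5)
        codes = np.array([0.0, 1.0] * 15)
        stat, df, p, n, k = em.lrt_association(y, codes)
        assert (stat, p) == (0.0, 1.0) and df == 1

    def test_exact_fit_capped(self):
        codes = np.array([0.0] * 10 + [1.0] * 10)
        y = np.where(codes == 0, 1.0, 2.0)
        stat, df, p, n, k = em.lrt_association(y, codes)
        assert stat == em.LRT_STAT_CAP and 0 < p < 1e-300

    def test_matches_nested_ols_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = 40
            k = rng.integers(2, 5)
            codes = rng.integers(0, k, n).astype(float)
            if np.unique(codes).size < 2:
                continue
            y = rng.normal(size=n) + 0.5 * codes
            stat, df, p, *_ = em.lrt_association(y, codes)
            o_stat, o_df, o_p = nested_ols_lrt_oracle(y, codes)
            assert df == o_df
            assert stat == pytest.approx(o_stat, rel=1e-8)
            assert p == pytest.approx(o_p, rel=1e-6)

    def test_missing_strains_do_not_change_result(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        codes = rng.integers(0, 3, 50).astype(float)
        base = em.lrt_association(y, codes)
        y2 = np.concatenate([y, [np.nan, 1.0, 2.0]])
        c2 = np.concatenate([codes, [0.0, np.nan, np.nan]])
        assert em.lrt_association(y2, c2) == base

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            em.lrt_association(np.ones(10), np.zeros(10))
        with pytest.raises(ValueError, match="few"):
            em.lrt_association(np.arange(4.0), np.array([0.0, 1, 2, 3]))


class TestPermutation:
    def test_shuffle_preserves_code_multiset_and_seed(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        codes = rng.integers(0, 3, 40).astype(float)
        r1 = em.permuted_association(y, codes, np.random.default_rng(7))
        r2 = em.permuted_association(y, codes, np.random.default_rng(7))
        assert r1 == r2
        # multiset preservation is structural: permutation cannot change k or n
        assert r1[4] == np.unique(codes).size and r1[3] == 40

    def test_permuted_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(1000):
            y = rng.normal(size=120)
            codes = rng.integers(0, 3, 120).astype(float)
            ps.append(em.permuted_association(y, codes, rng)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,expected",
        [(1_555_828, 3.2e-8), (1_227_485, 4.1e-8), (353_694, 1.4e-7)],
    )
    def test_reported_thresholds_at_two_sig_figs(self, n, expected):
        thr = em.bonferroni_threshold(n, 0.05)
        assert float(f"{thr:.1e}") == expected

    def test_edge_cases(self):
        assert em.bonferroni_threshold(1, 0.05) == 0.05
        with pytest.raises(ValueError):
            em.bonferroni_threshold(0)


class TestCandidates:
    @pytest.fixture()
    def meta(self):
        return pd.DataFrame(
            {"gene": ["g"], "chrom": ["II"], "tss": [2_000_000], "strand": ["+"]},
            index=pd.Index(["t1"], name="transcript"),
        )

    @pytest.fixture()
    def loci(self):
        return pd.DataFrame(
            {
                "chrom": ["II", "II", "II", "III"],
                "pos": [2_010_000, 3_000_000, 3_000_001, 2_010_000],
                "end": [2_010_010, 3_000_010, 3_000_011, 2_010_010],
                "motif": ["AT"] * 4,
            },
            index=pd.Index(["near", "boundary", "outside", "other_chrom"], name="locus"),
        )

    def test_window_membership(self, meta, loci):
        sel = em.select_local_candidates("t1", meta, loci, window_bp=1_000_000)
        assert "near" in sel.index
        assert "other_chrom" not in sel.index
        # boundary locus starts exactly at tss + window: closed interval
        assert "boundary" in sel.index
        assert "outside" not in sel.index

    def test_distance_sign_respects_strand(self, meta, loci):
        sel = em.select_local_candidates("t1", meta, loci, 1_000_000)
        assert sel.loc["near", "distance_to_tss"] > 0
        minus = meta.assign(strand="-")
        sel2 = em.select_local_candidates("t1", minus, loci, 1_000_000)
        assert sel2.loc["near", "distance_to_tss"] < 0

    def test_missing_coordinates_raise(self, meta, loci):
        with pytest.raises(KeyError):
            em.select_local_candidates("nope", meta, loci, 1_000_000)

    def test_distant_candidates_match_brute_force(self, meta):
        rng = np.random.default_rng(5)
        loci = pd.DataFrame(
            {
                "chrom": rng.choice(["II", "III"], 20),
                "pos": rng.integers(1, 5_000_000, 20),
                "motif": "AT",
            },
            index=pd.Index([f"L{i}" for i in range(20)], name="locus"),
        )
        loci["end"] = loci["pos"] + 10
        eqtl = pd.DataFrame(
            {
                "eqtl_id": ["q1", "q2", "q3"],
                "transcript": ["t1"] * 3,
                "chrom": ["II", "II", "III"],
                "peak": [1_050_000, 2_550_000, 900_000],
                "start": [1_000_000, 2_500_000, 800_000],
                "end": [1_100_000, 2_600_000, 1_000_000],
                "klass": ["distant"] * 3,
            }
        )
        w = 500_000
        sel = em.select_distant_candidates("t1", meta, eqtl, loci, w)
        expected = set()
        for _, r in eqtl.iterrows():
            for lid, lr in loci.iterrows():
                if lr["chrom"] == r["chrom"] and lr["end"] >= r["start"] - w and lr["pos"] <= r["end"] + w:
                    expected.add(lid)
        assert set(sel.index) == expected
        assert not sel.index.has_duplicates

    def test_no_distant_eqtl_gives_empty(self, meta):
        loci = pd.DataFrame(
            {"chrom": ["II"], "pos": [1], "end": [10], "motif": ["A"]},
            index=pd.Index(["L0"], name="locus"),
        )
        eqtl = pd.DataFrame(
            columns=["eqtl_id", "transcript", "chrom", "peak", "start", "end", "klass"]
        )
        assert em.select_distant_candidates("t1", meta, eqtl, loci, 100).empty


class TestCalling:
    def _results(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "transcript", "locus", "coding_kind", "n_strains", "n_codes",
                "lrt_stat", "df", "p_value", "is_permuted", "distance_to_tss",
            ],
        )

    def test_empty_results_give_empty_calls(self):
        calls = em.call_estrs(self._results([]), "local")
        assert calls.empty

    def test_tie_breaks_to_nearer_tss(self):
        rows = [
            ("t1", "far", "genotype", 50, 2, 40.0, 1, 1e-10, False, 50_000.0),
            ("t1", "near", "genotype", 50, 2, 40.0, 1, 1e-10, False, -1_000.0),
        ]
        calls = em.call_estrs(self._results(rows), "local")
        top = calls[calls["is_top_for_transcript"]]
        assert list(top["locus"]) == ["near"]

    def test_family_size_is_real_test_count(self):
        rows = [
            ("t1", "a", "genotype", 50, 2, 40.0, 1, 1e-10, False, 0.0),
            ("t1", "a", "genotype", 50, 2, 1.0, 1, 0.3, True, 0.0),
            ("t2", "b", "genotype", 50, 2, 1.0, 1, 0.4, False, 0.0),
        ]
        calls = em.call_estrs(self._results(rows), "local")
        assert calls.attrs["n_tests"] == 2
        assert calls.attrs["bonferroni_threshold"] == 0.025

    def test_planted_effects_recovered_without_permuted_passes(self):
        """20 planted biallelic local effects at delta/sigma = 2 with n = 200
        strains: nearly all recovered at family-wise Bonferroni; permuted
        copies never pass."""
        panel = sd.simulate_str_panel(200, 120, missing_rate=0.02, het_rate=0.0,
                                      seed=31, common_locus_fraction=1.0)
        codes = str_prep.transform_genotypes(panel)
        tr = sd.make_transcript_table(120, seed=32)
        # place transcripts near their loci so candidates exist
        tr = tr.copy()
        tr["chrom"] = panel.loci["chrom"].to_numpy()
        tr["tss"] = panel.loci["pos"].to_numpy() + 1000
        planted = sd.plant_local_effects(panel, tr, n_effects=20, delta=2.0)
        truth = sd.SimTruth(planted_local_effects=planted)
        expr = sd.simulate_expression(panel, tr, truth, noise_sd=1.0, seed=33)
        config = RunConfig(rng_seed=34, local_window_bp=100_000)
        results = em.map_local(expr, codes, config)
        calls = em.call_estrs(results, "local")
        thr = calls.attrs["bonferroni_threshold"]
        found = {
            (p["transcript"], p["locus"])
            for p in planted
            if not calls[
                (calls["transcript"] == p["transcript"])
                & (calls["locus"] == p["locus"])
                & calls["passes_bonferroni"]
            ].empty
        }
        assert len(found) >= 18
        permuted = results[results["is_permuted"]]
        assert (permuted["p_value"] > thr).all()


def test_merge_coding_calls_flags_both():
    g = pd.DataFrame(
        {"transcript": ["t1", "t2"], "locus": ["a", "b"],
         "passes_bonferroni": [True, True]}
    )
    l = pd.DataFrame(
        {"transcript": ["t1", "t3"], "locus": ["a", "c"],
         "passes_bonferroni": [True, True]}
    )
    merged = em.merge_coding_calls(g, l)
    by = dict(zip(zip(merged["transcript"], merged["locus"]), merged["found_by"]))
    assert by == {("t1", "a"): "both", ("t2", "b"): "genotype", ("t3", "c"): "length"}


class TestCommonEstrs:
    def _fixture(self):
        hotspots = IntervalSet(
            pd.DataFrame(
                {"chrom": ["II", "II", "III"], "start": [1_000_000, 5_000_000, 1],
                 "end": [1_200_000, 5_100_000, 100_000],
                 "name": ["h1", "h2", "h3"]}
            )
        )
        loci = pd.DataFrame(
            {"chrom": ["II", "II", "III"], "pos": [1_050_000, 5_050_000, 50_000],
             "end": [1_050_010, 5_050_010, 50_010], "motif": "AT"},
            index=pd.Index(["e1", "e2", "e3"], name="locus"),
        )
        eqtl_rows = []
        for i in range(10):
            eqtl_rows.append(
                {"eqtl_id": f"q{i}", "transcript": f"t{i}", "chrom": "II",
                 "peak": 1_000_000 + i * 10_000, "start": 1_000_000,
                 "end": 1_200_000, "klass": "distant"}
            )
        eqtl_rows.append(
            {"eqtl_id": "q_h2", "transcript": "t_h2", "chrom": "II",
             "peak": 5_050_000, "start": 5_000_000, "end": 5_100_000,
             "klass": "distant"}
        )
        eqtl = pd.DataFrame(eqtl_rows)
        call_rows = []
        for i in range(6):  # e1 called for 6 of the 10 h1 transcripts
            call_rows.append({"transcript": f"t{i}", "locus": "e1", "passes_bonferroni": True})
        call_rows.append({"transcript": "t_h2", "locus": "e2", "passes_bonferroni": True})
        calls = pd.DataFrame(call_rows)
        return calls, hotspots, eqtl, loci

    def test_counts_and_fractions_match_hand_enumeration(self):
        calls, hotspots, eqtl, loci = self._fixture()
        table = em.find_common_estrs(calls, hotspots, eqtl, loci, window_bp=500_000, min_eqtl=5)
        h1 = table[(table["hotspot"] == "h1") & (table["locus"] == "e1")].iloc[0]
        assert h1["n_eqtl_linked"] == 6 and h1["n_eqtl_in_hotspot"] == 10
        assert h1["fraction"] == pytest.approx(0.6)
        assert bool(h1["is_common"])
        h2 = table[(table["hotspot"] == "h2") & (table["locus"] == "e2")].iloc[0]
        assert h2["n_eqtl_linked"] == 1 and not h2["is_common"]
        assert "h3" not in set(table["hotspot"])  # no eQTL there

    def test_threshold_boundary(self):
        calls, hotspots, eqtl, loci = self._fixture()
        table = em.find_common_estrs(calls, hotspots, eqtl, loci, 500_000, min_eqtl=7)
        assert not table[table["locus"] == "e1"]["is_common"].any()


class TestMotifEnrichment:
    def _loci(self):
        motifs = ["AT"] * 10 + ["ATTTTT"] * 10
        return pd.DataFrame(
            {"chrom": "I", "pos": 1, "end": 2, "motif": motifs},
            index=pd.Index([f"L{i}" for i in range(20)], name="locus"),
        )

    def test_perfect_split_matches_hypergeometric_tail(self):
        loci = self._loci()
        called = [f"L{i}" for i in range(10, 20)]  # all ATTTTT called
        out = em.motif_enrichment(called, list(loci.index), loci)
        row = out[out["motif"] == "ATTTTT"].iloc[0]
        # one-sided enrichment tail summed directly from the hypergeometric pmf
        oracle = sum(stats.hypergeom.pmf(k, 20, 10, 10) for k in range(10, 11))
        assert row["p_value"] == pytest.approx(oracle, rel=1e-10)

    def test_motif_absent_from_calls_not_enriched(self):
        loci = self._loci()
        out = em.motif_enrichment(["L0"], list(loci.index), loci)
        row = out[out["motif"] == "ATTTTT"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)

    def test_adjusted_p_capped_at_one(self):
        loci = self._loci()
        out = em.motif_enrichment(["L0"], list(loci.index), loci)
        assert (out["p_adjusted"] <= 1.0).all()
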