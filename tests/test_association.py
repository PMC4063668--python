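import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tandemcnv import association as assoc
from tandemcnv.association import (
    DegenerateInput,
    MethylationStageConfig,
    PermutationConfig,
    SnpPanel,
    correlate,
    encode_genotypes,
    filter_snps,
    hwe_test,
    methylation_pipeline,
    methylation_qc,
    normalized_slope,
    permutation_p,
    sliding_window_enrichment,
    tag_snp_scan,
)
from tandemcnv.io_formats import FeatureMatrix, ValidationError
from tandemcnv.probe_design import WindowSet
from tests.conftest import make_matrix


def panel_from_codes(codes: dict, positions: dict | None = None, chrom="chr1",
                     samples=None):
    lut = {0: "AA", 1: "AG", 2: "GG"}
    n = len(next(iter(codes.values())))
    samples = samples or [f"s{i}" for i in range(n)]
    calls = pd.DataFrame(
        {
            snp: pd.Series(
                [lut[c] if not (isinstance(c, float) and np.isnan(c)) else pd.NA
                 for c in cs],
                index=samples,
                dtype="string",
            )
            for snp, cs in codes.items()
        }
    ).T
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [positions.get(s, 100 + 10 * i) if positions else 100 + 10 * i
                    for i, s in enumerate(calls.index)],
        },
        index=calls.index,
    )
    return SnpPanel.from_calls(calls, meta)


class TestEncodeGenotypes:
    def test_designated_allele_is_alphabetically_first(self):
        calls = pd.Series(["AA", "AG", "GG"], dtype="string")
        assert list(encode_genotypes(calls)) == [0, 1, 2]

    def test_monomorphic_all_zero(self):
        calls = pd.Series(["AA", "AA"], dtype="string")
        assert list(encode_genotypes(calls)) == [0, 0]

    def test_missing_preserved(self):
        calls = pd.Series(["AA", pd.NA, "GG"], dtype="string")
        codes = encode_genotypes(calls)
        assert np.isnan(codes.iloc[1])

    def test_third_allele_rejected(self):
        with pytest.raises(ValidationError):
            encode_genotypes(pd.Series(["AA", "AG", "CC"], dtype="string"))

    def test_allele_swap_flips_codes_but_not_r2(self, rng):
        """Reversing which homozygote is 0 maps codes 0<->2 and only flips r."""
        codes = rng.integers(0, 3, size=30)
        lut_fwd = {0: "AA", 1: "AG", 2: "GG"}
        lut_rev = {0: "TT", 1: "GT", 2: "GG"}  # G now alphabetically first
        fwd = encode_genotypes(pd.Series([lut_fwd[c] for c in codes], dtype="string"))
        rev = encode_genotypes(pd.Series([lut_rev[c] for c in codes], dtype="string"))
        assert list(rev) == list(2 - fwd)
        y = pd.Series(rng.normal(size=30))
        r_fwd = correlate(fwd.astype(float), y).r
        r_rev = correlate(rev.astype(float), y).r
        assert r_rev == pytest.approx(-r_fwd)


class TestHwe:
    def test_perfect_equilibrium(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_heterozygous_extreme_departure(self):
        p = hwe_test(0, 100, 0)
        assert p < 1e-20

    def test_monomorphic_returns_one(self):
        assert hwe_test(50, 0, 0) == 1.0

    def test_matches_expected_count_formula(self, rng):
        for _ in range(50):
            n_aa, n_ab, n_bb = rng.integers(1, 100, size=3)
            n = n_aa + n_ab + n_bb
            p = (2 * n_aa + n_ab) / (2 * n)
            q = 1 - p
            exp = [p * p * n, 2 * p * q * n, q * q * n]
            chi2 = sum((o - e) ** 2 / e for o, e in zip([n_aa, n_ab, n_bb], exp))
            assert hwe_test(n_aa, n_ab, n_bb) == pytest.approx(
                stats.chi2.sf(chi2, 1), abs=1e-12
            )


class TestFilterSnps:
    def test_low_maf_removed(self):
        panel = panel_from_codes({"common": [0, 1, 2, 1, 0, 1, 1, 2, 0, 1],
                                  "rare": [0, 0, 0, 0, 0, 0, 0, 0, 0, 1]})
        filtered, funnel = filter_snps(panel, maf_min=0.1)
        assert "rare" not in filtered.snp_ids
        assert "common" in filtered.snp_ids
        assert funnel["maf_below_min"] == 1

    def test_hwe_failure_removed(self):
        panel = panel_from_codes({"het": [1] * 40})
        filtered, funnel = filter_snps(panel)
        assert filtered.snp_ids == []
        assert funnel["hwe_fail"] == 1

    def test_stringent_flags_removed_only_when_requested(self):
        panel = panel_from_codes({"flagged": [0, 1, 2, 1, 0, 1, 1, 2, 0, 1]})
        panel.meta.loc["flagged", "in_segdup"] = True
        basic, _ = filter_snps(panel, stringent=False)
        strict, funnel = filter_snps(panel, stringent=True)
        assert "flagged" in basic.snp_ids
        assert "flagged" not in strict.snp_ids
        assert funnel["stringent_flags"] == 1

    def test_matches_rule_by_rule_oracle(self, rng):
        codes = {f"snp{i}": list(rng.integers(0, 3, size=40)) for i in range(30)}
        panel = panel_from_codes(codes)
        flag_rows = rng.choice(panel.snp_ids, size=5, replace=False)
        panel.meta.loc[flag_rows, "in_cnv"] = True
        filtered, _ = filter_snps(panel, stringent=True)
        for snp in panel.snp_ids:
            keep = (
                panel.maf[snp] >= 0.1
                and panel.hwe_p[snp] >= 0.05
                and not panel.meta.loc[snp, "tri_allelic"]
                and not panel.meta.loc[snp, ["multi_mapped_51bp", "in_segdup", "in_cnv"]].any()
            )
            assert (snp in filtered.snp_ids) == keep


class TestCorrelate:
    def test_exact_linear_relation(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        res_p = correlate(x, 2 * x, "pearson_r")
        res_s = correlate(x, 2 * x, "spearman_rho")
        assert res_p.r == pytest.approx(1.0)
        assert res_p.slope == pytest.approx(2.0)
        assert res_s.r == pytest.approx(1.0)

    def test_constant_feature_degenerate(self):
        x = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInput):
            correlate(x, pd.Series([5.0, 5.0, 5.0]))

    def test_pairwise_missing_removal(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0])
        y = pd.Series([2.0, 4.0, 6.0, np.nan, 10.0])
        res = correlate(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_spearman_equals_rank_then_pearson_oracle(self, rng):
        for _ in range(25):
            x = pd.Series(rng.normal(size=6))
            y = pd.Series(rng.normal(size=6))
            rho = correlate(x, y, "spearman_rho").r
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_pearson_matches_textbook_formula(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 20))
            x = pd.Series(rng.normal(size=n))
            y = pd.Series(rng.normal(size=n))
            r = correlate(x, y, "pearson_r").r
            xc, yc = x - x.mean(), y - y.mean()
            oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert r == pytest.approx(oracle, abs=1e-12)


class TestPermutation:
    def test_perfect_correlation_p_zero_with_resolution_flag(self, rng):
        x = pd.Series(np.arange(20.0))
        y = 3 * x + 1
        res = permutation_p(1.0, x, y, PermutationConfig(n_permutations=100), rng=rng)
        assert res.p == 0.0 and res.below_resolution

    def test_zero_observed_statistic_p_near_one(self, rng):
        x = pd.Series(rng.normal(size=50))
        y = pd.Series(rng.normal(size=50))
        res = permutation_p(0.0, x, y, PermutationConfig(n_permutations=500), rng=rng)
        assert res.p > 0.9

    def test_seeded_reproducibility(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        x = pd.Series(np.random.default_rng(0).normal(size=30))
        y = pd.Series(np.random.default_rng(1).normal(size=30))
        cfg = PermutationConfig(n_permutations=200)
        a = permutation_p(0.3, x, y, cfg, rng=rng1)
        b = permutation_p(0.3, x, y, cfg, rng=rng2)
        assert a.p == b.p

    def test_label_swap_invariance(self, rng):
        """Identically permuting both vectors leaves the statistic unchanged."""
        x = pd.Series(rng.normal(size=25))
        y = pd.Series(0.5 * x + rng.normal(size=25) * 0.5)
        perm = rng.permutation(25)
        r1 = correlate(x, y).r
        r2 = correlate(
            pd.Series(x.to_numpy()[perm]), pd.Series(y.to_numpy()[perm])
        ).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_resample_features_null(self, rng):
        samples = [f"s{i}" for i in range(40)]
        x = pd.Series(rng.normal(size=40), index=samples)
        y = pd.Series(rng.normal(size=40), index=samples)
        pool = pd.DataFrame(rng.normal(size=(300, 40)), columns=samples)
        cfg = PermutationConfig(n_permutations=200, null_kind="resample_features")
        res = permutation_p(0.9, x, y, cfg, pool=pool, rng=rng)
        assert res.p == 0.0  # null draws rarely beat |r| = 0.9 at n = 40
        res2 = permutation_p(0.0, x, y, cfg, pool=pool, rng=rng)
        assert res2.p > 0.9

    def test_resample_pool_smaller_than_draws_still_reports(self, rng):
        samples = [f"s{i}" for i in range(10)]
        x = pd.Series(rng.normal(size=10), index=samples)
        y = pd.Series(rng.normal(size=10), index=samples)
        pool = pd.DataFrame(rng.normal(size=(5, 10)), columns=samples)
        cfg = PermutationConfig(n_permutations=50, null_kind="resample_features")
        res = permutation_p(0.1, x, y, cfg, pool=pool, rng=rng)
        assert res.n_permutations == 50

    def test_empty_pool_rejected(self, rng):
        x = pd.Series(np.arange(5.0))
        cfg = PermutationConfig(n_permutations=10, null_kind="resample_features")
        with pytest.raises(ValidationError):
            permutation_p(0.5, x, x, cfg, pool=None, rng=rng)


class TestTagSnpScan:
    def test_perfect_planted_tag_recovered(self, tiny_samples):
        cn = pd.Series([2.0, 2, 4, 4, 6, 6, 4, 2], index=tiny_samples.sample_ids)
        codes = {"tag": [0, 0, 1, 1, 2, 2, 1, 0], "noise": [1, 0, 1, 0, 1, 0, 1, 0]}
        lut = {0: "AA", 1: "AG", 2: "GG"}
        calls = pd.DataFrame(
            {s: {snp: lut[codes[snp][i]] for snp in codes}
             for i, s in enumerate(tiny_samples.sample_ids)},
            dtype="string",
        )
        meta = pd.DataFrame({"chrom": "chr1", "pos": [150, 160]}, index=["tag", "noise"])
        panel = SnpPanel.from_calls(calls.loc[["tag", "noise"]], meta)
        ws = WindowSet("p1", [("chr1", 0, 1000)])
        records = tag_snp_scan(
            "p1", cn, panel, ws, tiny_samples, n_permutations=50,
            rng=np.random.default_rng(0),
        )
        combined = next(r for r in records if r.population_set == "combined")
        assert combined.feature_id == "tag"
        assert combined.r2 == pytest.approx(1.0)

    def test_no_in_window_snps_yields_missing_record(self, tiny_samples):
        cn = pd.Series(np.arange(8.0), index=tiny_samples.sample_ids)
        panel = panel_from_codes({"far": [0, 1, 2, 1, 0, 1, 2, 1]},
                                 positions={"far": 10_000},
                                 samples=tiny_samples.sample_ids)
        ws = WindowSet("p1", [("chr1", 0, 100)])
        records = tag_snp_scan("p1", cn, panel, ws, tiny_samples,
                               n_permutations=10, rng=np.random.default_rng(0))
        combined = next(r for r in records if r.population_set == "combined")
        assert combined.feature_id is None
        assert combined.flag == "no_snps_in_window"

    def test_reports_each_population_and_combined(self, tiny_samples):
        cn = pd.Series(np.arange(8.0), index=tiny_samples.sample_ids)
        panel = panel_from_codes({"s": [0, 1, 2, 1, 0, 1, 2, 1]},
                                 samples=tiny_samples.sample_ids)
        ws = WindowSet("p1", [("chr1", 0, 1000)])
        records = tag_snp_scan("p1", cn, panel, ws, tiny_samples,
                               n_permutations=10, rng=np.random.default_rng(0))
        assert {r.population_set for r in records} == {"CEU", "YRI", "combined"}


class TestExpressionScan:
    def _expr(self, rows, positions, samples):
        coords = pd.DataFrame(
            {"chrom": "chr1", "pos": [positions[t] for t in rows]}, index=list(rows)
        )
        return FeatureMatrix(
            pd.DataFrame({s: {t: rows[t][i] for t in rows}
                          for i, s in enumerate(samples)}),
            coords,
        )

    def test_low_mean_and_low_iqr_transcripts_removed(self):
        samples = [f"s{i}" for i in range(8)]
        spread = [0.0, 1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 0.0]
        rows = {
            "low_mean": [5.9 + v for v in spread],
            "low_iqr": [7.0 + v * 0.05 for v in spread],
            "ok": [7.0 + v for v in spread],
        }
        expr = self._expr(rows, {t: 100 for t in rows}, samples)
        kept, dropped = assoc.expression_filter(expr)
        assert set(dropped) == {"low_mean", "low_iqr"}
        assert kept.feature_ids == ["ok"]

    def test_planted_cis_effect_recovered_with_sign(self, tiny_samples, rng):
        cn = pd.Series([2.0, 4, 6, 8, 10, 12, 14, 16], index=tiny_samples.sample_ids)
        slope = -0.2
        planted = 8.0 + slope * cn + 0.05 * rng.standard_normal(8)
        null = 8.0 + rng.standard_normal(8)
        expr = self._expr(
            {"planted": list(planted), "null": list(null)},
            {"planted": 100, "null": 200},
            tiny_samples.sample_ids,
        )
        ws = WindowSet("p1", [("chr1", 0, 1000)])
        records = assoc.expression_scan(
            "p1", cn, expr, ws, tiny_samples, target_name="planted",
            n_permutations=200, rng=rng,
        )
        rec = next(
            r for r in records
            if r.population_set == "combined" and r.feature_id == "planted"
        )
        assert rec.r < 0 and np.sign(rec.slope) == np.sign(slope)
        assert rec.p_perm is not None and rec.p_perm <= 0.05
        assert "auto_correlation" in rec.flag


class TestNormalizedSlope:
    def test_closed_form(self):
        cn = pd.Series(np.linspace(0, 10, 6))
        beta = 0.01 * cn + 0.2
        ns, flag = normalized_slope(beta, cn)
        assert ns == pytest.approx(0.1)
        assert flag == ""

    def test_constant_beta_gives_zero(self):
        cn = pd.Series([1.0, 2.0, 3.0])
        ns, flag = normalized_slope(pd.Series([0.5, 0.5, 0.5]), cn)
        assert ns == 0.0 and flag == ""

    def test_zero_cn_range_flagged(self):
        cn = pd.Series([3.0, 3.0, 3.0])
        ns, flag = normalized_slope(pd.Series([0.1, 0.5, 0.9]), cn)
        assert ns == 0.0 and flag == "zero_cn_range"

    def test_noisy_fixture_matches_least_squares_oracle(self, rng):
        cn = pd.Series(rng.uniform(2, 40, size=30))
        beta = pd.Series(0.005 * cn + rng.normal(0, 0.02, size=30))
        ns, _ = normalized_slope(beta, cn)
        slope_oracle = np.polyfit(cn, beta, 1)[0]
        assert ns == pytest.approx(slope_oracle * (cn.max() - cn.min()), abs=1e-12)

    def test_scale_free_in_cn_units(self, rng):
        cn = pd.Series(rng.uniform(2, 40, size=30))
        beta = pd.Series(0.005 * cn + rng.normal(0, 0.02, size=30))
        ns1, _ = normalized_slope(beta, cn)
        ns2, _ = normalized_slope(beta, cn * 13.7 + 5)
        assert ns1 == pytest.approx(ns2, abs=1e-12)


class TestMethylationQc:
    def _meth(self, n_samples=20):
        vals = np.full((4, n_samples), 0.5)
        vals[1, : int(0.06 * n_samples) + 1] = np.nan  # just above 5% missing
        coords = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chrY", "chrX"], "pos": [1, 2, 3, 4]},
            index=["cg_ok", "cg_missing", "cg_y", "cg_x"],
        )
        return make_matrix(vals, probes=list(coords.index), coords=coords)

    def test_high_missing_and_chry_removed(self):
        auto, chrx, funnel = methylation_qc(self._meth())
        assert auto.feature_ids == ["cg_ok"]
        assert chrx.feature_ids == ["cg_x"]
        assert funnel["chrY"] == 1 and funnel["high_missing"] == 1

    def test_flag_table_respected(self):
        meth = self._meth()
        flags = pd.DataFrame(
            {"multi_loci": [True, False, False, False],
             "snp_overlap": [False, False, False, False]},
            index=meth.feature_ids,
        )
        auto, _, funnel = methylation_qc(meth, flags)
        assert "cg_ok" not in auto.feature_ids
        assert funnel["multi_loci"] == 1

    def test_matches_rule_oracle_on_random_flags(self, rng):
        n = 30
        vals = rng.uniform(0, 1, size=(n, 40))
        miss = rng.uniform(size=(n, 40)) < rng.uniform(0, 0.12, size=(n, 1))
        vals[miss] = np.nan
        chroms = rng.choice(["chr1", "chrX", "chrY"], size=n)
        coords = pd.DataFrame(
            {"chrom": chroms, "pos": np.arange(n)}, index=[f"cg{i}" for i in range(n)]
        )
        fm = make_matrix(vals, probes=list(coords.index), coords=coords)
        flags = pd.DataFrame(
            {"multi_loci": rng.uniform(size=n) < 0.2,
             "snp_overlap": rng.uniform(size=n) < 0.2},
            index=fm.feature_ids,
        )
        auto, chrx, _ = methylation_qc(fm, flags)
        for i, cg in enumerate(fm.feature_ids):
            keep = (
                not flags.loc[cg].any()
                and chroms[i] != "chrY"
                and np.isnan(vals[i]).mean() <= 0.05
            )
            expected_bucket = (
                None if not keep else ("chrx" if chroms[i] == "chrX" else "auto")
            )
            assert (cg in auto.feature_ids) == (expected_bucket == "auto")
            assert (cg in chrx.feature_ids) == (expected_bucket == "chrx")


class TestMethylationPipeline:
    def _setup(self, rng, n_samples=40, planted_rho_rank=True):
        samples = [f"s{i}" for i in range(n_samples)]
        pops = ["CEU"] * (n_samples // 2) + ["YRI"] * (n_samples - n_samples // 2)
        sample_df = pd.DataFrame(
            {"sample_id": samples, "population": pops,
             "sex": ["male", "female"] * (n_samples // 2), "species": "human"}
        ).set_index("sample_id")
        from tandemcnv.io_formats import SampleTable

        st = SampleTable(sample_df)
        cn = pd.DataFrame(
            {s: {"p1": v} for s, v in zip(samples, rng.uniform(2, 40, n_samples))}
        )
        coords_rows = []
        vals = {}
        for j in range(30):
            cid = f"cg{j}"
            vals[cid] = np.clip(0.5 + 0.1 * rng.standard_normal(n_samples), 0, 1)
            coords_rows.append({"feature_id": cid, "chrom": "chr1", "pos": 10 + j})
        cn_vec = cn.loc["p1"].to_numpy()
        vals["cg_planted"] = np.clip(
            0.2 + 0.3 * (cn_vec - cn_vec.min()) / np.ptp(cn_vec)
            + 0.03 * rng.standard_normal(n_samples),
            0, 1,
        )
        coords_rows.append({"feature_id": "cg_planted", "chrom": "chr1", "pos": 500})
        coords = pd.DataFrame(coords_rows).set_index("feature_id")
        meth = FeatureMatrix(
            pd.DataFrame.from_dict(vals, orient="index", columns=samples), coords
        )
        pool = pd.DataFrame(
            np.clip(0.5 + 0.1 * rng.standard_normal((400, n_samples)), 0, 1),
            columns=samples,
        )
        windows = {"p1": WindowSet("p1", [("chr1", 0, 1000)])}
        return st, cn, meth, pool, windows

    def test_planted_effect_survives_all_stages(self, rng):
        st, cn, meth, pool, windows = self._setup(rng)
        cfg = MethylationStageConfig(n_permutations=200)
        records, funnel = methylation_pipeline(cn, meth, windows, pool, st, cfg, rng=rng)
        assert funnel["tested_pairs"] == 31
        assert any(r.feature_id == "cg_planted" for r in records)
        rec = next(r for r in records if r.feature_id == "cg_planted")
        assert rec.normalized_slope == pytest.approx(0.3, abs=0.1)

    def test_null_cpgs_fall_at_top_quantile_stage(self, rng):
        st, cn, meth, pool, windows = self._setup(rng)
        cfg = MethylationStageConfig(n_permutations=100)
        records, funnel = methylation_pipeline(cn, meth, windows, pool, st, cfg, rng=rng)
        assert funnel["after_top_quantile"] <= max(1, int(0.03 * funnel["tested_pairs"]) + 1)
        assert all(r.feature_id == "cg_planted" for r in records)

    def test_funnel_counts_monotone(self, rng):
        st, cn, meth, pool, windows = self._setup(rng)
        cfg = MethylationStageConfig(n_permutations=100)
        _, funnel = methylation_pipeline(cn, meth, windows, pool, st, cfg, rng=rng)
        assert (
            funnel["tested_pairs"]
            >= funnel["after_top_quantile"]
            >= funnel["after_normalized_slope"]
            >= funnel["after_permutation"]
            >= funnel["after_replication"]
        )


class TestSlidingWindows:
    def test_identical_tracks_ratio_one(self, rng):
        cov = rng.uniform(1, 5, size=1000)
        df = sliding_window_enrichment(cov, cov)
        assert np.allclose(df["ratio"], 1.0)

    def test_uniform_scaling_cancels(self, rng):
        cov = rng.uniform(1, 5, size=1000)
        df = sliding_window_enrichment(2 * cov, cov)
        assert np.allclose(df["ratio"], 1.0)

    def test_window_count_formula(self):
        df = sliding_window_enrichment(np.ones(1000), np.ones(1000), window=170, step=85)
        assert len(df) == (1000 - 170) // 85 + 1 == 10
        assert df["start"].iloc[0] == 0 and df["end"].iloc[-1] == 9 * 85 + 170

    @pytest.mark.parametrize("L,window,step", [(170, 170, 85), (400, 100, 50),
                                               (999, 170, 85), (171, 170, 85)])
    def test_window_count_grid(self, L, window, step):
        df = sliding_window_enrichment(np.ones(L), np.ones(L), window=window, step=step)
        assert len(df) == (L - window) // step + 1

    def test_region_shorter_than_window_empty(self):
        df = sliding_window_enrichment(np.ones(100), np.ones(100), window=170)
        assert df.empty

    def test_zero_input_window_missing_without_pseudocount(self):
        chip = np.ones(340)
        inp = np.concatenate([np.zeros(170), np.ones(170)])
        df = sliding_window_enrichment(chip, inp, window=170, step=170)
        assert np.isnan(df["ratio"].iloc[0])
        with_eps = sliding_window_enrichment(chip, inp, window=170, step=170, epsilon=1e-6)
        assert np.isfinite(with_eps["ratio"].iloc[0])
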