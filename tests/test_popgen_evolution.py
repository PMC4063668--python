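import itertools

import numpy as np
import pandas as pd
import pytest

from tandemcnv import popgen_evolution as pg
from tandemcnv.io_formats import ValidationError
from tandemcnv.popgen_evolution import DnDsRecord


def oracle_vst(values_by_group):
    """Independent variance decomposition by direct summation."""
    allv = [v for vs in values_by_group.values() for v in vs]
    n = len(allv)
    mean = sum(allv) / n
    v_total = sum((v - mean) ** 2 for v in allv) / (n - 1)
    num = 0.0
    den = 0
    for vs in values_by_group.values():
        m = sum(vs) / len(vs)
        var = sum((v - m) ** 2 for v in vs) / (len(vs) - 1)
        num += len(vs) * var
        den += len(vs)
    v_within = num / den
    if v_total == 0:
        return None
    return (v_total - v_within) / v_total


def series_from_groups(values_by_group):
    vals, groups = {}, {}
    for g, vs in values_by_group.items():
        for i, v in enumerate(vs):
            sid = f"{g}{i}"
            vals[sid] = v
            groups[sid] = g
    return pd.Series(vals, dtype=float), pd.Series(groups)


class TestVst:
    def test_all_identical_undefined(self):
        vals, groups = series_from_groups({"CEU": [2, 2], "YRI": [2, 2]})
        rec = pg.vst(vals, groups)
        assert np.isnan(rec.vst) and rec.flag == "v_total_zero"

    def test_within_group_constant_gives_one(self):
        vals, groups = series_from_groups({"CEU": [2, 2], "YRI": [8, 8]})
        rec = pg.vst(vals, groups)
        assert rec.vst == pytest.approx(1.0)
        assert rec.v_within == 0.0

    def test_three_group_fixture_matches_direct_summation(self):
        by_group = {"CEU": [4, 6], "YRI": [8, 10], "CHB": [4, 6]}
        vals, groups = series_from_groups(by_group)
        rec = pg.vst(vals, groups)
        assert rec.vst_raw == pytest.approx(oracle_vst(by_group), abs=1e-12)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(200):
            by_group = {
                g: list(rng.normal(rng.uniform(0, 10), rng.uniform(0.5, 3),
                                   size=rng.integers(2, 20)))
                for g in ("CEU", "YRI", "CHB")
            }
            vals, groups = series_from_groups(by_group)
            rec = pg.vst(vals, groups)
            assert rec.vst_raw == pytest.approx(oracle_vst(by_group), abs=1e-12)

    def test_shift_and_scale_invariance(self, rng):
        by_group = {
            g: list(rng.normal(i, 1, size=10)) for i, g in enumerate(("CEU", "YRI"))
        }
        vals, groups = series_from_groups(by_group)
        base = pg.vst(vals, groups).vst_raw
        assert pg.vst(vals + 100, groups).vst_raw == pytest.approx(base, abs=1e-10)
        assert pg.vst(vals * -3.7, groups).vst_raw == pytest.approx(base, abs=1e-10)

    def test_negative_raw_floored_for_reporting(self):
        by_group = {"CEU": [1.0, 9.0], "YRI": [2.0, 8.0]}
        vals, groups = series_from_groups(by_group)
        rec = pg.vst(vals, groups)
        assert rec.vst_raw < 0
        assert rec.vst == 0.0

    def test_too_few_groups_rejected(self):
        vals, groups = series_from_groups({"CEU": [1, 2]})
        with pytest.raises(ValidationError):
            pg.vst(vals, groups)

    def test_simulation_mean_approaches_analytic_expectation(self, rng):
        """Planted between-population shifts: mean V_ST ≈ σ²_B/(σ²_B+σ²_W)."""
        shift = {"CEU": -1.0, "YRI": 0.0, "CHB": 1.0}
        n_per = 40
        sigma_w = 1.0
        # population variance of the group means (population-weighted, equal sizes)
        sigma_b2 = np.var(list(shift.values()))
        expected = sigma_b2 / (sigma_b2 + sigma_w**2)
        vsts = []
        for _ in range(300):
            by_group = {
                g: list(rng.normal(mu, sigma_w, size=n_per)) for g, mu in shift.items()
            }
            vals, groups = series_from_groups(by_group)
            vsts.append(pg.vst(vals, groups).vst_raw)
        assert np.mean(vsts) == pytest.approx(expected, abs=0.03)


class TestVstSexAware:
    def _stratified(self, male_groups, female_groups):
        vals, groups, sexes = {}, {}, {}
        for sex, by_group in (("male", male_groups), ("female", female_groups)):
            for g, vs in by_group.items():
                for i, v in enumerate(vs):
                    sid = f"{sex}_{g}{i}"
                    vals[sid] = v
                    groups[sid] = g
                    sexes[sid] = sex
        return pd.Series(vals, dtype=float), pd.Series(groups), pd.Series(sexes)

    def test_identical_strata_equal_autosomal_value(self):
        by_group = {"CEU": [4.0, 6.0], "YRI": [8.0, 10.0]}
        vals, groups, sexes = self._stratified(by_group, by_group)
        rec = pg.vst_sex_aware(vals, groups, sexes, "chrX")
        auto = oracle_vst(by_group)
        assert rec.vst_male == pytest.approx(max(auto, 0))
        assert rec.vst == pytest.approx(max(auto, 0))

    def test_mean_of_constructed_strata(self, rng):
        male = {"CEU": list(rng.normal(0, 1, 30)), "YRI": list(rng.normal(2, 1, 30))}
        female = {"CEU": list(rng.normal(0, 2, 30)), "YRI": list(rng.normal(1, 2, 30))}
        vals, groups, sexes = self._stratified(male, female)
        rec = pg.vst_sex_aware(vals, groups, sexes, "chrX")
        vm = max(oracle_vst(male), 0)
        vf = max(oracle_vst(female), 0)
        assert rec.vst_male == pytest.approx(vm, abs=1e-12)
        assert rec.vst_female == pytest.approx(vf, abs=1e-12)
        assert rec.vst == pytest.approx((vm + vf) / 2, abs=1e-12)

    def test_chry_uses_males_only(self):
        male = {"CEU": [2.0, 2.0], "YRI": [8.0, 8.0]}
        female = {"CEU": [5.0, 5.0], "YRI": [5.0, 5.0]}
        vals, groups, sexes = self._stratified(male, female)
        rec = pg.vst_sex_aware(vals, groups, sexes, "chrY")
        assert rec.vst == pytest.approx(1.0)

    def test_missing_sex_rejected_for_chrx(self):
        male = {"CEU": [2.0, 3.0], "YRI": [8.0, 9.0]}
        vals, groups, sexes = self._stratified(male, {})
        with pytest.raises(ValidationError):
            pg.vst_sex_aware(vals, groups, sexes, "chrX")


class TestFlagDifferentiated:
    def test_strict_threshold(self):
        recs = [
            pg.VstRecord(f"p{i}", v, v, 1, 1, {})
            for i, v in enumerate([0.19, 0.2, 0.21, float("nan")])
        ]
        flagged = pg.flag_differentiated(recs, threshold=0.2)
        assert [r.probe_id for r in flagged] == ["p2"]

    def test_matches_filter_oracle(self, rng):
        vals = rng.uniform(0, 0.5, size=50)
        recs = [pg.VstRecord(f"p{i}", v, v, 1, 1, {}) for i, v in enumerate(vals)]
        flagged = {r.probe_id for r in pg.flag_differentiated(recs)}
        assert flagged == {f"p{i}" for i, v in enumerate(vals) if v > 0.2}


class TestPrimateInvariantSubset:
    def _counts(self, shares, total=1000.0):
        return pd.DataFrame(
            {"chimp": np.asarray(shares) * total},
            index=[f"i{k}" for k in range(len(shares))],
        )

    def test_zero_deviation_included_quarter_deviation_excluded(self):
        human = pd.Series([0.25, 0.25, 0.25, 0.25], index=["i0", "i1", "i2", "i3"])
        shares = np.array([0.25, 0.25 * 1.25, 0.25 * 0.9, 0.25 * 0.85])
        shares = shares / shares.sum()
        counts = self._counts(shares)
        # recompute deviations as the operation defines them (share-of-total)
        passing = pg.primate_invariant_subset(counts, human, tolerance=0.20)["chimp"]
        rel = counts["chimp"] / counts["chimp"].sum()
        expected = [i for i in human.index if abs(rel[i] - human[i]) / human[i] < 0.20]
        assert passing == expected
        assert "i0" in passing

    def test_planted_divergent_controls_excluded(self, rng):
        n = 8
        human = pd.Series(np.full(n, 1 / n), index=[f"i{k}" for k in range(n)])
        shares = np.full(n, 1 / n)
        divergent = {"i2", "i5"}
        for d in divergent:
            shares[int(d[1])] *= 0.5  # halved binding from sequence divergence
        counts = self._counts(shares / shares.sum())
        passing = set(pg.primate_invariant_subset(counts, human)["chimp"])
        assert divergent.isdisjoint(passing)
        assert len(passing) == n - len(divergent)

    def test_too_few_passing_controls_aborts(self):
        human = pd.Series([0.5, 0.3, 0.2], index=["i0", "i1", "i2"])
        counts = self._counts([0.2, 0.3, 0.5])
        with pytest.raises(ValidationError):
            pg.primate_invariant_subset(counts, human, tolerance=0.05)


class TestPrimateFoldChange:
    def _records(self, fold, identity):
        species = pd.DataFrame({"chimp": [fold * 10.0]}, index=["p1"])
        human = pd.Series([10.0], index=["p1"])
        ident = pd.DataFrame({"chimp": [identity]}, index=["p1"])
        (rec,) = pg.primate_fold_change(species, human, ident)
        return rec

    @pytest.mark.parametrize(
        "fold,identity,retained,direction,flagged",
        [
            (3.2, 96.0, True, "gain", True),
            (0.4, 96.0, False, "loss", False),  # losses need >= 98% identity
            (0.4, 99.0, True, "loss", False),  # 1/3 < 0.4: not a 3-fold change
            (0.3, 99.0, True, "loss", True),
            (3.0, 95.0, True, "gain", True),  # both thresholds inclusive
            (2.9, 96.0, True, "gain", False),
            (1.5, 94.9, False, "gain", False),
        ],
    )
    def test_rule_examples(self, fold, identity, retained, direction, flagged):
        rec = self._records(fold, identity)
        assert rec.retained == retained
        assert rec.direction == direction
        assert rec.flagged_3fold == flagged

    def test_retention_rule_exhaustive_grid(self):
        folds = [0.1, 1 / 3, 0.5, 0.99, 1.01, 2.0, 3.0, 5.0]
        idents = [90.0, 94.9, 95.0, 97.9, 98.0, 100.0]
        for fold, ident in itertools.product(folds, idents):
            rec = self._records(fold, ident)
            gain = fold > 1
            expected_retained = ident >= (95.0 if gain else 98.0)
            assert rec.retained == expected_retained
            assert rec.flagged_3fold == (
                expected_retained and (fold >= 3 or fold <= 1 / 3)
            )

    def test_zero_human_mean_skipped(self):
        species = pd.DataFrame({"chimp": [5.0]}, index=["p1"])
        human = pd.Series([0.0], index=["p1"])
        ident = pd.DataFrame({"chimp": [99.0]}, index=["p1"])
        assert pg.primate_fold_change(species, human, ident) == []


class TestDnDs:
    def _table(self, multi, back, identity=95.0):
        return [
            DnDsRecord(f"m{i}", v, identity, True) for i, v in enumerate(multi)
        ] + [DnDsRecord(f"b{i}", v, identity, False) for i, v in enumerate(back)]

    def test_identical_groups_give_zero_statistic(self):
        table = self._table([0.5, 1.5], [0.5, 1.5])
        d, p, fm, fb = pg.dnds_compare(table)
        assert d == 0.0
        assert fm == fb == 0.5

    def test_low_identity_records_excluded_before_testing(self):
        table = self._table([0.5, 0.6], [0.5, 0.6]) + [
            DnDsRecord("junk", 50.0, 60.0, True)  # below the 80% identity cut
        ]
        d, _, fm, _ = pg.dnds_compare(table)
        assert d == 0.0 and fm == 0.0

    def test_statistic_matches_cdf_scan_oracle(self, rng):
        for _ in range(20):
            multi = list(rng.gamma(2, 0.3, size=rng.integers(3, 10)))
            back = list(rng.gamma(2, 0.25, size=rng.integers(3, 12)))
            d, _, _, _ = pg.dnds_compare(self._table(multi, back))
            grid = sorted(multi + back)
            oracle = max(
                abs(
                    sum(v <= g for v in multi) / len(multi)
                    - sum(v <= g for v in back) / len(back)
                )
                for g in grid
            )
            assert d == pytest.approx(oracle, abs=1e-12)

    def test_empty_group_after_filter_rejected(self):
        table = [DnDsRecord("m0", 0.5, 50.0, True)] + [
            DnDsRecord(f"b{i}", 0.5, 95.0, False) for i in range(3)
        ]
        with pytest.raises(ValidationError):
            pg.dnds_compare(table)
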