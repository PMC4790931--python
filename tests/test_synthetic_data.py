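"""The synthetic herd generator: determinism, variance structure, gestation
mechanics."""

import numpy as np
import pytest

from lactbias.lactation_yield import WoodsCurve, daily_sum_yield
from lactbias.synthetic_data import (
    SimulationConfig,
    simulate_herd,
    simulate_pedigree,
    write_herd,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_generations": 0},
            {"heritability": 1.2},
            {"heritability": 0.7, "pe_variance_fraction": 0.5},
            {"calving_spread_days": -1},
            {"dry_off_day": 30},
            {"yield_method": "nope"},
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestPedigreeSimulation:
    def test_zero_heritability_gives_zero_breeding_values(self):
        cfg = SimulationConfig(n_herds=2, cows_per_herd=20, heritability=0.0, seed=1)
        ped = simulate_pedigree(cfg)
        assert max(abs(v) for v in ped.breeding_values.values()) == 0.0

    def test_founder_bv_variance_matches_additive_variance(self):
        cfg = SimulationConfig(n_herds=10, cows_per_herd=200, seed=2)
        ped = simulate_pedigree(cfg)
        founders = [e.animal_id for e in ped.entries if e.sire_id is None and e.dam_id is None]
        bv = np.array([ped.breeding_values[a] for a in founders])
        s2a = cfg.additive_variance
        # sampling SE of a variance estimate: s2a * sqrt(2/(n-1))
        mc_se = s2a * np.sqrt(2 / (len(founders) - 1))
        assert abs(bv.var(ddof=1) - s2a) < 3 * mc_se

    def test_parent_offspring_regression_recovers_heritability(self):
        cfg = SimulationConfig(n_herds=10, cows_per_herd=300, seed=3)
        ped = simulate_pedigree(cfg)
        bv = ped.breeding_values
        pairs = [
            (0.5 * (bv[e.sire_id] + bv[e.dam_id]), bv[e.animal_id])
            for e in ped.entries
            if e.sire_id is not None and e.dam_id is not None
        ]
        mid, off = np.array(pairs).T
        slope = np.polyfit(mid, off, 1)[0]
        # offspring on mid-parent BV regression slope is 1 by construction
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_same_seed_reproduces_files_bitwise(self, tmp_path):
        cfg = SimulationConfig(n_herds=2, cows_per_herd=15, seed=9)
        p1 = write_herd(simulate_herd(cfg), tmp_path / "a")
        p2 = write_herd(simulate_herd(cfg), tmp_path / "b")
        for key in ("s1", "s2", "s3", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()


class TestLactationSimulation:
    def test_all_variances_zero_yield_is_curve_daily_sum(self):
        cfg = SimulationConfig(
            n_herds=1, cows_per_herd=10, seed=4,
            heritability=0.0, pe_variance_fraction=0.0, residual_variance=0.0,
            herd_year_sd=0.0, true_gender_effect_liters=0.0,
            gestation_offset_male_days=0,
            curve_variation="raw", yield_method="exact",
        )
        herd = simulate_herd(cfg)
        for rec, t in zip(herd.lactation_records, herd.truth["records"]):
            a, b, c = t["woods"]
            expect = daily_sum_yield(WoodsCurve(a, b, c), t["lactation_length"])
            assert rec.milk_yield == pytest.approx(expect, abs=2e-3)

    def test_no_offset_no_effect_balanced_gender_yields(self):
        cfg = SimulationConfig(
            n_herds=10, cows_per_herd=100, seed=5, yield_method="exact",
            gestation_offset_male_days=0, true_gender_effect_liters=0.0,
        )
        herd = simulate_herd(cfg)
        rec1 = [r for r in herd.lactation_records if r.lactation_number == 1]
        truth = {(t["animal_id"], t["parity"]): t for t in herd.truth["records"]}
        fem = [r.milk_yield for r in rec1 if truth[(r.animal_id, 1)]["female_calf"]]
        mal = [r.milk_yield for r in rec1 if not truth[(r.animal_id, 1)]["female_calf"]]
        diff = np.mean(fem) - np.mean(mal)
        se = np.sqrt(np.var(fem) / len(fem) + np.var(mal) / len(mal))
        assert abs(diff) < 3 * se

    def test_gestation_offset_shortens_male_calf_lactations(self):
        cfg = SimulationConfig(n_herds=10, cows_per_herd=100, seed=6)
        herd = simulate_herd(cfg)
        truth = {(t["animal_id"], t["parity"]): t for t in herd.truth["records"]}
        lf, lm = [], []
        for r in herd.lactation_records:
            t = truth[(r.animal_id, r.lactation_number)]
            (lf if t["female_calf"] else lm).append(r.days_in_milk)
        gap = np.mean(lf) - np.mean(lm)
        assert gap == pytest.approx(2.0, abs=0.5)

    def test_every_recorded_animal_is_in_pedigree(self):
        cfg = SimulationConfig(n_herds=2, cows_per_herd=20, seed=7)
        herd = simulate_herd(cfg)
        ped_ids = {e.animal_id for e in herd.pedigree}
        assert {r.animal_id for r in herd.lactation_records} <= ped_ids

    def test_testday_series_match_s3_shape(self):
        cfg = SimulationConfig(n_herds=1, cows_per_herd=50, n_herd_tests=9, seed=8)
        herd = simulate_herd(cfg)
        assert len(herd.testday_series) == 50
        counts = [len(s.tests) for s in herd.testday_series]
        assert min(counts) >= 8 and max(counts) <= 10
        for s in herd.testday_series:
            dims = s.days_in_milk()
            assert all(d >= 1 for d in dims)
            assert dims == sorted(dims)
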