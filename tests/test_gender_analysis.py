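"""Cohort filters, sequence contrasts, letters and EBV comparison."""

import numpy as np
import pandas as pd
import pytest

from lactbias.io_formats import LactationRecord
from lactbias.gender_analysis import (
    apply_cohort_filters,
    compact_letter_display,
    compare_ebvs,
    estimate_sequence_effects,
    lactation_frame,
    model1_fixed_spec,
)
from lactbias.mixed_models import fit_model


def rec(animal, lact=1, dim=230, seq="MFF", milk=4000.0):
    return LactationRecord(animal, lact, milk, "HolsteinFriesian", seq, dim, "H1")


def calving_row(animal, parity, month=8, year=None, single=True, live=True,
                assisted=False, gender="F"):
    return {
        "animal_id": animal, "parity": parity, "month": month,
        "year": (1999 + parity) if year is None else year,
        "single": single, "live": live, "assisted": assisted,
        "calf_gender": gender,
    }


def full_calvings(animal, **kw):
    return [calving_row(animal, p, **kw) for p in (1, 2, 3)]


class TestCohortFilters:
    def test_short_lactation_removed_by_length_rule(self):
        recs = [rec("A", dim=99), rec("B", dim=100), rec("C", dim=305), rec("D", dim=306)]
        out, report = apply_cohort_filters(recs, None)
        assert {r.animal_id for r in out} == {"B", "C"}
        rule = next(s for s in report.steps if "length" in s["rule"])
        assert rule["removed"] == 2

    def test_out_of_season_calving_removed(self):
        calvings = pd.DataFrame(
            full_calvings("A")
            + [calving_row("B", 1, month=6), calving_row("B", 2), calving_row("B", 3)]
        )
        out, report = apply_cohort_filters([rec("A"), rec("B")], calvings)
        assert {r.animal_id for r in out} == {"A"}
        assert report.steps[0]["rule"].startswith("calvings in July")

    def test_non_consecutive_years_removed(self):
        calvings = pd.DataFrame(
            full_calvings("A")
            + [calving_row("B", 1, year=2000), calving_row("B", 2, year=2002),
               calving_row("B", 3, year=2003)]
        )
        out, _ = apply_cohort_filters([rec("A"), rec("B")], calvings)
        assert {r.animal_id for r in out} == {"A"}

    def test_assisted_birth_removed(self):
        calvings = pd.DataFrame(
            full_calvings("A") + full_calvings("B", assisted=True)
        )
        out, _ = apply_cohort_filters([rec("A"), rec("B")], calvings)
        assert {r.animal_id for r in out} == {"A"}

    def test_missing_gender_removed(self):
        calvings = pd.DataFrame(
            full_calvings("A")
            + [calving_row("B", 1), calving_row("B", 2, gender=""), calving_row("B", 3)]
        )
        out, _ = apply_cohort_filters([rec("A"), rec("B")], calvings)
        assert {r.animal_id for r in out} == {"A"}

    def test_counts_never_increase(self):
        recs = [rec(f"A{i}", dim=90 + 10 * i) for i in range(10)]
        _, report = apply_cohort_filters(recs, None)
        befores = [s["before"] for s in report.steps]
        afters = [s["after"] for s in report.steps]
        assert all(a <= b for a, b in zip(afters, befores))
        assert befores[1:] == afters[:-1]

    def test_missing_metadata_columns_error(self):
        with pytest.raises(ValueError, match="missing columns"):
            apply_cohort_filters([rec("A")], pd.DataFrame({"animal_id": ["A"]}))


def sequence_fixture(value_fn, n_per_level=6, noise=0.0, seed=0):
    """Balanced records over all 8 three-parity sequences with yield set by
    value_fn(sequence); fit the fixed-effects model (no pedigree needed)."""
    rng = np.random.default_rng(seed)
    seqs = [f"{a}{b}{c}" for a in "MF" for b in "MF" for c in "MF"]
    recs = []
    for s in seqs:
        for i in range(n_per_level):
            recs.append(
                rec(f"{s}{i}", seq=s, milk=value_fn(s) + rng.normal(0, noise))
            )
    df = lactation_frame(recs, lactation=1)
    return fit_model(df.drop(columns=["herd_year"]).assign(herd_year="H1"),
                     model1_fixed_spec())


class TestSequenceEffects:
    def test_equal_level_means_give_zero_effects(self):
        fit = sequence_fixture(lambda s: 4000.0)
        tab = estimate_sequence_effects(fit)
        assert np.allclose(tab.parity_effects["estimate"], 0.0, atol=1e-8)

    def test_count_of_females_gives_unit_effect_each_parity(self):
        # hand enumeration: level mean = number of F in the sequence makes the
        # F-vs-M contrast exactly 1.0 at every parity
        fit = sequence_fixture(lambda s: float(s.count("F")))
        tab = estimate_sequence_effects(fit)
        assert tab.parity_effects["estimate"].to_numpy() == pytest.approx(
            [1.0, 1.0, 1.0], abs=1e-8
        )
        assert list(tab.parity_effects["parity"]) == [1, 2, 3]

    def test_single_parity_effect_isolated(self):
        fit = sequence_fixture(lambda s: 30.0 if s[0] == "F" else 0.0)
        tab = estimate_sequence_effects(fit)
        assert tab.parity_effects["estimate"].to_numpy() == pytest.approx(
            [30.0, 0.0, 0.0], abs=1e-8
        )

    def test_letters_consistent_with_pairwise_tests(self):
        fit = sequence_fixture(
            lambda s: 3000.0 + 200.0 * s.count("F"), n_per_level=8, noise=40.0,
            seed=3,
        )
        tab = estimate_sequence_effects(fit)
        letters = dict(zip(tab.sequence_means["sequence"], tab.sequence_means["letters"]))
        from lactbias.mixed_models import contrast

        for a in letters:
            for b in letters:
                if a >= b:
                    continue
                res = contrast(fit, {("gender_sequence", a): 1.0,
                                     ("gender_sequence", b): -1.0})
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (res.p >= 0.05), (a, b, letters, res.p)


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        out = compact_letter_display(["a", "b", "c"], {})
        assert set(out.values()) == {"a"}

    def test_chain_structure(self):
        # x > y > z with only x vs z significant: x=a, y=ab, z=b
        sig = {("x", "z"): True, ("z", "x"): True}
        out = compact_letter_display(["x", "y", "z"], sig)
        assert not set(out["x"]) & set(out["z"])
        assert set(out["y"]) & set(out["x"])
        assert set(out["y"]) & set(out["z"])

    def test_all_different_distinct_letters(self):
        levels = ["p", "q", "r"]
        sig = {(a, b): True for a in levels for b in levels if a != b}
        out = compact_letter_display(levels, sig)
        assert len({out[lv] for lv in levels}) == 3


class TestCompareEBVs:
    def make_fit(self, ebvs: pd.Series):
        """Minimal stand-in fit carrying just what compare_ebvs reads."""
        from lactbias.mixed_models import MMEFit, MMESystem
        import scipy.sparse as sp

        system = MMESystem(
            WtW=sp.csc_matrix((1, 1)), Wty=np.zeros(1), yty=0.0, n=1, p=0,
            col_labels=[], blocks={}, structures={}, log_det_K={},
            animal_order=list(ebvs.index), pe_order=[], response="y",
            data_animals=list(ebvs.index),
        )
        return MMEFit(
            spec=None, system=system, solutions=np.zeros(1),
            fixed_solutions=pd.DataFrame(), random_solutions={"animal": ebvs},
            variance_components={}, log_likelihood=np.nan, converged=True,
        )

    def test_identical_rankings_perfect_agreement(self):
        e = pd.Series(np.arange(50.0), index=[f"C{i}" for i in range(50)])
        cmp = compare_ebvs(self.make_fit(e), self.make_fit(e.copy()), "dams", k=10)
        assert cmp.pearson_all == pytest.approx(1.0)
        assert cmp.spearman_all == pytest.approx(1.0)
        assert cmp.top_overlap == 10
        assert cmp.largest_rank_drop == 0

    def test_reversed_ranking_negative_spearman(self):
        e = pd.Series(np.arange(20.0), index=[f"C{i}" for i in range(20)])
        cmp = compare_ebvs(self.make_fit(-e), self.make_fit(e), "dams", k=5)
        assert cmp.spearman_all == pytest.approx(-1.0)

    def test_k_larger_than_group_rejected(self):
        e = pd.Series(np.arange(5.0), index=list("abcde"))
        with pytest.raises(ValueError, match="exceeds"):
            compare_ebvs(self.make_fit(e), self.make_fit(e), "dams", k=10)
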