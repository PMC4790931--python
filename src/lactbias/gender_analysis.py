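"""End-to-end calf-gender analysis: filters, contrasts, tables, EBV compare.

Ties the other modules together into the study's analyses:

* cohort filtering with an auditable per-rule report;
* per-parity calf-gender contrasts from the gender-sequence factor of an
  animal-model fit, with compact-letter-display groups over the sequence
  levels;
* the lactation-length-by-gender table (repeatability-model least-squares
  means) and the gender-specific yield-on-length slope table;
* the comparison of EBVs between models including and excluding the
  calf-gender terms (Pearson/Spearman, top-k overlap and re-ranking).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import LactationRecord, PedigreeEntry
from .mixed_models import ANIMAL, Covariate, MMEFit, ModelSpec, contrast

__all__ = [
    "FilterReport",
    "GenderEffectTable",
    "EBVComparison",
    "lactation_frame",
    "model1_spec",
    "model2_spec",
    "model3_spec",
    "model5_spec",
    "apply_cohort_filters",
    "estimate_sequence_effects",
    "compact_letter_display",
    "lactation_length_table",
    "gender_slope_table",
    "compare_ebvs",
]

SEQ_TERM = "gender_sequence"
GENDER_TERM = "calf_gender"
SLOPE_TERM = "days_in_milk:calf_gender"


# ---------------------------------------------------------------------------
# data preparation and model specs


def lactation_frame(
    records: list[LactationRecord],
    lactation: int | None = None,
    window_start: int = 1,
) -> pd.DataFrame:
    """Records as a model-ready DataFrame.

    Adds ``calf_gender`` — the gender of the calf whose birth initiated the
    record's lactation, read off the gender sequence.  ``window_start`` is
    the first parity the sequence covers (1 for sequences over parities 1-3
    or 1-4, 2 when the sequence spans parities 2-4 as in third-lactation
    analyses).
    """
    rows = []
    for r in records:
        if lactation is not None and r.lactation_number != lactation:
            continue
        pos = r.lactation_number - window_start
        if not (0 <= pos < len(r.gender_sequence)):
            raise ValueError(
                f"lactation {r.lactation_number} outside sequence window of "
                f"{r.animal_id} (window_start={window_start})"
            )
        rows.append(
            {
                "animal_id": r.animal_id,
                "lactation_number": r.lactation_number,
                "milk_yield": r.milk_yield,
                "breed": r.breed,
                "gender_sequence": r.gender_sequence,
                "days_in_milk": r.days_in_milk,
                "herd_year": r.herd_year,
                "calf_gender": r.gender_sequence[pos],
            }
        )
    return pd.DataFrame(rows)


def model1_spec(components: dict[str, float] | None = None) -> ModelSpec:
    """Yield on gender sequence + herd-year with a pedigree animal effect."""
    return ModelSpec(
        response="milk_yield",
        fixed_factors=[SEQ_TERM, "herd_year"],
        random_terms=[ANIMAL],
        variance_components=components,
    )


def model1_fixed_spec() -> ModelSpec:
    """The fixed-effects-only variant (no animal term)."""
    return ModelSpec(response="milk_yield", fixed_factors=[SEQ_TERM, "herd_year"])


def model2_spec(components: dict[str, float] | None = None) -> ModelSpec:
    """Lactation length on calf gender: repeatability model over parities."""
    return ModelSpec(
        response="days_in_milk",
        fixed_factors=[GENDER_TERM, "herd_year"],
        random_terms=[ANIMAL, "permanent_environment"],
        variance_components=components,
    )


def model3_spec(components: dict[str, float] | None = None) -> ModelSpec:
    """Model 1 plus gender-specific days-in-milk slopes."""
    return ModelSpec(
        response="milk_yield",
        fixed_factors=[SEQ_TERM, "herd_year"],
        covariates=[Covariate("days_in_milk", by=GENDER_TERM)],
        random_terms=[ANIMAL],
        variance_components=components,
    )


def model5_spec(components: dict[str, float] | None = None) -> ModelSpec:
    """Yield on days in milk + herd-year, no calf-gender terms."""
    return ModelSpec(
        response="milk_yield",
        fixed_factors=["herd_year"],
        covariates=[Covariate("days_in_milk")],
        random_terms=[ANIMAL],
        variance_components=components,
    )


# ---------------------------------------------------------------------------
# cohort filters


@dataclass
class FilterReport:
    """Per-rule record counts through the filter chain."""

    steps: list[dict] = field(default_factory=list)

    def add(self, rule: str, before: int, after: int) -> None:
        self.steps.append(
            {"rule": rule, "before": before, "after": after, "removed": before - after}
        )

    @property
    def final_count(self) -> int:
        return self.steps[-1]["after"] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def apply_cohort_filters(
    records: list[LactationRecord],
    calvings: pd.DataFrame | None,
    parity_window: int = 3,
) -> tuple[list[LactationRecord], FilterReport]:
    """Apply the cohort rules in order, logging counts after each.

    ``calvings`` carries one row per cow-parity with columns ``animal_id``,
    ``parity``, ``month`` (calving month 1-12), ``year``, ``single``,
    ``live``, ``assisted`` and ``calf_gender`` ('M'/'F', '' if unrecorded).
    Rules, in order: (1) the first three calvings fall in July-October;
    (2) in consecutive years; (3) each a single live calf born unassisted;
    (4) 100 <= lactation length <= 305 days; (5) calf gender recorded for
    every parity in the window.  With ``calvings=None`` the data are taken
    as pre-filtered and only the record-level rules (4, 5) are audited.
    """
    report = FilterReport()
    recs = list(records)

    if calvings is not None:
        required = {"animal_id", "parity", "month", "year",
                    "single", "live", "assisted", "calf_gender"}
        missing = required - set(calvings.columns)
        if missing:
            raise ValueError(f"calvings table missing columns: {sorted(missing)}")
        first3 = calvings[calvings["parity"].isin([1, 2, 3])]
        by_cow = first3.groupby("animal_id")

        def _cows_where(pred) -> set[str]:
            return {cow for cow, g in by_cow if len(g) == 3 and pred(g)}

        ok = _cows_where(lambda g: g["month"].between(7, 10).all())
        n0 = len(recs)
        recs = [r for r in recs if r.animal_id in ok]
        report.add("calvings in July-October", n0, len(recs))

        ok = _cows_where(
            lambda g: np.all(np.diff(g.sort_values("parity")["year"]) == 1)
        )
        n0 = len(recs)
        recs = [r for r in recs if r.animal_id in ok]
        report.add("consecutive calving years", n0, len(recs))

        ok = _cows_where(
            lambda g: (g["single"] & g["live"] & ~g["assisted"]).all()
        )
        n0 = len(recs)
        recs = [r for r in recs if r.animal_id in ok]
        report.add("single live unassisted calf", n0, len(recs))

    n0 = len(recs)
    recs = [r for r in recs if 100 <= r.days_in_milk <= 305]
    report.add("100 <= lactation length <= 305", n0, len(recs))

    n0 = len(recs)
    if calvings is not None:
        genders = {
            (row.animal_id, row.parity): row.calf_gender
            for row in calvings.itertuples()
        }
        window = range(1, parity_window + 1)
        recorded = {
            r.animal_id
            for r in recs
            if all(genders.get((r.animal_id, p)) in ("M", "F") for p in window)
        }
        recs = [r for r in recs if r.animal_id in recorded]
    else:
        recs = [
            r
            for r in recs
            if len(r.gender_sequence) == parity_window
            and set(r.gender_sequence) <= {"M", "F"}
        ]
    report.add(f"gender recorded for parities 1-{parity_window}", n0, len(recs))
    return recs, report


# ---------------------------------------------------------------------------
# sequence contrasts and letters


@dataclass
class GenderEffectTable:
    parity_effects: pd.DataFrame   # parity, estimate, se, t, p
    sequence_means: pd.DataFrame   # sequence, estimate, se, letters


def _sequence_levels(fit: MMEFit) -> list[str]:
    tab = fit.fixed_solutions
    return list(tab.loc[tab["term"] == SEQ_TERM, "level"])


def estimate_sequence_effects(
    fit: MMEFit,
    parity_window: int = 3,
    window_start: int = 1,
    alpha: float = 0.05,
    slope_parity: int | None = None,
    at_length: float | None = None,
) -> GenderEffectTable:
    """Per-parity female-minus-male contrasts and lettered sequence means.

    The parity-*p* effect is the unweighted mean of the sequence-level
    solutions with F in position *p* minus the mean of those with M there;
    its SE comes from the contrast quadratic form.  Letters are a compact
    letter display over all pairwise comparison-wise t-tests at ``alpha``.

    When the fit carries gender-specific days-in-milk slopes, the
    sequence-level contrast alone is the gender effect extrapolated to zero
    days in milk.  Pass ``slope_parity`` (the parity whose calf initiated
    the analysed lactation) and ``at_length`` (days) to report that
    parity's effect at a reference lactation length instead:
    ``contrast + at_length * (slope_F - slope_M)``.
    """
    levels = _sequence_levels(fit)
    if not levels:
        raise ValueError("fit has no gender_sequence factor")
    width = len(levels[0])
    half = 2 ** (width - 1)

    parity_rows = []
    for pos in range(width):
        fem = [lv for lv in levels if lv[pos] == "F"]
        mal = [lv for lv in levels if lv[pos] == "M"]
        if not fem or not mal:
            continue
        weights = {(SEQ_TERM, lv): 1.0 / len(fem) for lv in fem}
        weights.update({(SEQ_TERM, lv): -1.0 / len(mal) for lv in mal})
        if at_length is not None and window_start + pos == slope_parity:
            weights[(SLOPE_TERM, "F")] = float(at_length)
            weights[(SLOPE_TERM, "M")] = -float(at_length)
        res = contrast(fit, weights)
        parity_rows.append(
            {
                "parity": window_start + pos,
                "estimate": res.estimate,
                "se": res.se,
                "t": res.t,
                "p": res.p,
            }
        )

    tab = fit.fixed_solutions
    seq_tab = tab[tab["term"] == SEQ_TERM][["level", "estimate", "se"]].rename(
        columns={"level": "sequence"}
    )
    sig = {}
    for a, b in itertools.combinations(levels, 2):
        res = contrast(fit, {(SEQ_TERM, a): 1.0, (SEQ_TERM, b): -1.0})
        sig[(a, b)] = sig[(b, a)] = res.p < alpha
    order = list(seq_tab.sort_values("estimate", ascending=False)["sequence"])
    letters = compact_letter_display(order, sig)
    seq_tab = seq_tab.assign(letters=seq_tab["sequence"].map(letters))
    return GenderEffectTable(
        parity_effects=pd.DataFrame(parity_rows), sequence_means=seq_tab
    )


def compact_letter_display(
    ordered_levels: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two levels share a letter iff their pairwise test does NOT reject.
    ``ordered_levels`` fixes letter assignment order (best first);
    ``significant[(a, b)]`` is True when a and b differ significantly.
    """
    columns: list[set[str]] = [set(ordered_levels)]
    for a, b in itertools.combinations(ordered_levels, 2):
        if not significant.get((a, b), False):
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            col_a, col_b = col - {b}, col - {a}
            for new in (col_a, col_b):
                if not any(new <= other for other in columns):
                    columns.append(new)
    # absorb: drop any column contained in another
    columns = [
        c for c in columns if not any(c < other for other in columns)
    ]
    # order columns by the best-ranked member for stable lettering
    rank = {lv: i for i, lv in enumerate(ordered_levels)}
    columns.sort(key=lambda c: min(rank[x] for x in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in ordered_levels}
    for letter, col in zip(alphabet, columns):
        for lv in col:
            out[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in out.items()}


# ---------------------------------------------------------------------------
# lactation length and slope tables


def _ls_mean_weights(fit: MMEFit, gender: str) -> dict[tuple[str, str], float]:
    """Least-squares-mean contrast: the gender level plus the average
    herd-year effect (reference level contributes zero and is included in
    the average)."""
    tab = fit.fixed_solutions
    hy_levels = list(tab.loc[tab["term"] == "herd_year", "level"])
    n_hy = len(hy_levels) + 1  # + the zeroed reference level
    w = {("calf_gender", gender): 1.0}
    for lv in hy_levels:
        w[("herd_year", lv)] = 1.0 / n_hy
    return w


def lactation_length_table(fits: dict[tuple[str, int], MMEFit]) -> pd.DataFrame:
    """Gender least-squares means of lactation length per breed x lactation.

    ``fits`` maps (breed, lactation) to a repeatability-model fit on that
    breed's records (single fit across parities; key by lactation when fits
    are per-lactation).
    """
    rows = []
    for (breed, lact), fit in sorted(fits.items()):
        f = contrast(fit, _ls_mean_weights(fit, "F"))
        m = contrast(fit, _ls_mean_weights(fit, "M"))
        d = contrast(fit, {(GENDER_TERM, "F"): 1.0, (GENDER_TERM, "M"): -1.0})
        rows.append(
            {
                "breed": breed,
                "lactation": lact,
                "female_mean": f.estimate,
                "female_se": f.se,
                "male_mean": m.estimate,
                "male_se": m.se,
                "difference": d.estimate,
                "difference_se": d.se,
                "p": d.p,
            }
        )
    return pd.DataFrame(rows)


def gender_slope_table(fits: dict[tuple[str, int], MMEFit]) -> pd.DataFrame:
    """Female and male yield-on-length slopes and their difference."""
    rows = []
    for (breed, lact), fit in sorted(fits.items()):
        f = contrast(fit, {(SLOPE_TERM, "F"): 1.0})
        m = contrast(fit, {(SLOPE_TERM, "M"): 1.0})
        d = contrast(fit, {(SLOPE_TERM, "F"): 1.0, (SLOPE_TERM, "M"): -1.0})
        rows.append(
            {
                "breed": breed,
                "lactation": lact,
                "female_slope": f.estimate,
                "female_se": f.se,
                "male_slope": m.estimate,
                "male_se": m.se,
                "difference": d.estimate,
                "difference_se": d.se,
                "p": d.p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EBV comparison


@dataclass
class EBVComparison:
    group: str
    k: int
    pearson_all: float
    spearman_all: float
    pearson_top: float
    spearman_top: float
    top_overlap: int
    largest_rank_drop: int
    mean_top_with: float
    mean_top_without: float


def _group_animals(
    fit: MMEFit, group: str, pedigree: list[PedigreeEntry] | None
) -> list[str]:
    phenotyped = set(fit.system.data_animals)
    if group == "dams":
        return sorted(phenotyped)
    if group == "sires":
        if pedigree is None:
            raise ValueError("sire group needs the pedigree")
        sires = {
            e.sire_id
            for e in pedigree
            if e.animal_id in phenotyped and e.sire_id is not None
        }
        return sorted(sires)
    raise ValueError("group must be 'sires' or 'dams'")


def compare_ebvs(
    fit_with_gender: MMEFit,
    fit_without: MMEFit,
    group: str = "dams",
    k: int = 100,
    pedigree: list[PedigreeEntry] | None = None,
) -> EBVComparison:
    """Compare EBVs between the gender-including and gender-excluding fits.

    Correlations over the whole group and over the top-k of the
    gender-excluding model; top-k set overlap; the largest downward rank
    move among those top-k animals; and the mean top-k EBV under each model.
    """
    animals = _group_animals(fit_without, group, pedigree)
    if k > len(animals):
        raise ValueError(f"k={k} exceeds group size {len(animals)}")
    a = fit_with_gender.ebv().loc[animals]
    b = fit_without.ebv().loc[animals]
    pear_all = float(stats.pearsonr(a, b)[0])
    spear_all = float(stats.spearmanr(a, b)[0])
    top_without = list(b.sort_values(ascending=False).index[:k])
    top_with = set(a.sort_values(ascending=False).index[:k])
    at, bt = a.loc[top_without], b.loc[top_without]
    pear_top = float(stats.pearsonr(at, bt)[0]) if k > 1 else 1.0
    spear_top = float(stats.spearmanr(at, bt)[0]) if k > 1 else 1.0
    rank_with = pd.Series(
        np.arange(1, len(animals) + 1),
        index=a.sort_values(ascending=False).index,
    )
    rank_without = pd.Series(
        np.arange(1, len(animals) + 1),
        index=b.sort_values(ascending=False).index,
    )
    drops = [int(rank_with[x] - rank_without[x]) for x in top_without]
    return EBVComparison(
        group=group,
        k=k,
        pearson_all=pear_all,
        spearman_all=spear_all,
        pearson_top=pear_top,
        spearman_top=spear_top,
        top_overlap=len(top_with & set(top_without)),
        largest_rank_drop=max(drops) if drops else 0,
        mean_top_with=float(a.loc[list(top_with)].mean()) if top_with else np.nan,
        mean_top_without=float(bt.mean()),
    )
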