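"""Synthetic seasonal-calving herds with the structure the analyses assume.

The generator produces a multi-generation pedigree with additive breeding
values, and per cow-parity: a calf gender, a Spring calving date inside a
~44-day window (male calves arriving ~2 days later, mirroring their longer
gestation), a cow-specific Wood's lactation curve, a common herd dry-off
date, and daily yields sampled on common herd-test dates.  Whole-lactation
yield is recorded either as the exact day-by-day sum of the daily curve or —
the default, matching how national herd-testing schemes derive it — by
interval centering of the cow's own test-day records, which is what lets the
gestation-length artefact propagate into the phenotype file.

Animal-level effects (herd-year, breeding value, permanent environment, an
optional true calf-gender effect, and a lactation residual) are expressed in
whole-lactation litres and enter as a uniform level shift of daily yield
(``eta / L`` added to every day), so the exact lactation total is the curve
integral plus ``eta``.  By default each cow's curve is additionally centred
so her exact total equals the population-mean curve's total over her own
lactation plus ``eta``: curve shapes still differ between cows (so Wood's
fitting and the bias study see realistic dispersion) while total-yield
variance stays governed by the configured variance components — without
this, curve-parameter dispersion would silently inflate the phenotypic
variance and the realised heritability would fall below its configured
value.  Set ``curve_variation="raw"`` to disable.

Everything is driven by one :class:`numpy.random.Generator`; the same seed
reproduces the herd bit-for-bit.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    LactationRecord,
    PedigreeEntry,
    TestDaySeries,
    write_lactation_data,
    write_pedigree,
    write_testday_series,
)
from .pedigree import compute_inbreeding, topological_order, _indices

__all__ = ["SimulationConfig", "SimulatedPedigree", "SyntheticHerd",
           "simulate_pedigree", "simulate_lactations", "simulate_herd",
           "write_herd"]


@dataclass
class SimulationConfig:
    """Generating parameters of the synthetic herd.

    Defaults describe a pastoral Spring-calving herd: a 44-day calving
    spread, a 2-day later calving for dams of male calves, whole-herd
    dry-off 260 days after the season start, herd tests roughly monthly or
    sparser.  Yield variance components are on the whole-lactation litre
    scale: heritability 0.30 and permanent-environment fraction 0.15 around
    a residual variance of 120 000 L^2 give a phenotypic SD near 470 L.
    Wood's-curve parameter means (a = 15 L/d, b = 0.15, c = 0.004 /d) give a
    peak near 22 L/d around day 40 and a daily yield near 13.5 L/d at day
    235, typical of first-parity pasture-fed Holstein Friesians.
    """

    n_herds: int = 10
    cows_per_herd: int = 50
    n_generations: int = 3
    n_parities: int = 3
    heritability: float = 0.30
    pe_variance_fraction: float = 0.15
    residual_variance: float = 120_000.0
    herd_year_sd: float = 150.0
    calving_spread_days: int = 44
    gestation_offset_male_days: int = 2
    true_gender_effect_liters: float = 0.0
    calving_distribution: str = "uniform"   # or "front_loaded"
    calving_genetic_sd: float = 2.0         # days, additive, for calving date
    calving_pe_sd: float = 3.0              # days, permanent, for calving date
    woods_a_mean: float = 15.0
    woods_a_sd: float = 2.0
    woods_b_mean: float = 0.15
    woods_b_sd: float = 0.03
    woods_c_mean: float = 0.004
    woods_c_sd: float = 0.0008
    dry_off_day: int = 260                  # days after season start
    n_herd_tests: int = 6                   # 5-6 tests reach every cow
    first_test_day: int = 30                # days after season start
    yield_method: str = "interval"          # or "exact"
    curve_variation: str = "centered"       # or "raw"
    parity_window: int = 3                  # gender-sequence length recorded
    season_start_year: int = 2000
    breed: str = "HolsteinFriesian"
    seed: int = 20160314

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (0 <= self.heritability <= 1 and 0 <= self.pe_variance_fraction <= 1):
            raise ValueError("variance fractions must lie in [0, 1]")
        if self.heritability + self.pe_variance_fraction > 1:
            raise ValueError("heritability + PE fraction must be <= 1")
        if self.calving_spread_days < 0:
            raise ValueError("calving_spread_days must be >= 0")
        if self.dry_off_day <= self.calving_spread_days + self.gestation_offset_male_days:
            raise ValueError("herd would dry off before all calvings complete")
        if self.yield_method not in ("interval", "exact"):
            raise ValueError("yield_method must be 'interval' or 'exact'")
        if self.parity_window not in (3, 4):
            raise ValueError("parity_window must be 3 or 4")

    @property
    def additive_variance(self) -> float:
        e_frac = 1.0 - self.heritability - self.pe_variance_fraction
        if e_frac <= 0:
            raise ValueError("residual fraction must be positive")
        return self.residual_variance * self.heritability / e_frac

    @property
    def pe_variance(self) -> float:
        e_frac = 1.0 - self.heritability - self.pe_variance_fraction
        return self.residual_variance * self.pe_variance_fraction / e_frac


@dataclass
class SimulatedPedigree:
    entries: list[PedigreeEntry]
    breeding_values: dict[str, float]          # yield trait, litres
    calving_breeding_values: dict[str, float]  # calving-date trait, days
    cows: list[str]                            # phenotyped (final-generation) females
    inbreeding: dict[str, float]


@dataclass
class SyntheticHerd:
    config: SimulationConfig
    pedigree: list[PedigreeEntry]
    true_breeding_values: dict[str, float]
    lactation_records: list[LactationRecord]
    testday_series: list[TestDaySeries]
    truth: dict = field(default_factory=dict)


def _draw_bvs(
    entries: list[PedigreeEntry], sigma2_a: float, rng: np.random.Generator
) -> dict[str, float]:
    """Additive breeding values down a sorted pedigree.

    Founders ~ N(0, sigma2_a); offspring = parent average + Mendelian
    sampling with variance 0.5 sigma2_a (1 - mean parental inbreeding); an
    animal with one unknown parent gets 0.75 sigma2_a sampling variance.
    """
    order, sire, dam = _indices(entries)
    F = compute_inbreeding(sire, dam)
    bv = np.zeros(len(order))
    for i in range(len(order)):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            bv[i] = rng.normal(0.0, np.sqrt(sigma2_a))
            continue
        mean = 0.0
        ms_var = sigma2_a
        for p in (s, d):
            if p >= 0:
                mean += 0.5 * bv[p]
                ms_var -= 0.25 * sigma2_a * (1.0 + F[p])
        bv[i] = mean + rng.normal(0.0, np.sqrt(max(ms_var, 0.0)))
    return dict(zip(order, bv))


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedPedigree:
    """Multi-generation pedigree with true breeding values for two traits.

    The final generation holds the phenotyped cows (``n_herds *
    cows_per_herd`` females); earlier generations are smaller, with a
    limited sire team per generation as under artificial insemination.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_cows = config.n_herds * config.cows_per_herd
    entries: list[PedigreeEntry] = []
    prev_females: list[str] = []
    prev_sires: list[str] = []
    for g in range(config.n_generations):
        final = g == config.n_generations - 1
        n_f = n_cows if final else max(n_cows // 3, 40)
        n_s = max(n_cows // 100, 8)
        females = [f"G{g}F{i}" for i in range(n_f)]
        sires = [f"G{g}S{i}" for i in range(n_s)]
        for a in females + sires:
            if g == 0:
                entries.append(PedigreeEntry(a))
            else:
                entries.append(
                    PedigreeEntry(
                        a,
                        sire_id=prev_sires[rng.integers(len(prev_sires))],
                        dam_id=prev_females[rng.integers(len(prev_females))],
                    )
                )
        prev_females, prev_sires = females, sires
    entries = topological_order(entries)
    bv = _draw_bvs(entries, config.additive_variance, rng)
    bv_calving = _draw_bvs(entries, config.calving_genetic_sd**2, rng)
    order, sire, dam = _indices(entries)
    F = compute_inbreeding(sire, dam)
    return SimulatedPedigree(
        entries=entries,
        breeding_values=bv,
        calving_breeding_values=bv_calving,
        cows=prev_females,
        inbreeding=dict(zip(order, F)),
    )


def _calving_base(config: SimulationConfig, rng, size: int) -> np.ndarray:
    spread = config.calving_spread_days
    margin = config.gestation_offset_male_days
    width = max(spread - margin, 1)
    if config.calving_distribution == "front_loaded":
        return width * rng.beta(1.2, 2.5, size=size)
    return width * rng.uniform(0.0, 1.0, size=size)


def simulate_lactations(
    config: SimulationConfig,
    ped: SimulatedPedigree,
    rng: np.random.Generator | None = None,
) -> SyntheticHerd:
    """Generate lactation records and parity-1 test-day series for the cows."""
    rng = rng or np.random.default_rng(config.seed + 1)
    cows = ped.cows
    n = len(cows)
    herd_of = {c: i % config.n_herds for i, c in enumerate(cows)}

    # latent per-cow values
    a = np.maximum(rng.normal(config.woods_a_mean, config.woods_a_sd, n), 1.0)
    b = np.maximum(rng.normal(config.woods_b_mean, config.woods_b_sd, n), 0.01)
    c = np.maximum(rng.normal(config.woods_c_mean, config.woods_c_sd, n), 1e-4)
    pe = rng.normal(0.0, np.sqrt(config.pe_variance), n)
    pe_calving = rng.normal(0.0, config.calving_pe_sd, n)
    genders = rng.integers(0, 2, size=(n, 4))  # 1 = female, parities 1-4
    herd_year_effects = rng.normal(
        0.0, config.herd_year_sd, (config.n_herds, config.n_parities)
    )

    records: list[LactationRecord] = []
    series: list[TestDaySeries] = []
    truth_rows = []
    for i, cow in enumerate(cows):
        seq = "".join("F" if g else "M" for g in genders[i, : config.parity_window])
        for parity in range(1, config.n_parities + 1):
            female = bool(genders[i, parity - 1])
            season_start = _dt.date(
                config.season_start_year + parity - 1, 8, 1
            )
            base = _calving_base(config, rng, 1)[0]
            calving_day = int(
                round(
                    np.clip(
                        base
                        + ped.calving_breeding_values[cow]
                        + pe_calving[i]
                        + (0 if female else config.gestation_offset_male_days),
                        0,
                        config.calving_spread_days
                        + config.gestation_offset_male_days,
                    )
                )
            )
            L = config.dry_off_day - calving_day
            eta = (
                herd_year_effects[herd_of[cow], parity - 1]
                + ped.breeding_values[cow]
                + pe[i]
                + (config.true_gender_effect_liters if female else 0.0)
                + rng.normal(0.0, np.sqrt(config.residual_variance))
            )
            days = np.arange(1, L + 1)
            raw = a[i] * days**b[i] * np.exp(-c[i] * days)
            if config.curve_variation == "centered":
                # curve shape varies between cows but each cow's exact total
                # is the mean curve's total plus eta, so total-yield variance
                # is governed by the configured components
                ref = (
                    config.woods_a_mean
                    * days**config.woods_b_mean
                    * np.exp(-config.woods_c_mean * days)
                )
                shift = (float(ref.sum()) - float(raw.sum()) + eta) / L
            else:
                shift = eta / L
            daily = np.maximum(raw + shift, 0.0)
            exact_total = float(daily.sum())

            test_days_cal = np.round(
                np.linspace(
                    config.first_test_day,
                    config.dry_off_day - 5,
                    config.n_herd_tests,
                )
            ).astype(int)
            dim = test_days_cal - calving_day
            dim = dim[(dim >= 1) & (dim <= L)]
            test_yields = daily[dim - 1]

            if config.yield_method == "interval" and dim.size >= 4:
                from .lactation_yield import interval_centering_yield

                milk = interval_centering_yield(dim, test_yields, L)
            else:
                milk = exact_total
            records.append(
                LactationRecord(
                    animal_id=cow,
                    lactation_number=parity,
                    milk_yield=round(max(milk, 0.0), 3),
                    breed=config.breed,
                    gender_sequence=seq,
                    days_in_milk=L,
                    herd_year=f"H{herd_of[cow]}Y{season_start.year}",
                )
            )
            if parity == 1:
                series.append(
                    TestDaySeries(
                        animal_id=cow,
                        calving_date=season_start + _dt.timedelta(days=calving_day),
                        tests=[
                            (
                                season_start
                                + _dt.timedelta(days=int(d + calving_day)),
                                float(round(yv, 4)),
                            )
                            for d, yv in zip(dim, test_yields)
                        ],
                    )
                )
            truth_rows.append(
                {
                    "animal_id": cow,
                    "parity": parity,
                    "calving_day": calving_day,
                    "female_calf": female,
                    "lactation_length": L,
                    "eta": eta,
                    "exact_total": exact_total,
                    "woods": [float(a[i]), float(b[i]), float(c[i])],
                }
            )
    truth = {
        "config": asdict(config),
        "herd_year_effects": herd_year_effects.tolist(),
        "pe": dict(zip(cows, pe.tolist())),
        "records": truth_rows,
    }
    return SyntheticHerd(
        config=config,
        pedigree=ped.entries,
        true_breeding_values=ped.breeding_values,
        lactation_records=records,
        testday_series=series,
        truth=truth,
    )


def simulate_herd(config: SimulationConfig) -> SyntheticHerd:
    """Pedigree + lactations in one deterministic call."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    return simulate_lactations(config, ped, rng)


def write_herd(herd: SyntheticHerd, outdir: str | Path) -> dict[str, Path]:
    """Write s1/s2/s3 files plus a truth.json sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "s1": outdir / "s1_lactations.txt",
        "s2": outdir / "s2_pedigree.txt",
        "s3": outdir / "s3_testdays.txt",
        "truth": outdir / "truth.json",
    }
    write_lactation_data(herd.lactation_records, paths["s1"])
    write_pedigree(herd.pedigree, paths["s2"])
    write_testday_series(herd.testday_series, paths["s3"])
    with open(paths["truth"], "w") as fh:
        json.dump(herd.truth, fh, indent=1)
    return paths
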