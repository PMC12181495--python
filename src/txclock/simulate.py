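"""Synthetic bulk RNA-seq generator with known frequency-age trends.

Samples sit on a discrete age grid; each signal gene's relative frequency
follows a smooth monotone curve in age (logistic, exponential-saturating or
power-law shape, rising or falling), noise genes keep an age-constant
frequency, and one "rest-of-transcriptome" filler gene absorbs the
remaining frequency mass so per-gene frequencies sum to 1 at every age.
Counts are then drawn independently per sample as Poisson(frequency x
library size), the same count model the clock assumes, so parameter
recovery on this data tests the estimator rather than model
misspecification.  An optional gamma-mixed (overdispersed) mode is included
but off by default.

Signal genes come in up/down pairs sharing shape and amplitude, keeping the
aggregate signal mass age-invariant: the filler gene then carries no age
trend, as the bulk of a real transcriptome does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .io import AgeAnnotation, CountMatrix

__all__ = [
    "GeneTrend",
    "SyntheticSpec",
    "trend_frequency",
    "build_trends",
    "simulate_counts",
    "make_regression_fixture",
    "FIXTURE_SPEC",
]

FILLER_GENE = "rest_of_transcriptome"
_FAMILIES = ("logistic", "expsat", "power")


@dataclass
class GeneTrend:
    """Parameters of one gene's frequency-vs-age curve.

    ``base`` is the frequency at the low end of the trend, ``amplitude``
    the total rise (or fall, for ``sign=-1``) across the age range.
    ``rate``/``midpoint`` shape the curve; for the power family ``rate`` is
    the exponent.  ``family="constant"`` marks a noise gene.
    """

    gene_id: str
    family: str
    sign: int
    base: float
    amplitude: float
    rate: float = 1.0
    midpoint: float = 14.0


def trend_frequency(trend: GeneTrend, age, age_min: float,
                    age_max: float) -> np.ndarray:
    """Evaluate a gene's frequency curve at one or more ages.

    The raw family curve is min-max normalized over ``[age_min, age_max]``
    so the frequency runs exactly from ``base`` to ``base + amplitude``
    (reversed for falling genes), making every signal gene's range
    comparable regardless of shape parameters.
    """
    a = np.asarray(age, dtype=float)
    if (a < age_min - 1e-9).any() or (a > age_max + 1e-9).any():
        raise ValueError("age outside the grid range")
    if trend.family == "constant":
        return np.broadcast_to(trend.base, a.shape).copy()
    if trend.family == "logistic":
        g = lambda t: 1.0 / (1.0 + np.exp(-trend.rate * (t - trend.midpoint)))
    elif trend.family == "expsat":
        g = lambda t: 1.0 - np.exp(-trend.rate * (t - age_min))
    elif trend.family == "power":
        g = lambda t: ((t - age_min) / (age_max - age_min)) ** trend.rate
    else:
        raise ValueError(f"unknown trend family {trend.family!r}")
    lo, hi = g(np.array(age_min)), g(np.array(age_max))
    h = (g(a) - lo) / (hi - lo)
    if trend.sign < 0:
        h = 1.0 - h
    return trend.base + trend.amplitude * h


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic dataset.

    Defaults describe the standard recovery setting: 30 strongly trending
    signal genes and 20 age-invariant noise genes over the 10 sampled ages
    1-27 months, 4 replicates per age, mean library size 1e5.  The seed
    fully determines the output.
    """

    n_signal_genes: int = 30
    n_noise_genes: int = 20
    age_grid: tuple = (1, 3, 6, 9, 12, 15, 18, 21, 24, 27)
    samples_per_age: int = 4
    library_size: float = 1e5
    signal_base_range: tuple = (1e-4, 3e-4)
    signal_amp_range: tuple = (3e-4, 9e-4)
    noise_freq_range: tuple = (1e-4, 5e-4)
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(a) for a in self.age_grid)
        if len(grid) < 2 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("age_grid must be strictly increasing, length >= 2")
        self.age_grid = grid
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.samples_per_age < 1:
            raise ValueError("samples_per_age must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown spec keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def build_trends(spec: SyntheticSpec) -> list[GeneTrend]:
    """Draw the per-gene trend parameters (deterministic in the seed)."""
    rng = np.random.default_rng([spec.seed, 0])
    trends: list[GeneTrend] = []
    n_pairs, odd = divmod(spec.n_signal_genes, 2)
    for p in range(n_pairs):
        family = _FAMILIES[p % len(_FAMILIES)]
        amp = rng.uniform(*spec.signal_amp_range)
        rate = {"logistic": rng.uniform(0.15, 0.4),
                "expsat": rng.uniform(0.05, 0.2),
                "power": rng.uniform(0.5, 2.5)}[family]
        mid = rng.uniform(8.0, 20.0)
        for sign, tag in ((1, "up"), (-1, "dn")):
            base = rng.uniform(*spec.signal_base_range)
            trends.append(GeneTrend(f"sig{p:03d}_{tag}", family, sign,
                                    base, amp, rate, mid))
    if odd:
        trends.append(GeneTrend(f"sig{n_pairs:03d}_odd", "logistic", 1,
                                rng.uniform(*spec.signal_base_range),
                                rng.uniform(*spec.signal_amp_range),
                                rng.uniform(0.15, 0.4),
                                rng.uniform(8.0, 20.0)))
    for j in range(spec.n_noise_genes):
        trends.append(GeneTrend(f"noise{j:03d}", "constant", 1,
                                rng.uniform(*spec.noise_freq_range), 0.0))
    return trends


def _frequency_table(spec: SyntheticSpec) -> pd.DataFrame:
    trends = build_trends(spec)
    grid = np.asarray(spec.age_grid)
    rows = {t.gene_id: trend_frequency(t, grid, grid[0], grid[-1])
            for t in trends}
    table = pd.DataFrame(rows, index=grid).T
    totals = table.sum(axis=0)
    if (totals >= 1.0).any():
        raise ValueError(
            f"gene frequencies sum to >= 1 (max {totals.max():.4f}); "
            "reduce gene counts or frequency ranges")
    table.loc[FILLER_GENE] = 1.0 - totals
    return table


def simulate_counts(spec: SyntheticSpec
                    ) -> tuple[CountMatrix, AgeAnnotation, pd.DataFrame]:
    """Draw a synthetic dataset.

    Returns the count matrix (genes x samples, filler gene included), the
    age annotation, and the true frequency table (genes x grid ages) the
    counts were generated from.
    """
    truth = _frequency_table(spec)
    grid = np.asarray(spec.age_grid)
    sample_ids, sample_ages = [], []
    for age in grid:
        for r in range(spec.samples_per_age):
            sample_ids.append(f"s{len(sample_ids):03d}_a{age:g}")
            sample_ages.append(float(age))
    age_col = {a: j for j, a in enumerate(grid)}
    lam = np.column_stack([truth.to_numpy()[:, age_col[a]]
                           for a in sample_ages]) * spec.library_size
    rng = np.random.default_rng([spec.seed, 1])
    if spec.dispersion > 0:
        lam = lam * rng.gamma(1.0 / spec.dispersion, spec.dispersion,
                              size=lam.shape)
    counts = rng.poisson(lam)
    cm = CountMatrix(list(truth.index), sample_ids, counts)
    ann = AgeAnnotation(dict(zip(sample_ids, sample_ages)))
    return cm, ann, truth


FIXTURE_SPEC = SyntheticSpec(seed=917_301)
"""Frozen spec behind :func:`make_regression_fixture`."""


def make_regression_fixture() -> tuple[CountMatrix, AgeAnnotation, pd.DataFrame]:
    """The deterministic end-to-end test fixture (30+20 genes, 10x4 samples)."""
    return simulate_counts(FIXTURE_SPEC)
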