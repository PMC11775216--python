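"""Synthetic score panels with a planted two-block specialization structure.

Every downstream stage of the pipeline — specialization, sustainability
indices, relatedness networks, trajectories, stages — is tested against a
ground truth that only a generator can supply. The generator plants the
polarized structure observed in real score panels: one group of countries
sits at a higher overall score level and over-performs (relative to its own
level) on one block of indicators, while the other group over-performs on
the complementary block. Under the centered Balassa index this yields an
exactly block-structured binary advantage matrix when noise is zero, so
partition recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import ScorePanel

FIRST_YEAR = 2000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block panel generator.

    All score-like quantities are in points on the 0-100 scale.

    Attributes
    ----------
    n_countries, n_indicators:
        Panel dimensions (each >= 4 so both blocks are non-empty).
    country_split, indicator_split:
        Fraction of countries / indicators assigned to block A.
    base_level_low, base_level_high:
        Mean score of the low- and high-scoring country block.
    boost:
        Additive within-block specialization increment: block-A countries
        get ``base_level_high + boost`` on block-A indicators, block-B
        countries get ``base_level_low + boost`` on block-B indicators.
    noise_sd:
        Standard deviation of i.i.d. Gaussian noise added per cell; the
        result is clipped to [0, 100].
    n_years, year_drift:
        Number of consecutive years starting at 2000, and the common
        per-year upward shift of all means (points per year).
    seed:
        Seed of the single NumPy generator stream driving all noise.
    """

    n_countries: int = 166
    n_indicators: int = 96
    country_split: float = 0.5
    indicator_split: float = 0.5
    base_level_low: float = 55.0
    base_level_high: float = 72.0
    boost: float = 8.0
    noise_sd: float = 3.0
    n_years: int = 1
    year_drift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 4 or self.n_indicators < 4:
            raise DegenerateInputError("need at least 4 countries and 4 indicators")
        if not (0.0 < self.country_split < 1.0 and 0.0 < self.indicator_split < 1.0):
            raise DegenerateInputError("splits must lie strictly in (0, 1)")
        if self.n_years < 1:
            raise DegenerateInputError("n_years must be >= 1")
        if self.noise_sd < 0 or self.boost < 0 or self.year_drift < 0:
            raise DegenerateInputError("noise_sd, boost and year_drift must be >= 0")
        for lvl in (self.base_level_low, self.base_level_high):
            if not 0.0 <= lvl <= 100.0:
                raise DegenerateInputError("base levels must lie in [0, 100]")
        n_ca = round(self.n_countries * self.country_split)
        n_ia = round(self.n_indicators * self.indicator_split)
        if n_ca in (0, self.n_countries) or n_ia in (0, self.n_indicators):
            raise DegenerateInputError("a block would be empty after rounding")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth block labels planted by :func:`generate_panel`."""

    country_block: dict[str, str]    # country -> "A" | "B"
    indicator_block: dict[str, str]  # indicator -> "A" | "B"

    def country_labels(self, order) -> list[str]:
        return [self.country_block[c] for c in order]

    def indicator_labels(self, order) -> list[str]:
        return [self.indicator_block[i] for i in order]


def default_study_shape(**overrides) -> SyntheticSpec:
    """Spec emulating the shape of the reference panel: 166 countries x
    96 indicators over the 23 years 2000-2022."""
    return replace(SyntheticSpec(n_countries=166, n_indicators=96, n_years=23),
                   **overrides)


def _mean_matrix(spec: SyntheticSpec, n_ca: int, n_ia: int) -> np.ndarray:
    """Closed-form per-cell mean before drift, noise and clipping."""
    mu = np.empty((spec.n_countries, spec.n_indicators))
    mu[:n_ca, :] = spec.base_level_high
    mu[n_ca:, :] = spec.base_level_low
    mu[:n_ca, :n_ia] += spec.boost
    mu[n_ca:, n_ia:] += spec.boost
    return mu


def expected_cell_means(spec: SyntheticSpec, year: int = FIRST_YEAR) -> pd.DataFrame:
    """Pre-clipping expectation of every cell for one year (labelled)."""
    n_ca = round(spec.n_countries * spec.country_split)
    n_ia = round(spec.n_indicators * spec.indicator_split)
    mu = _mean_matrix(spec, n_ca, n_ia) + (year - FIRST_YEAR) * spec.year_drift
    return pd.DataFrame(mu, index=_country_names(spec.n_countries),
                        columns=_indicator_names(spec.n_indicators))


def _country_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"C{idx:0{width}d}" for idx in range(n)]


def _indicator_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"I{idx:0{width}d}" for idx in range(n)]


def generate_panel(spec: SyntheticSpec) -> tuple[ScorePanel, PlantedTruth]:
    """Generate a score panel with the planted two-block structure.

    Deterministic: the same spec (including seed) always yields the same
    panel. Scores are Gaussian around the block means, shifted upward by
    ``year_drift`` per year, and clipped to [0, 100].
    """
    n_ca = round(spec.n_countries * spec.country_split)
    n_ia = round(spec.n_indicators * spec.indicator_split)
    countries = _country_names(spec.n_countries)
    indicators = _indicator_names(spec.n_indicators)
    truth = PlantedTruth(
        country_block={c: ("A" if k < n_ca else "B")
                       for k, c in enumerate(countries)},
        indicator_block={i: ("A" if k < n_ia else "B")
                         for k, i in enumerate(indicators)},
    )
    rng = np.random.default_rng(spec.seed)
    mu = _mean_matrix(spec, n_ca, n_ia)
    frames = []
    for t in range(spec.n_years):
        year = FIRST_YEAR + t
        scores = mu + t * spec.year_drift
        if spec.noise_sd > 0:
            scores = scores + rng.normal(0.0, spec.noise_sd, size=mu.shape)
        scores = np.clip(scores, 0.0, 100.0)
        frame = pd.DataFrame(scores, index=countries, columns=indicators)
        long = frame.stack().rename("score").reset_index()
        long.columns = ["country", "indicator", "score"]
        long["year"] = year
        frames.append(long[["country", "year", "indicator", "score"]])
    panel = ScorePanel(pd.concat(frames, ignore_index=True))
    return panel, truth
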