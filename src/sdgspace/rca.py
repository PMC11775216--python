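"""Revealed comparative advantage (centered Balassa index) and its binarization.

For a complete country x indicator score matrix, the uncentered index is
the ratio of two shares::

    RCA'[c, i] = (Score[c, i] / sum_i Score[c, i])
                 / (sum_c Score[c, i] / sum_{c,i} Score[c, i])

and the centered index is ``RCA = RCA' - 1``, so RCA > 0 means country ``c``
devotes a larger share of its total score to indicator ``i`` than the world
does — it is *specialized* in ``i``. The binary advantage matrix M applies
the strict threshold M = 1 iff RCA > 0; its row sums are a country's
*diversity* (how many indicators it specializes in) and its column sums an
indicator's *ubiquity* (how many countries specialize in it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import ScoreMatrix


@dataclass(frozen=True)
class SpecializationMatrix:
    """Centered RCA values for one year.

    ``rca`` is countries x indicators with 0 meaning world-average share;
    ``rca_ratio = rca + 1`` is the raw Balassa ratio (>= 0). For every
    country the world-share-weighted mean of ``rca_ratio`` is exactly 1
    (share conservation).
    """

    year: int
    rca: pd.DataFrame

    @property
    def rca_ratio(self) -> pd.DataFrame:
        return self.rca + 1.0

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.rca.index)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.rca.columns)


@dataclass(frozen=True)
class BinaryAdvantageMatrix:
    """Binarized specialization M with entries in {0, 1}."""

    m: pd.DataFrame

    @property
    def diversity(self) -> pd.Series:
        """Per-country count of specialized indicators (row sums)."""
        return self.m.sum(axis=1)

    @property
    def ubiquity(self) -> pd.Series:
        """Per-indicator count of specialized countries (column sums)."""
        return self.m.sum(axis=0)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.m.index)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.m.columns)


def compute_rca(matrix: ScoreMatrix) -> SpecializationMatrix:
    """Centered Balassa index of every (country, indicator) cell.

    Raises :class:`DegenerateInputError` naming the offending entity if a
    country row or indicator column sums to zero (shares undefined).
    """
    values = matrix.values.to_numpy(dtype=float)
    row_tot = values.sum(axis=1)
    col_tot = values.sum(axis=0)
    if (row_tot <= 0).any():
        bad = matrix.values.index[int(np.argmax(row_tot <= 0))]
        raise DegenerateInputError(f"country {bad!r} has zero total score")
    if (col_tot <= 0).any():
        bad = matrix.values.columns[int(np.argmax(col_tot <= 0))]
        raise DegenerateInputError(f"indicator {bad!r} has zero total score")
    world_share = col_tot / col_tot.sum()
    ratio = (values / row_tot[:, None]) / world_share[None, :]
    rca = pd.DataFrame(ratio - 1.0, index=matrix.values.index,
                       columns=matrix.values.columns)
    return SpecializationMatrix(year=matrix.year, rca=rca)


def binarize_advantage(spec: SpecializationMatrix) -> BinaryAdvantageMatrix:
    """Strict binarization: M = 1 iff RCA > 0 (a tie at exactly 0 is 0)."""
    m = (spec.rca > 0).astype(int)
    return BinaryAdvantageMatrix(m=m)


def region_rca(matrix: ScoreMatrix,
               membership: Mapping[str, str]) -> SpecializationMatrix:
    """Centered Balassa index over regions instead of countries.

    Each region's score on an indicator is the unweighted mean of its
    member countries' scores; the index is then computed on the resulting
    region x indicator matrix. Requires at least two non-empty regions and
    a region for every country in ``matrix``.
    """
    missing = [c for c in matrix.countries if c not in membership]
    if missing:
        raise DegenerateInputError(
            f"countries without region membership: {missing[:5]}")
    groups = pd.Series({c: membership[c] for c in matrix.countries},
                       name="region")
    regions = sorted(set(groups))
    if len(regions) < 2:
        raise DegenerateInputError("need at least 2 regions")
    means = matrix.values.groupby(groups).mean()
    if (means.index.value_counts() == 0).any():  # pragma: no cover
        raise DegenerateInputError("empty region")
    region_matrix = ScoreMatrix(year=matrix.year, values=means.sort_index())
    return compute_rca(region_matrix)
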