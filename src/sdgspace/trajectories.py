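"""Moving-window trajectories of specialization along the score gradient.

Countries are sorted from lowest to highest aggregate score and grouped
into overlapping rank-contiguous windows (default width 50, stride 1, so
166 countries yield 117 windows). For each window and indicator the mean
centered RCA and mean absolute score are recorded; plotting these against
the window index exposes how specialization shifts as overall performance
rises. Indicator-group curves and their crossing points summarize the
divergence of the high- and low-index indicator clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import ScoreMatrix
from .rca import SpecializationMatrix

DEFAULT_WINDOW = 50


@dataclass(frozen=True)
class CountryRanking:
    """Countries ordered from lowest to highest aggregate score.

    Ties are broken lexicographically by country identifier so the order
    is total and reproducible.
    """

    order: tuple[str, ...]
    aggregate: pd.Series
    source: str  # "mean_of_indicators" | "external_index"

    def __len__(self) -> int:
        return len(self.order)

    def position(self, country: str) -> int:
        """1-based rank (1 = lowest aggregate score)."""
        return self.order.index(country) + 1


@dataclass(frozen=True)
class TrajectoryTable:
    """Per-window, per-indicator mean RCA and mean absolute score.

    ``mean_rca`` and ``mean_score`` are windows x indicators frames whose
    integer index 1..(N - w + 1) is the window number; window ``j`` holds
    ranking positions ``j .. j+w-1``.
    """

    window_size: int
    members: tuple[tuple[str, ...], ...]
    mean_rca: pd.DataFrame
    mean_score: pd.DataFrame

    @property
    def n_windows(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        """Long export: window_index, indicator, mean_rca, mean_score."""
        rca = self.mean_rca.stack().rename("mean_rca")
        score = self.mean_score.stack().rename("mean_score")
        out = pd.concat([rca, score], axis=1).reset_index()
        out.columns = ["window_index", "indicator", "mean_rca", "mean_score"]
        return out


def rank_countries(matrix: ScoreMatrix,
                   external_scores: Mapping[str, float] | None = None
                   ) -> CountryRanking:
    """Rank countries ascending by aggregate score.

    The aggregate defaults to the unweighted mean over indicators; an
    official composite index can be supplied through ``external_scores``
    (which must then cover every country).
    """
    if external_scores is not None:
        missing = [c for c in matrix.countries if c not in external_scores]
        if missing:
            raise DegenerateInputError(
                f"external scores missing for countries: {missing[:5]}")
        aggregate = pd.Series({c: float(external_scores[c])
                               for c in matrix.countries})
        source = "external_index"
    else:
        aggregate = matrix.values.mean(axis=1)
        source = "mean_of_indicators"
    # lexsort keys: secondary = label (tie-break), primary = aggregate value.
    order = tuple(aggregate.index[np.lexsort(
        (np.array(aggregate.index, dtype=object), aggregate.to_numpy()))])
    return CountryRanking(order=order, aggregate=aggregate, source=source)


def moving_window_means(spec: SpecializationMatrix, scores: ScoreMatrix,
                        ranking: CountryRanking,
                        w: int = DEFAULT_WINDOW) -> TrajectoryTable:
    """Mean RCA and mean absolute score per window of ``w`` consecutive
    ranks (stride 1), giving N - w + 1 windows."""
    n = len(ranking)
    if not 2 <= w <= n:
        raise DegenerateInputError(
            f"window size {w} invalid for {n} ranked countries")
    rca = spec.rca.loc[list(ranking.order)]
    sco = scores.values.loc[list(ranking.order), spec.rca.columns]
    members = tuple(tuple(ranking.order[j:j + w]) for j in range(n - w + 1))
    idx = pd.RangeIndex(1, n - w + 2, name="window_index")
    roll_rca = rca.rolling(w).mean().iloc[w - 1:].set_axis(idx)
    roll_sco = sco.rolling(w).mean().iloc[w - 1:].set_axis(idx)
    return TrajectoryTable(window_size=w, members=members,
                           mean_rca=roll_rca, mean_score=roll_sco)


def group_trajectories(traj: TrajectoryTable,
                       groups: Mapping[str, object],
                       value: str = "mean_rca") -> pd.DataFrame:
    """Unweighted mean curve per indicator group (windows x groups).

    ``groups`` must cover every indicator of the trajectory table; an
    empty group is an error.
    """
    frame = getattr(traj, value)
    missing = [i for i in frame.columns if i not in groups]
    if missing:
        raise DegenerateInputError(f"indicators without group: {missing[:5]}")
    assignment = pd.Series({i: groups[i] for i in frame.columns})
    curves = frame.T.groupby(assignment).mean().T
    if curves.isna().any().any():  # pragma: no cover
        raise DegenerateInputError("empty indicator group")
    return curves


def find_crossings(curve_a: Sequence[float],
                   curve_b: Sequence[float]) -> list[int]:
    """Window indices where two curves cross.

    A crossing is a strict sign change of (A - B) between consecutive
    windows, reported as the right-hand (1-based) window index; touching
    zero without changing sign is not a crossing.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateInputError("curves must have equal length")
    diff = a - b
    sign = np.sign(diff)
    crossings = []
    prev = 0.0
    for j in range(len(sign)):
        s = sign[j]
        if s == 0.0:
            continue
        if prev != 0.0 and s != prev:
            crossings.append(j + 1)
        prev = s
    return crossings
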