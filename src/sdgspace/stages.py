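"""Development stages, stage-to-stage specialization shifts, orphaned
indicators, GSI grouping and the four-area indicator classification.

Countries are divided into contiguous rank blocks (quartiles by default:
Stage 1 "Primary" holds the lowest aggregate scores, Stage 4 "Advanced"
the highest). Per-stage mean RCA profiles and their consecutive
differences show which indicators a country group gains or loses
specialization in as it advances; indicators that are *lost into
non-positive territory* on the way up, and that sit in the low-GSI side
of the indicator structure, are flagged as orphaned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import IndicatorCatalog
from .rca import SpecializationMatrix
from .trajectories import CountryRanking

STAGE_NAMES = {1: "Primary", 2: "Low medium", 3: "High medium", 4: "Advanced"}

#: GSI cut points shared by the environment (groups 1-3) and
#: non-environment (groups 4-6) indicator families.
GSI_HIGH_CUT = 0.5
GSI_LOW_CUT = -1.0


@dataclass(frozen=True)
class StageAssignment:
    """Mapping country -> stage 1..n_stages (1 = lowest scores)."""

    n_stages: int
    stage_of: dict[str, int]
    sizes: tuple[int, ...]

    def members(self, stage: int) -> list[str]:
        return sorted(c for c, s in self.stage_of.items() if s == stage)


@dataclass(frozen=True)
class StageSummary:
    """Per-stage mean RCA, consecutive-stage deltas and top/bottom lists.

    ``mean_rca`` is stages x indicators; ``deltas`` has one row per
    consecutive stage pair labelled ``"s->s+1"`` and equals exactly
    ``mean_rca[s+1] - mean_rca[s]``.
    """

    mean_rca: pd.DataFrame
    deltas: pd.DataFrame
    top: dict[int, list[str]]
    bottom: dict[int, list[str]]
    k: int


def _stage_sizes(n: int, n_stages: int) -> list[int]:
    """Near-equal contiguous block sizes, remainder to the outermost
    stages first (166 countries in 4 stages -> 42, 41, 41, 42)."""
    base, rem = divmod(n, n_stages)
    sizes = [base] * n_stages
    # Stages ordered by distance from the center, outermost first; ties
    # resolved toward the lower stage.
    center = (n_stages + 1) / 2.0
    order = sorted(range(1, n_stages + 1),
                   key=lambda s: (-abs(s - center), s))
    for s in order[:rem]:
        sizes[s - 1] += 1
    return sizes


def assign_stages(ranking: CountryRanking, n_stages: int = 4) -> StageAssignment:
    """Partition the ranking into ``n_stages`` contiguous blocks of
    near-equal size (lowest aggregate scores in Stage 1)."""
    if n_stages < 2:
        raise DegenerateInputError("need at least 2 stages")
    n = len(ranking)
    if n < n_stages:
        raise DegenerateInputError(
            f"cannot split {n} countries into {n_stages} stages")
    sizes = _stage_sizes(n, n_stages)
    stage_of: dict[str, int] = {}
    pos = 0
    for stage, size in enumerate(sizes, start=1):
        for country in ranking.order[pos:pos + size]:
            stage_of[country] = stage
        pos += size
    return StageAssignment(n_stages=n_stages, stage_of=stage_of,
                           sizes=tuple(sizes))


def split_stage_halves(stages: StageAssignment, ranking: CountryRanking,
                       stage: int) -> StageAssignment:
    """Split one stage into a lower and an upper half (by rank), shifting
    later stages up by one. Supports the finer advanced-stage analysis
    where the top quartile is halved to see near-future transitions."""
    if stage not in range(1, stages.n_stages + 1):
        raise DegenerateInputError(f"no stage {stage}")
    members = [c for c in ranking.order if stages.stage_of[c] == stage]
    if len(members) < 2:
        raise DegenerateInputError(f"stage {stage} too small to split")
    half = len(members) // 2
    lower = set(members[:half])
    stage_of = {}
    for c, s in stages.stage_of.items():
        if s < stage:
            stage_of[c] = s
        elif s == stage:
            stage_of[c] = stage if c in lower else stage + 1
        else:
            stage_of[c] = s + 1
    sizes = []
    for s in range(1, stages.n_stages + 2):
        sizes.append(sum(1 for v in stage_of.values() if v == s))
    return StageAssignment(n_stages=stages.n_stages + 1, stage_of=stage_of,
                           sizes=tuple(sizes))


def stage_summary(spec: SpecializationMatrix, stages: StageAssignment,
                  k: int = 20) -> StageSummary:
    """Per-stage unweighted mean RCA profile, consecutive deltas, and the
    top-k / bottom-k indicator lists per stage (ties broken
    lexicographically by indicator code)."""
    if k > len(spec.indicators):
        raise DegenerateInputError(
            f"k={k} exceeds indicator count {len(spec.indicators)}")
    assignment = pd.Series({c: stages.stage_of[c] for c in spec.countries})
    if assignment.isna().any():
        raise DegenerateInputError("countries without stage assignment")
    mean_rca = spec.rca.groupby(assignment).mean()
    mean_rca.index.name = "stage"
    deltas = mean_rca.diff().iloc[1:]
    deltas.index = [f"{s - 1}->{s}" for s in deltas.index]
    top: dict[int, list[str]] = {}
    bottom: dict[int, list[str]] = {}
    for stage in mean_rca.index:
        row = mean_rca.loc[stage]
        by_desc = sorted(row.index, key=lambda i: (-row[i], i))
        by_asc = sorted(row.index, key=lambda i: (row[i], i))
        top[int(stage)] = by_desc[:k]
        bottom[int(stage)] = by_asc[:k]
    return StageSummary(mean_rca=mean_rca, deltas=deltas, top=top,
                        bottom=bottom, k=k)


def identify_orphaned(summary: StageSummary, gsi: Mapping[str, float],
                      low_gsi_community: set[str] | None = None
                      ) -> pd.DataFrame:
    """Flag indicators a rising country group abandons.

    An indicator is flagged at transition s -> s+1 when its mean RCA falls
    (delta < 0) *into* non-positive territory (mean at s+1 <= 0). The
    overall ``orphaned`` verdict requires the flag at the final transition
    plus membership in the low-GSI side — by default ``gsi < 0``, or an
    explicit community set when the space partition is available.

    Returns one row per indicator with per-transition flag columns, its
    GSI and the overall verdict.
    """
    indicators = list(summary.mean_rca.columns)
    missing = [i for i in indicators if i not in gsi]
    if missing:
        raise DegenerateInputError(f"gsi missing for indicators: {missing[:5]}")
    rows = []
    transitions = list(summary.deltas.index)
    stage_ids = list(summary.mean_rca.index)
    for ind in indicators:
        flags = {}
        for t_idx, trans in enumerate(transitions):
            into_stage = stage_ids[t_idx + 1]
            falling = summary.deltas.loc[trans, ind] < 0
            nonpos = summary.mean_rca.loc[into_stage, ind] <= 0
            flags[f"flag_{trans}"] = bool(falling and nonpos)
        low_side = (ind in low_gsi_community if low_gsi_community is not None
                    else float(gsi[ind]) < 0.0)
        orphaned = bool(flags[f"flag_{transitions[-1]}"]) and low_side
        rows.append({"indicator": ind, "gsi": float(gsi[ind]),
                     **flags, "orphaned": orphaned})
    return pd.DataFrame(rows)


def gsi_groups(gsi: Mapping[str, float],
               catalog: IndicatorCatalog) -> dict[str, int]:
    """Six-way indicator grouping by GSI value and environment flag.

    Environment-related indicators: group 1 (GSI > 0.5), group 2
    (-1.0 <= GSI <= 0.5), group 3 (GSI < -1.0). Non-environment
    indicators: groups 4-6 by the same cuts.
    """
    env = catalog.environment_flags()
    missing = [i for i in catalog.indicators if i not in gsi]
    if missing:
        raise DegenerateInputError(f"gsi missing for indicators: {missing[:5]}")
    out: dict[str, int] = {}
    for ind in catalog.indicators:
        value = float(gsi[ind])
        if value > GSI_HIGH_CUT:
            band = 0
        elif value >= GSI_LOW_CUT:
            band = 1
        else:
            band = 2
        out[ind] = band + (1 if env[ind] else 4)
    return out


def classify_quadrants(rca_row: pd.Series, score_row: pd.Series,
                       global_avg: float) -> dict[str, str]:
    """Four-area classification of one country's indicators.

    Area I: specialized (RCA > 0) and score at or above the global
    average — the ideal case. Area II: specialized but below-average
    score. Area III: not specialized and below average — both relative
    and absolute underperformance. Area IV: not specialized but at or
    above average.
    """
    if not rca_row.index.equals(score_row.index):
        common = rca_row.index.intersection(score_row.index)
        if len(common) != len(rca_row) or len(common) != len(score_row):
            raise DegenerateInputError("rca and score rows are not aligned")
        score_row = score_row.loc[rca_row.index]
    out = {}
    for ind in rca_row.index:
        advantage = rca_row[ind] > 0
        high = score_row[ind] >= global_avg
        if advantage:
            out[ind] = "I" if high else "II"
        else:
            out[ind] = "IV" if high else "III"
    return out
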