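"""Reading, validating and writing score panels and indicator catalogs.

This module is the single source of truth for the package's input schemas.
The canonical score input is a long ("tidy") CSV with one row per
(country, year, indicator) observation and a score on the 0-100
percent-of-optimum scale; wide country x indicator matrices are an export
convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, IntegrityError, SchemaError

#: Default column names of the scores CSV.
SCORE_COLUMNS = {"country": "country_code", "year": "year",
                 "indicator": "indicator", "score": "score"}

#: Closed vocabulary for the UNSD cross-walk column of the catalog.
UNSD_MATCH_LEVELS = ("Match", "Closely aligned", "Not in UNSTATS")

CATALOG_COLUMNS = ("indicator", "sdr_code", "goal", "label", "environment",
                   "unsd_target", "unsd_match")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScorePanel:
    """A validated country x indicator x year panel of scores in [0, 100].

    ``data`` is a long DataFrame with columns ``country``, ``year``,
    ``indicator``, ``score``; at most one row per key triple. The panel may
    be incomplete (not every country observed on every indicator every
    year); :func:`select_year` produces complete per-year matrices.
    """

    data: pd.DataFrame
    countries: tuple[str, ...] = field(init=False)
    indicators: tuple[str, ...] = field(init=False)
    years: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = {"country", "year", "indicator", "score"} - set(df.columns)
        if missing:
            raise SchemaError(f"panel frame missing columns: {sorted(missing)}")
        scores = df["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(scores)):
            bad = df.index[~np.isfinite(scores)][0]
            raise IntegrityError(f"non-finite score at row {bad}")
        out = (scores < 0.0) | (scores > 100.0)
        if out.any():
            bad = df.index[out][0]
            raise IntegrityError(
                f"score out of [0, 100] at row {bad}: {df.loc[bad, 'score']!r} "
                f"(country={df.loc[bad, 'country']!r}, year={df.loc[bad, 'year']!r}, "
                f"indicator={df.loc[bad, 'indicator']!r})")
        dup = df.duplicated(subset=["country", "year", "indicator"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise IntegrityError(
                "duplicate (country, year, indicator) entry: "
                f"({bad['country']!r}, {bad['year']!r}, {bad['indicator']!r})")
        object.__setattr__(self, "countries",
                           tuple(pd.unique(df["country"].astype(str))))
        object.__setattr__(self, "indicators",
                           tuple(pd.unique(df["indicator"].astype(str))))
        object.__setattr__(self, "years",
                           tuple(sorted(int(y) for y in pd.unique(df["year"]))))

    def __len__(self) -> int:
        return len(self.data)

    def year_slice(self, year: int) -> pd.DataFrame:
        """Long rows for one year (no completeness guarantee)."""
        if year not in self.years:
            raise DegenerateInputError(f"year {year} not present in panel")
        return self.data.loc[self.data["year"] == year]


@dataclass(frozen=True)
class ScoreMatrix:
    """A complete countries x indicators score matrix for one year.

    ``values`` is a DataFrame with country row labels and indicator column
    labels, no missing cells, every cell in [0, 100]. ``dropped_countries``
    and ``dropped_indicators`` report what :func:`select_year` removed.
    """

    year: int
    values: pd.DataFrame
    dropped_countries: tuple[str, ...] = ()
    dropped_indicators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise IntegrityError("score matrix has missing cells")
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise IntegrityError("score matrix has duplicate row/column labels")
        arr = v.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0.0 or arr.max() > 100.0):
            raise IntegrityError("score matrix has values outside [0, 100]")

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass(frozen=True)
class IndicatorCatalog:
    """Metadata for each indicator: codes, goal, label, environment flag,
    and the cross-walk to the UNSD global indicator framework."""

    data: pd.DataFrame  # one row per indicator, CATALOG_COLUMNS

    def __post_init__(self) -> None:
        df = self.data
        missing = set(CATALOG_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"catalog missing columns: {sorted(missing)}")
        for col in ("indicator", "sdr_code"):
            if df[col].duplicated().any():
                dup = df.loc[df[col].duplicated(), col].iloc[0]
                raise IntegrityError(f"duplicate {col} in catalog: {dup!r}")
        goals = df["goal"].astype(int)
        if ((goals < 1) | (goals > 17)).any():
            raise IntegrityError("catalog goal outside 1..17")
        bad = ~df["unsd_match"].isin(UNSD_MATCH_LEVELS)
        if bad.any():
            raise SchemaError(
                f"unknown unsd_match value {df.loc[bad, 'unsd_match'].iloc[0]!r}; "
                f"expected one of {UNSD_MATCH_LEVELS}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.data["indicator"].astype(str))

    def environment_flags(self) -> dict[str, bool]:
        return dict(zip(self.data["indicator"].astype(str),
                        self.data["environment"].astype(bool)))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_score_panel(path: str | Path,
                     schema: Mapping[str, str] | None = None) -> ScorePanel:
    """Load and validate a long scores CSV into a :class:`ScorePanel`.

    Parameters
    ----------
    path:
        CSV with a header row; UTF-8.
    schema:
        Optional mapping from the canonical names ``country``, ``year``,
        ``indicator``, ``score`` to the column names actually present.
        Defaults to :data:`SCORE_COLUMNS`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(SCORE_COLUMNS)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}; "
                          f"found {list(raw.columns)}")
    df = pd.DataFrame({
        "country": raw[colmap["country"]].astype(str),
        "year": _parse_int_column(raw[colmap["year"]], "year"),
        "indicator": raw[colmap["indicator"]].astype(str),
        "score": _parse_float_column(raw[colmap["score"]], "score"),
    })
    return ScorePanel(df)


def _parse_float_column(col: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise IntegrityError(
            f"non-numeric {name} at data row {row}: {col.iloc[row]!r}")
    return out.astype(float)


def _parse_int_column(col: pd.Series, name: str) -> pd.Series:
    out = _parse_float_column(col, name)
    if not np.allclose(out, np.round(out)):
        row = int(out.index[(out != np.round(out))][0])
        raise IntegrityError(f"non-integer {name} at data row {row}")
    return out.astype(int)


def load_indicator_catalog(path: str | Path) -> IndicatorCatalog:
    """Load the indicator catalog CSV (see :data:`CATALOG_COLUMNS`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CATALOG_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    df = raw.loc[:, list(CATALOG_COLUMNS)].copy()
    df["goal"] = _parse_int_column(df["goal"], "goal")
    df["environment"] = df["environment"].str.strip().str.lower().map(
        {"true": True, "false": False, "1": True, "0": False})
    if df["environment"].isna().any():
        raise SchemaError("environment column must be true/false")
    return IndicatorCatalog(df)


# ---------------------------------------------------------------------------
# Per-year selection
# ---------------------------------------------------------------------------

def select_year(panel: ScorePanel, year: int,
                coverage: float = 0.8) -> ScoreMatrix:
    """Slice one year out of a panel and make it complete.

    Indicators observed for fewer than ``coverage`` x (number of countries
    present that year) are dropped first — the panel's analogue of excluding
    indicators that cannot cover most countries. Countries with any
    remaining missing cell are then dropped. Both dropped sets are recorded
    on the returned :class:`ScoreMatrix`.

    Idempotent: applied to a complete matrix it changes nothing.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rows = panel.year_slice(year)
    wide = rows.pivot(index="country", columns="indicator", values="score")
    wide = wide.loc[sorted(wide.index), sorted(wide.columns)]
    n_countries = len(wide.index)
    counts = wide.notna().sum(axis=0)
    keep_ind = counts[counts >= coverage * n_countries].index
    dropped_ind = tuple(c for c in wide.columns if c not in set(keep_ind))
    wide = wide.loc[:, keep_ind]
    complete = wide.dropna(axis=0)
    dropped_cty = tuple(c for c in wide.index if c not in set(complete.index))
    if complete.empty or complete.shape[1] == 0:
        raise DegenerateInputError(
            f"year {year}: nothing left after coverage filtering "
            f"(dropped {len(dropped_ind)} indicators, {len(dropped_cty)} countries)")
    return ScoreMatrix(year=year, values=complete,
                       dropped_countries=dropped_cty,
                       dropped_indicators=dropped_ind)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

#: Fixed decimal formatting used for every CSV export, so that a
#: write -> load round trip is bit-for-bit stable.
FLOAT_FORMAT = "%.9f"


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 index_label: str = "country") -> Path:
    """Write a wide matrix (entities as rows) to CSV with fixed formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, float_format=FLOAT_FORMAT, index_label=index_label)
    return path


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a long table to CSV (no index) with fixed float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, float_format=FLOAT_FORMAT, index=False)
    return path


def write_score_panel(panel: ScorePanel, path: str | Path) -> Path:
    """Write a panel back to the canonical long CSV layout."""
    df = panel.data.rename(columns={"country": "country_code"})
    return write_table(df[["country_code", "year", "indicator", "score"]], path)


def write_indicator_catalog(catalog: IndicatorCatalog, path: str | Path) -> Path:
    df = catalog.data.copy()
    df["environment"] = df["environment"].map({True: "true", False: "false"})
    return write_table(df, path)


def panel_from_matrix(matrix: ScoreMatrix) -> ScorePanel:
    """Lift a single complete year matrix back into panel form."""
    long = matrix.values.stack().rename("score").reset_index()
    long.columns = ["country", "indicator", "score"]
    long["year"] = matrix.year
    return ScorePanel(long[["country", "year", "indicator", "score"]])
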