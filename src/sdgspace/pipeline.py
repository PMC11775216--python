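"""End-to-end pipeline, robustness sweeps and machine-readable summaries.

``run_full_pipeline`` chains every stage for each requested year —
per-year matrix selection, RCA, binarization, sustainability indices,
indicator and country spaces, trajectories, stages and orphaned-indicator
flags — writes the exports, and returns an in-memory bundle plus a JSON
summary (dropped entities, convergence, community sizes). The run is
fully deterministic given the config.

The robustness helpers quantify the stability claims that justify the
default parameters: community partitions across proximity thresholds
(adjusted Rand index), trajectory shapes across window sizes (Spearman),
and GSI vectors across years (Pearson).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .complexity import SustainabilityIndices, eigen_indices, reflections_indices
from .errors import DegenerateInputError, SDGSpaceError
from .io import (IndicatorCatalog, ScoreMatrix, ScorePanel,
                 load_indicator_catalog, load_score_panel, select_year,
                 write_matrix, write_table)
from .rca import (BinaryAdvantageMatrix, SpecializationMatrix,
                  binarize_advantage, compute_rca)
from .space import (COSINE, DEFAULT_THRESHOLD, ProximityMatrix, SpaceGraph,
                    build_space_graph, country_space, layout_graph,
                    proximity_matrix, write_space)
from .stages import (StageAssignment, StageSummary, assign_stages,
                     classify_quadrants, identify_orphaned, stage_summary)
from .trajectories import (DEFAULT_WINDOW, CountryRanking, TrajectoryTable,
                           moving_window_means, rank_countries)

log = logging.getLogger("sdgspace")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    scores: str = ""
    catalog: str | None = None
    years: list[int] | None = None          # None = every year in the panel
    formula: str = COSINE
    threshold: float = DEFAULT_THRESHOLD
    window: int = DEFAULT_WINDOW
    n_stages: int = 4
    top_k: int = 20
    coverage: float = 0.8
    tol: float = 1e-10
    max_iter: int = 1000
    seed: int = 0
    out: str = "sdgspace_out"
    formats: list[str] = field(default_factory=lambda: ["csv"])
    per_country_spaces: bool = False
    reflections_check: bool = False

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SDGSpaceError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class YearResult:
    """All artifacts derived from one year of the panel."""

    year: int
    matrix: ScoreMatrix
    spec: SpecializationMatrix
    m: BinaryAdvantageMatrix
    indices: SustainabilityIndices
    reflections: SustainabilityIndices | None
    proximity: ProximityMatrix
    space: SpaceGraph
    cspace: SpaceGraph
    ranking: CountryRanking
    trajectories: TrajectoryTable | None
    stages: StageAssignment
    summary: StageSummary
    orphaned: pd.DataFrame


@dataclass
class RunBundle:
    config: RunConfig
    results: dict[int, YearResult]
    summary: dict


def analyse_year(matrix: ScoreMatrix, config: RunConfig) -> YearResult:
    """Run every analysis stage on one complete year matrix."""
    spec = compute_rca(matrix)
    m = binarize_advantage(spec)
    indices = eigen_indices(m, scores=matrix)
    refl = (reflections_indices(m, tol=config.tol, max_iter=config.max_iter,
                                scores=matrix)
            if config.reflections_check else None)
    kept = BinaryAdvantageMatrix(
        m=m.m.drop(index=list(indices.dropped_countries),
                   columns=list(indices.dropped_indicators)))
    # allow_forest: in the perfectly polarized limit the two clusters share
    # no co-specialization and the proximity graph splits in two; the
    # pipeline then renders the maximum spanning forest instead of failing.
    prox = proximity_matrix(kept, formula=config.formula)
    space = build_space_graph(prox, threshold=config.threshold,
                              node_scores=indices.gsi, allow_forest=True)
    layout_graph(space, seed=config.seed)
    cspace = country_space(kept, threshold=config.threshold,
                           node_scores=indices.csi, formula=config.formula,
                           allow_forest=True)
    layout_graph(cspace, seed=config.seed)
    ranking = rank_countries(matrix)
    traj = None
    if 2 <= config.window <= len(ranking):
        traj = moving_window_means(spec, matrix, ranking, w=config.window)
    stages = assign_stages(ranking, n_stages=config.n_stages)
    summary = stage_summary(spec, stages, k=min(config.top_k,
                                                len(spec.indicators)))
    orphaned_communities = {
        node for node, comm in space.communities().items() if comm == 2}
    orphaned = identify_orphaned(summary, indices.gsi,
                                 low_gsi_community=orphaned_communities)
    return YearResult(year=matrix.year, matrix=matrix, spec=spec, m=m,
                      indices=indices, reflections=refl, proximity=prox,
                      space=space, cspace=cspace, ranking=ranking,
                      trajectories=traj, stages=stages, summary=summary,
                      orphaned=orphaned)


def enumerate_country_year_spaces(panel: ScorePanel,
                                  coverage: float = 0.8
                                  ) -> list[tuple[str, int]]:
    """The (country, year) pairs for which a per-country space exists,
    i.e. every country retained in each year's complete matrix. The
    national space is the year's indicator space recolored with that
    country's RCA row, so one exists per retained (country, year)."""
    pairs: list[tuple[str, int]] = []
    for year in panel.years:
        matrix = select_year(panel, year, coverage=coverage)
        pairs.extend((c, year) for c in matrix.countries)
    return pairs


def run_full_pipeline(config: RunConfig) -> RunBundle:
    """Execute the whole pipeline per the config and write all exports."""
    if not config.scores:
        raise SDGSpaceError("data_io: no scores path configured")
    scores_path = Path(config.scores)
    if not scores_path.exists():
        raise SDGSpaceError(f"data_io: scores file not found: {scores_path}")
    catalog: IndicatorCatalog | None = None
    if config.catalog:
        if not Path(config.catalog).exists():
            raise SDGSpaceError(f"data_io: catalog not found: {config.catalog}")
        catalog = load_indicator_catalog(config.catalog)
    panel = load_score_panel(scores_path)
    years = config.years or list(panel.years)
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    results: dict[int, YearResult] = {}
    summary: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "years": {},
    }
    for year in years:
        try:
            matrix = select_year(panel, year, coverage=config.coverage)
            result = analyse_year(matrix, config)
        except SDGSpaceError as err:
            raise type(err)(f"year {year}: {err}") from err
        results[year] = result
        _write_year(result, config, out, catalog)
        comm = result.space.communities()
        sizes = pd.Series(list(comm.values())).value_counts().sort_index()
        summary["years"][str(year)] = {
            "n_countries": len(matrix.countries),
            "n_indicators": len(matrix.indicators),
            "dropped_countries": list(matrix.dropped_countries),
            "dropped_indicators": list(matrix.dropped_indicators),
            "index_dropped_countries": list(result.indices.dropped_countries),
            "index_dropped_indicators": list(result.indices.dropped_indicators),
            "indices_converged": bool(result.indices.converged),
            "community_sizes": {int(k): int(v) for k, v in sizes.items()},
            "n_windows": (result.trajectories.n_windows
                          if result.trajectories is not None else 0),
            "n_orphaned": int(result.orphaned["orphaned"].sum()),
        }
        for name in summary["years"][str(year)]["dropped_countries"]:
            log.info("year %s: dropped country %s (reason: incomplete)", year, name)
        for name in summary["years"][str(year)]["dropped_indicators"]:
            log.info("year %s: dropped indicator %s (reason: coverage)", year, name)
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return RunBundle(config=config, results=results, summary=summary)


def _write_year(result: YearResult, config: RunConfig, out: Path,
                catalog: IndicatorCatalog | None) -> None:
    ydir = out / str(result.year)
    ydir.mkdir(parents=True, exist_ok=True)
    write_matrix(result.spec.rca, ydir / "rca.csv")
    write_table(result.indices.to_frame(year=result.year), ydir / "indices.csv")
    fmts = config.formats or ["csv"]
    for fmt in fmts:
        suffix = {"graphml": ".graphml", "gexf": ".gexf", "csv": ""}.get(fmt)
        if suffix is None:
            raise SDGSpaceError(f"cli_reporting: unknown export format {fmt!r}")
        write_space(result.space, ydir / f"space{suffix or '.csv'}", fmt=fmt)
        write_space(result.cspace, ydir / f"country_space{suffix or '.csv'}",
                    fmt=fmt)
    if result.trajectories is not None:
        write_table(result.trajectories.to_frame(), ydir / "trajectories.csv")
    stage_rows = pd.DataFrame(
        {"country": list(result.ranking.order),
         "rank": range(1, len(result.ranking) + 1),
         "aggregate": [result.ranking.aggregate[c]
                       for c in result.ranking.order],
         "stage": [result.stages.stage_of[c] for c in result.ranking.order]})
    write_table(stage_rows, ydir / "stages.csv")
    write_table(result.summary.deltas.reset_index(names="transition"),
                ydir / "stage_deltas.csv")
    write_table(result.orphaned, ydir / "orphaned.csv")
    avg = float(result.matrix.values.to_numpy().mean())
    quad_rows = []
    for country in result.matrix.countries:
        quads = classify_quadrants(result.spec.rca.loc[country],
                                   result.matrix.values.loc[country], avg)
        quad_rows.extend({"country": country, "indicator": i, "area": a}
                         for i, a in quads.items())
    write_table(pd.DataFrame(quad_rows), ydir / "quadrants.csv")
    if catalog is not None:
        from .stages import gsi_groups
        common = [i for i in catalog.indicators
                  if i in result.indices.gsi.index]
        if common:
            sub = IndicatorCatalog(
                catalog.data[catalog.data["indicator"].isin(common)])
            groups = gsi_groups(result.indices.gsi, sub)
            write_table(pd.DataFrame(sorted(groups.items()),
                                     columns=["indicator", "group"]),
                        ydir / "gsi_groups.csv")
    if config.per_country_spaces:
        sdir = ydir / "country_spaces"
        sdir.mkdir(exist_ok=True)
        nodes = result.space.node_table().set_index("node")
        for country in result.matrix.countries:
            table = nodes.copy()
            table["rca"] = result.spec.rca.loc[country]
            write_table(table.reset_index(), sdir / f"{country}.csv")


# ---------------------------------------------------------------------------
# Robustness sweeps
# ---------------------------------------------------------------------------

def sweep_threshold(p: ProximityMatrix, thresholds: Sequence[float],
                    node_scores: pd.Series | None = None) -> pd.DataFrame:
    """Pairwise adjusted Rand index of the two-community partition across
    proximity thresholds. A threshold that yields a single community is
    flagged (``degenerate``) rather than fatal."""
    if len(thresholds) < 2:
        raise DegenerateInputError("need at least 2 thresholds to sweep")
    partitions: dict[float, list[int] | None] = {}
    labels = sorted(p.labels)
    for thr in thresholds:
        graph = build_space_graph(p, threshold=thr, node_scores=node_scores)
        comm = graph.communities()
        labs = [comm[n] for n in labels]
        partitions[thr] = labs if len(set(labs)) > 1 else None
    rows = []
    for i, ta in enumerate(thresholds):
        for tb in thresholds[i + 1:]:
            pa, pb = partitions[ta], partitions[tb]
            degenerate = pa is None or pb is None
            ari = (np.nan if degenerate
                   else float(adjusted_rand_score(pa, pb)))
            rows.append({"threshold_a": ta, "threshold_b": tb,
                         "ari": ari, "degenerate": degenerate})
    return pd.DataFrame(rows)


def _window_centers(n: int, w: int) -> np.ndarray:
    return np.arange(1, n - w + 2) + (w - 1) / 2.0


def sweep_window(spec: SpecializationMatrix, scores: ScoreMatrix,
                 ranking: CountryRanking,
                 sizes: Sequence[int]) -> pd.DataFrame:
    """Per-indicator Spearman correlation of trajectory curves between
    window sizes. Curves of different sizes live on different window
    grids, so each is linearly interpolated onto a common grid of window-
    center rank positions before correlating."""
    if len(sizes) < 2:
        raise DegenerateInputError("need at least 2 window sizes to sweep")
    n = len(ranking)
    tables = {w: moving_window_means(spec, scores, ranking, w=w)
              for w in sizes}
    lo = max(_window_centers(n, w)[0] for w in sizes)
    hi = min(_window_centers(n, w)[-1] for w in sizes)
    grid = np.linspace(lo, hi, 100)
    rows = []
    for i, wa in enumerate(sizes):
        for wb in sizes[i + 1:]:
            corrs = []
            for ind in spec.indicators:
                ca = np.interp(grid, _window_centers(n, wa),
                               tables[wa].mean_rca[ind].to_numpy())
                cb = np.interp(grid, _window_centers(n, wb),
                               tables[wb].mean_rca[ind].to_numpy())
                rho = spearmanr(ca, cb).statistic
                if np.isfinite(rho):
                    corrs.append(float(rho))
            rows.append({"window_a": wa, "window_b": wb,
                         "min_spearman": min(corrs) if corrs else np.nan,
                         "mean_spearman": (float(np.mean(corrs))
                                           if corrs else np.nan)})
    return pd.DataFrame(rows)


def year_stability(panel: ScorePanel, years: Sequence[int],
                   coverage: float = 0.8) -> pd.DataFrame:
    """Pearson correlation of the GSI vector between pairs of years,
    computed on the indicators common to both years."""
    if len(years) < 2:
        raise DegenerateInputError("need at least 2 years to compare")
    gsis: dict[int, pd.Series] = {}
    for year in years:
        matrix = select_year(panel, year, coverage=coverage)
        m = binarize_advantage(compute_rca(matrix))
        gsis[year] = eigen_indices(m, scores=matrix).gsi
    rows = []
    for i, ya in enumerate(years):
        for yb in years[i + 1:]:
            common = gsis[ya].index.intersection(gsis[yb].index)
            r = float(np.corrcoef(gsis[ya][common], gsis[yb][common])[0, 1])
            rows.append({"year_a": ya, "year_b": yb,
                         "n_common": len(common), "pearson_r": r})
    return pd.DataFrame(rows)
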