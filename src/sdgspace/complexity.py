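"""Country and goal sustainability indices (CSI / GSI).

These are the economic-complexity ECI/PCI analogues computed on the binary
advantage matrix M: high-CSI countries tend to be specialized in high-GSI
indicators and vice versa, so the pair of indices summarizes which side of
the polarized indicator structure each entity sits on.

Two routes are provided and cross-checked against each other:

* the spectral route (canonical): CSI is the eigenvector of the
  second-largest eigenvalue of the row-stochastic country-projection
  matrix ``W[c, c'] = sum_i M[c, i] M[c', i] / (k_c k_i)``, where ``k_c``
  is diversity and ``k_i`` ubiquity. GSI is the ubiquity-normalized
  average of CSI over the countries specialized in each indicator.
* the method of reflections: alternate averaging of the two index vectors
  over the bipartite advantage graph, standardized after every round.
  With per-round standardization this iteration converges to the same
  second eigenvector (the constant leading eigenvector is removed by the
  centering), which is asserted numerically in the test-suite.

Both indices are z-scored (mean 0, sd 1) and sign-oriented so that CSI
correlates non-negatively with the per-country total raw score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DegeneracyError
from .io import ScoreMatrix
from .rca import BinaryAdvantageMatrix

#: Eigenvalue separation below which the second eigenpair is ambiguous.
EIGEN_GAP_TOL = 1e-10
#: Standard deviation below which a vector counts as constant.
ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class SustainabilityIndices:
    """Z-scored CSI (per country) and GSI (per indicator) plus provenance."""

    csi: pd.Series
    gsi: pd.Series
    method: str                       # "eigen" | "reflections"
    iterations_used: int              # eigen rank used, or reflection rounds
    sign_anchor: str
    converged: bool
    dropped_countries: tuple[str, ...] = ()
    dropped_indicators: tuple[str, ...] = ()

    def to_frame(self, year: int | None = None) -> pd.DataFrame:
        """Long export: entity, kind, value, method[, year]."""
        rows = pd.concat([
            pd.DataFrame({"entity": self.csi.index, "kind": "country",
                          "value": self.csi.to_numpy()}),
            pd.DataFrame({"entity": self.gsi.index, "kind": "indicator",
                          "value": self.gsi.to_numpy()}),
        ], ignore_index=True)
        rows["method"] = self.method
        if year is not None:
            rows["year"] = year
        return rows


def prune_for_indices(m: BinaryAdvantageMatrix
                      ) -> tuple[BinaryAdvantageMatrix, tuple[str, ...], tuple[str, ...]]:
    """Repeatedly drop zero-diversity countries and zero-ubiquity indicators.

    Returns the pruned matrix plus the dropped country and indicator sets.
    Raises :class:`DegeneracyError` if nothing survives.
    """
    frame = m.m
    dropped_c: list[str] = []
    dropped_i: list[str] = []
    while True:
        row = frame.sum(axis=1)
        col = frame.sum(axis=0)
        dead_rows = row.index[row == 0]
        dead_cols = col.index[col == 0]
        if len(dead_rows) == 0 and len(dead_cols) == 0:
            break
        dropped_c.extend(str(c) for c in dead_rows)
        dropped_i.extend(str(i) for i in dead_cols)
        frame = frame.drop(index=dead_rows, columns=dead_cols)
        if frame.empty:
            raise DegeneracyError("all countries/indicators pruned: no support")
    if frame.empty:
        raise DegeneracyError("empty advantage matrix")
    return BinaryAdvantageMatrix(m=frame), tuple(dropped_c), tuple(dropped_i)


def _zscore(values: np.ndarray, what: str) -> np.ndarray:
    sd = values.std()
    if sd < ZERO_VAR_TOL:
        raise DegeneracyError(f"{what} has zero variance; indices undefined")
    return (values - values.mean()) / sd


def _total_scores(scores: ScoreMatrix | pd.DataFrame | None,
                  countries: pd.Index) -> np.ndarray | None:
    if scores is None:
        return None
    frame = scores.values if isinstance(scores, ScoreMatrix) else scores
    if not set(countries).issubset(frame.index):
        return None
    return frame.loc[countries].sum(axis=1).to_numpy(dtype=float)


def _indicator_means(scores: ScoreMatrix | pd.DataFrame | None,
                     indicators: pd.Index) -> np.ndarray | None:
    if scores is None:
        return None
    frame = scores.values if isinstance(scores, ScoreMatrix) else scores
    if not set(indicators).issubset(frame.columns):
        return None
    return frame[indicators].mean(axis=0).to_numpy(dtype=float)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() < ZERO_VAR_TOL or b.std() < ZERO_VAR_TOL:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _orient(csi: np.ndarray, gsi: np.ndarray, m: np.ndarray,
            k_c: np.ndarray, k_i: np.ndarray,
            totals: np.ndarray | None,
            ind_means: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, str]:
    """Fix global signs.

    CSI is flipped so it correlates non-negatively with the per-country
    total raw score (or with diversity when no scores are supplied); GSI is
    then aligned with the CSI-implied indicator index so the pair stays
    coherent. A secondary anchor (GSI vs indicator world-mean score) is
    used only when the primary correlation is exactly zero.
    """
    anchor_vec = totals if totals is not None else k_c.astype(float)
    anchor_name = ("corr(csi, total raw score) >= 0" if totals is not None
                   else "corr(csi, diversity) >= 0")
    r = _safe_corr(csi, anchor_vec)
    if r == 0.0 and ind_means is not None:
        r_g = _safe_corr(gsi, ind_means)
        anchor_name = "corr(gsi, indicator world-mean score) >= 0"
        if r_g < 0:
            gsi = -gsi
        implied_csi = (m @ gsi) / k_c
        if _safe_corr(csi, implied_csi) < 0:
            csi = -csi
        return csi, gsi, anchor_name
    if r == 0.0:
        # No usable anchor: make the largest-magnitude CSI entry positive.
        anchor_name = "largest-|csi| entry positive (no usable anchor)"
        pivot = int(np.argmax(np.abs(csi)))
        if csi[pivot] < 0:
            csi = -csi
    elif r < 0:
        csi = -csi
    implied_gsi = (m.T @ csi) / k_i
    if _safe_corr(gsi, implied_gsi) < 0:
        gsi = -gsi
    return csi, gsi, anchor_name


def eigen_indices(m: BinaryAdvantageMatrix,
                  scores: ScoreMatrix | pd.DataFrame | None = None
                  ) -> SustainabilityIndices:
    """CSI/GSI by the spectral route (canonical).

    The country projection ``W = D^-1 M U^-1 M^T`` (D = diag(diversity),
    U = diag(ubiquity)) is row-stochastic, so its leading eigenvector is
    constant and carries no information; CSI is the eigenvector of the
    second-largest eigenvalue, obtained from the symmetrized similar
    matrix ``D^-1/2 M U^-1 M^T D^-1/2`` for numerical stability. GSI is
    the ubiquity-normalized average of CSI over specialized countries.

    Raises :class:`DegeneracyError` when no informative second eigenpair
    exists (all-equal structure, or a tied eigenvalue making it ambiguous).
    """
    pruned, dropped_c, dropped_i = prune_for_indices(m)
    mat = pruned.m.to_numpy(dtype=float)
    k_c = mat.sum(axis=1)
    k_i = mat.sum(axis=0)
    if mat.shape[0] < 2:
        raise DegeneracyError("need at least 2 countries with support")
    d_isqrt = 1.0 / np.sqrt(k_c)
    sym = (mat / k_i[None, :]) @ mat.T
    sym = d_isqrt[:, None] * sym * d_isqrt[None, :]
    sym = (sym + sym.T) / 2.0
    # W is row-stochastic, so sym has the known leading eigenpair
    # (1, D^1/2 1). Deflate it, then the top remaining eigenvector is the
    # second eigenvector of W regardless of multiplicity in the λ=1 space.
    u = np.sqrt(k_c)
    u = u / np.linalg.norm(u)
    deflated = sym - np.outer(u, u)
    eigvals, eigvecs = scipy.linalg.eigh(deflated)   # ascending
    top, runner_up = eigvals[-1], (eigvals[-2] if len(eigvals) > 1 else None)
    if runner_up is not None and abs(top - runner_up) < EIGEN_GAP_TOL:
        raise DegeneracyError(
            "second eigenvalue is not separated from the next; "
            "indices ambiguous on this structure")
    csi = _zscore(d_isqrt * eigvecs[:, -1], "csi eigenvector")
    gsi = _zscore((mat.T @ csi) / k_i, "gsi")
    rank = 2  # second eigenpair of the projection matrix
    csi, gsi, anchor = _orient(
        csi, gsi, mat, k_c, k_i,
        _total_scores(scores, pruned.m.index),
        _indicator_means(scores, pruned.m.columns))
    return SustainabilityIndices(
        csi=pd.Series(csi, index=pruned.m.index, name="csi"),
        gsi=pd.Series(gsi, index=pruned.m.columns, name="gsi"),
        method="eigen", iterations_used=int(rank), sign_anchor=anchor,
        converged=True, dropped_countries=dropped_c, dropped_indicators=dropped_i)


def _initial_csi(mat: np.ndarray, k_c: np.ndarray, k_i: np.ndarray) -> np.ndarray:
    """Diversity, with deterministic fallbacks for perfectly regular M.

    On regular structures (constant diversity and ubiquity) the classic
    diversity initialization is constant and the reflections iteration
    cannot break symmetry; the ladder below falls back to progressively
    finer structure-sensitive vectors.
    """
    candidates = [
        k_c.astype(float),
        mat @ k_i.astype(float),                       # ubiquity-weighted
        mat @ np.arange(1.0, mat.shape[1] + 1.0),      # column-position weighted
    ]
    for cand in candidates:
        if cand.std() >= ZERO_VAR_TOL:
            return cand
    raise DegeneracyError("no symmetry-breaking initialization found")


def reflections_indices(m: BinaryAdvantageMatrix,
                        tol: float = 1e-10, max_iter: int = 1000,
                        scores: ScoreMatrix | pd.DataFrame | None = None
                        ) -> SustainabilityIndices:
    """CSI/GSI by the method of reflections with per-round standardization.

    Initial values are diversity and ubiquity; each round replaces a
    country's index with the mean indicator index over its specializations
    and an indicator's index with the mean country index over the countries
    specialized in it, then z-scores both vectors. Iteration stops when the
    largest absolute change falls below ``tol``; hitting ``max_iter`` first
    returns ``converged=False`` with the last iterate.
    """
    pruned, dropped_c, dropped_i = prune_for_indices(m)
    mat = pruned.m.to_numpy(dtype=float)
    k_c = mat.sum(axis=1)
    k_i = mat.sum(axis=0)
    csi = _zscore(_initial_csi(mat, k_c, k_i), "initial csi")
    gsi_raw = k_i.astype(float)
    if gsi_raw.std() < ZERO_VAR_TOL:
        gsi_raw = mat.T @ csi
    gsi = _zscore(gsi_raw, "initial gsi")
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        csi_new = _zscore((mat @ gsi) / k_c, "csi")
        gsi_new = _zscore((mat.T @ csi) / k_i, "gsi")
        # The sign of a standardized iterate is arbitrary; align with the
        # previous round before measuring the change.
        if float(csi_new @ csi) < 0:
            csi_new = -csi_new
        if float(gsi_new @ gsi) < 0:
            gsi_new = -gsi_new
        delta = max(np.abs(csi_new - csi).max(), np.abs(gsi_new - gsi).max())
        csi, gsi = csi_new, gsi_new
        if delta < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("method of reflections did not converge within "
                      f"{max_iter} iterations", RuntimeWarning, stacklevel=2)
    csi, gsi, anchor = _orient(
        csi, gsi, mat, k_c, k_i,
        _total_scores(scores, pruned.m.index),
        _indicator_means(scores, pruned.m.columns))
    return SustainabilityIndices(
        csi=pd.Series(csi, index=pruned.m.index, name="csi"),
        gsi=pd.Series(gsi, index=pruned.m.columns, name="gsi"),
        method="reflections", iterations_used=iterations, sign_anchor=anchor,
        converged=converged, dropped_countries=dropped_c,
        dropped_indicators=dropped_i)
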