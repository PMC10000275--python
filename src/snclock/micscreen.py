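"""Maximal/total information coefficient (MIC/TIC) age-association screening.

MIC captures both linear and nonlinear dependence between a gene's expression
and donor age: for every grid shape (k columns x l rows) within the budget
B(n) = ceil(n**alpha), the mutual information of the induced discretization is
maximized over grid placements and normalized by log(min(k, l)). MIC is the
largest normalized value over shapes; TIC is their mean, a statistic of
independence-testing power on the same [0, 1] scale. Genes whose expression
clears a shared MIC and TIC threshold against chronological age (default 0.7)
are retained as age-associated.

The nonlinearity diagnostic MIC - rho^2 (rho^2 the squared Pearson
correlation) is near zero for linear relationships and exceeds ~0.2 for
strongly nonlinear ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mine import grid_budget, half_characteristic_matrix

__all__ = [
    "MineParams",
    "characteristic_matrix",
    "mic_tic",
    "mine_stats",
    "pearson_r2",
    "screen",
]


@dataclass(frozen=True)
class MineParams:
    """Tuning knobs of the approximate characteristic-matrix search.

    alpha: exponent of the grid budget B(n) = ceil(n**alpha), 0 < alpha < 1.
    c: clump factor; the column optimizer works over at most c*k merged
       clumps ("superclumps") when searching k-column partitions.
    both_orientations: optimize the grid in both (x|y) and (y|x) orientations
       and take the elementwise maximum, making the statistic symmetric.
    """

    alpha: float = 0.6
    c: float = 15.0
    both_orientations: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.c < 1.0:
            raise ValueError(f"c must be >= 1, got {self.c}")


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.shape[0] < 10:
        raise ValueError(f"need at least 10 observations, got {x.shape[0]}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("association undefined for a constant vector")
    return x, y


def characteristic_matrix(
    x: np.ndarray, y: np.ndarray, params: MineParams = MineParams()
) -> np.ndarray:
    """Normalized-MI characteristic matrix M[k, l] over grid shapes.

    Entry (k, l), for k, l >= 2 and k*l <= B(n), is the maximal mutual
    information over k-column x l-row grids found by the approximate search,
    normalized by log(min(k, l)); other entries are NaN. With
    ``both_orientations`` the matrix is the elementwise maximum of the two
    axis orientations, so M[k, l] uses the better of (k cols on x) and
    (k cols on y).
    """
    x, y = _validate_pair(x, y)
    B = grid_budget(x.shape[0], params.alpha)
    m = half_characteristic_matrix(x, y, B, params.c)
    if params.both_orientations:
        m = np.fmax(m, half_characteristic_matrix(y, x, B, params.c).T)
    return np.clip(m, 0.0, 1.0)  # guard float overshoot at exactly-functional data


def mine_stats(
    x: np.ndarray, y: np.ndarray, params: MineParams = MineParams()
) -> dict[str, float]:
    """MIC, TIC (mean of characteristic-matrix entries) and the raw TIC sum."""
    m = characteristic_matrix(x, y, params)
    vals = m[np.isfinite(m)]
    if vals.size == 0:
        raise ValueError("grid budget admits no valid shapes; increase n or alpha")
    return {
        "mic": float(vals.max()),
        "tic": float(vals.mean()),
        "tic_sum": float(vals.sum()),
        "n_shapes": int(vals.size),
    }


def mic_tic(
    x: np.ndarray, y: np.ndarray, params: MineParams = MineParams()
) -> tuple[float, float]:
    """(MIC, TIC) of a pair of vectors; both lie in [0, 1]."""
    s = mine_stats(x, y, params)
    return s["mic"], s["tic"]


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; raises if either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("pearson_r2 undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def screen(
    expr: pd.DataFrame,
    ages: np.ndarray,
    threshold: float = 0.7,
    params: MineParams = MineParams(),
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Screen every gene's expression against age by the dual MIC/TIC rule.

    Parameters
    ----------
    expr : genes x samples expression matrix (typically batch-corrected
        log-scale or CPM values); rows are genes.
    ages : chronological age per sample, aligned with ``expr`` columns.
    threshold : shared cutoff applied to both MIC and TIC (default 0.7),
        inclusive unless ``strict``.
    strict : require MIC and TIC strictly greater than the threshold.

    Returns the association table (one row per gene: mic, tic, pearson_r2,
    nonlinearity = mic - pearson_r2, passes) sorted by MIC descending, and
    the list of passing gene ids.
    """
    ages = np.asarray(ages, dtype=np.float64)
    if expr.shape[1] != ages.shape[0]:
        raise ValueError(
            f"expression has {expr.shape[1]} samples but {ages.shape[0]} ages given"
        )
    records = []
    values = expr.to_numpy(dtype=np.float64)
    for gi, gene in enumerate(expr.index):
        v = values[gi]
        if np.all(v == v[0]):
            # constant gene: no association measurable
            records.append((gene, 0.0, 0.0, np.nan, np.nan, False))
            continue
        s = mine_stats(v, ages, params)
        r2 = pearson_r2(v, ages)
        if strict:
            passes = s["mic"] > threshold and s["tic"] > threshold
        else:
            passes = s["mic"] >= threshold and s["tic"] >= threshold
        records.append((gene, s["mic"], s["tic"], r2, s["mic"] - r2, passes))
    table = pd.DataFrame.from_records(
        records,
        columns=["gene_id", "mic", "tic", "pearson_r2", "nonlinearity", "passes"],
    ).set_index("gene_id")
    table = table.sort_values("mic", ascending=False, kind="stable")
    selected = table.index[table["passes"].astype(bool)].tolist()
    return table, selected
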