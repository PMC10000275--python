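"""Parametric empirical-Bayes batch correction (the ComBat model) and PCA diagnostics.

The model assumes, per gene g, sample j in batch i:

    Y_gij = alpha_g + X beta_g + gamma_ig + delta_ig * eps_gij

Location (gamma) and scale (delta^2) batch effects are estimated gene-wise,
shrunk toward batch-level normal / inverse-gamma priors whose hyperparameters
come from method-of-moments fits across genes, and removed. Correction is
additive, so it is meant for roughly Gaussian data: apply it to log2(CPM + 1)
(see ``combat_cpm``) rather than raw counts or CPM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BatchModel", "combat", "combat_cpm", "pca_diagnostic"]


@dataclass
class BatchModel:
    """Fitted ComBat parameters (all per-gene arrays aligned with the input rows)."""

    batches: list
    grand_mean: np.ndarray  # alpha-hat per gene
    beta: np.ndarray | None  # covariate coefficients (q x genes) or None
    pooled_var: np.ndarray  # sigma^2-hat per gene
    gamma_hat: np.ndarray  # raw location effects (batches x genes)
    delta2_hat: np.ndarray  # raw scale effects (batches x genes)
    gamma_star: np.ndarray  # EB-shrunk locations
    delta2_star: np.ndarray  # EB-shrunk scales
    gamma_bar: np.ndarray  # prior mean per batch
    t2: np.ndarray  # prior variance per batch
    a_prior: np.ndarray  # inverse-gamma shape per batch
    b_prior: np.ndarray  # inverse-gamma scale per batch
    n_iter: list[int] | None = None
    skipped_genes: list | None = None

    def report(self) -> str:
        lines = ["ComBat batch model", f"batches: {', '.join(map(str, self.batches))}"]
        for i, b in enumerate(self.batches):
            lines.append(
                f"  batch {b}: gamma_bar={self.gamma_bar[i]:+.4f} t2={self.t2[i]:.4f} "
                f"a={self.a_prior[i]:.4f} b={self.b_prior[i]:.4f}"
            )
        if self.skipped_genes:
            lines.append(f"zero-variance genes passed through: {len(self.skipped_genes)}")
        return "\n".join(lines)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _eb_iterate(sdat, g_hat, d_hat, g_bar, t2, a, b, tol, max_iter):
    """Iterate the EB conditional updates for one batch until convergence."""
    n = sdat.shape[1]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = max(
                np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                np.max(np.abs(d_new - d_old) / np.abs(d_old)),
            )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old, it


def combat(
    expr: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, BatchModel | None]:
    """Remove batch location/scale effects from a genes x samples real matrix.

    ``batch`` maps sample id -> batch label. ``covariates``, if given, is a
    numeric samples x q design of biological signal to protect (e.g. age).
    Deterministic; returns the corrected matrix and the fitted BatchModel.
    A single batch label is a no-op (nothing to remove). Zero-variance genes
    are passed through unadjusted with a warning.
    """
    batch = pd.Series(batch).reindex(expr.columns)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    levels = sorted(batch.unique(), key=str)
    if len(levels) == 1:
        return expr.copy(), None
    sizes = batch.value_counts()
    tiny = sizes.index[sizes < 2]
    if len(tiny):
        raise ValueError(
            f"batch {tiny[0]!r} has a single sample; merge it with another batch or drop it"
        )

    Y = expr.to_numpy(dtype=np.float64)
    G, N = Y.shape
    onehot = np.stack([(batch == b).to_numpy(float) for b in levels], axis=1)
    X = onehot
    q = 0
    if covariates is not None:
        C = covariates.reindex(expr.columns).to_numpy(dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        q = C.shape[1]
        X = np.hstack([onehot, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariates are confounded with batch (design not full rank)")

    # gene-wise least squares for batch means and covariate coefficients
    B_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (nb+q) x G
    n_sizes = np.array([sizes[b] for b in levels], dtype=float)
    grand = (n_sizes / N) @ B_hat[: len(levels)]
    fitted = (X @ B_hat).T
    pooled = ((Y - fitted) ** 2).mean(axis=1)

    ok = pooled > 1e-12  # numerically constant genes cannot be standardized
    skipped = list(expr.index[~ok])
    if skipped:
        warnings.warn(f"{len(skipped)} zero-variance genes passed through unadjusted")

    stand_mean = np.tile(grand[:, None], (1, N))
    beta = None
    if q:
        beta = B_hat[len(levels) :]
        stand_mean = stand_mean + (X[:, len(levels) :] @ beta).T

    sd = np.sqrt(pooled[ok])
    Z = (Y[ok] - stand_mean[ok]) / sd[:, None]

    nb = len(levels)
    g_hat = np.empty((nb, ok.sum()))
    d_hat = np.empty((nb, ok.sum()))
    for i, b in enumerate(levels):
        cols = (batch == b).to_numpy()
        g_hat[i] = Z[:, cols].mean(axis=1)
        d_hat[i] = Z[:, cols].var(axis=1, ddof=1)
    g_bar = g_hat.mean(axis=1)
    t2 = g_hat.var(axis=1, ddof=1)
    m = d_hat.mean(axis=1)
    s2 = d_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_star = np.empty_like(g_hat)
    d_star = np.empty_like(d_hat)
    iters = []
    adjusted = Z.copy()
    for i, b in enumerate(levels):
        cols = (batch == b).to_numpy()
        gs, ds, it = _eb_iterate(
            Z[:, cols], g_hat[i], d_hat[i], g_bar[i], t2[i], a_prior[i], b_prior[i], tol, max_iter
        )
        g_star[i], d_star[i] = gs, ds
        iters.append(it)
        adjusted[:, cols] = (Z[:, cols] - gs[:, None]) / np.sqrt(ds)[:, None]

    out = Y.copy()
    out[ok] = adjusted * sd[:, None] + stand_mean[ok]
    model = BatchModel(
        batches=levels,
        grand_mean=grand,
        beta=beta,
        pooled_var=pooled,
        gamma_hat=g_hat,
        delta2_hat=d_hat,
        gamma_star=g_star,
        delta2_star=d_star,
        gamma_bar=g_bar,
        t2=t2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iter=iters,
        skipped_genes=skipped,
    )
    return pd.DataFrame(out, index=expr.index, columns=expr.columns), model


def combat_cpm(
    cpm_matrix: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    keep_log_scale: bool = True,
    **kwargs,
) -> tuple[pd.DataFrame, BatchModel | None]:
    """ComBat on log2(CPM + 1); the additive scale the model assumes.

    With ``keep_log_scale`` the corrected log2(CPM + 1) matrix is returned
    (the scale used downstream for screening and modeling); otherwise values
    are mapped back to the CPM scale by 2**y - 1, floored at zero.
    """
    logged = np.log2(cpm_matrix + 1.0)
    corrected, model = combat(logged, batch, covariates=covariates, **kwargs)
    if keep_log_scale:
        return corrected, model
    back = np.maximum(2.0**corrected - 1.0, 0.0)
    return back, model


def pca_diagnostic(
    expr: pd.DataFrame, meta: pd.DataFrame, grouping=None
) -> tuple[pd.DataFrame, dict]:
    """Sample scores on the first two principal components, labeled by batch.

    Returns the score table (PC1, PC2, batch, age_group) and a summary dict
    with the variance fractions of PC1/PC2 and the share of PC1 variance
    explained by batch label (R^2 of a one-way fit) -- the quantity to compare
    before and after correction. Identical samples give a degenerate
    decomposition, reported via ``summary['degenerate']`` instead of failing.
    """
    if expr.shape[1] < 3:
        raise ValueError("PCA diagnostic needs at least 3 samples")
    Y = expr.to_numpy(dtype=np.float64)
    centered = (Y - Y.mean(axis=1, keepdims=True)).T  # samples x genes
    total_var = float((centered**2).sum())
    if total_var == 0.0:
        scores = pd.DataFrame(0.0, index=expr.columns, columns=["PC1", "PC2"])
        summary = {"degenerate": True, "pc1_var": 0.0, "pc2_var": 0.0, "pc1_batch_r2": np.nan}
    else:
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        scores = pd.DataFrame(
            u[:, :2] * s[:2], index=expr.columns, columns=["PC1", "PC2"]
        )
        pc1 = scores["PC1"].to_numpy()
        b = meta.loc[expr.columns, "batch"]
        sst = ((pc1 - pc1.mean()) ** 2).sum()
        ssw = sum(
            ((pc1[(b == lev).to_numpy()] - pc1[(b == lev).to_numpy()].mean()) ** 2).sum()
            for lev in b.unique()
        )
        summary = {
            "degenerate": False,
            "pc1_var": float(s[0] ** 2 / total_var),
            "pc2_var": float(s[1] ** 2 / total_var) if len(s) > 1 else 0.0,
            "pc1_batch_r2": float(1.0 - ssw / sst) if sst > 0 else np.nan,
        }
    scores["batch"] = meta.loc[expr.columns, "batch"].to_numpy()
    if grouping is not None:
        scores["age_group"] = grouping.assign(meta.loc[expr.columns, "age"]).to_numpy()
    return scores, summary
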