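"""Screen-level statistics: PC correction, robust null, z/p/q, calls.

Fold-change variation that is shared across protein screens (carry-over,
batch and pool effects, ionisation drift) is not specific to any
protein-metabolite pair.  It is removed by subtracting the top principal
components of the cross-protein fold-change matrix ("corrected fold
change").  Each metabolite then gets a no-signal model from its corrected
fold changes across all screens - centre = median, spread = SD
extrapolated from the 25-75% quantiles - which true interactions in the
tails cannot inflate.  Pair z scores against that null give two-sided
normal p values, FDR-adjusted with Storey q values within one protein
screen's metabolite family; a pair is called significant when p < 0.05 and
q < 0.1.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SD_PER_IQR",
    "CorrectionReport",
    "NullModel",
    "remove_principal_components",
    "robust_null",
    "z_and_p",
    "storey_pi0",
    "storey_q",
    "call_interactions",
    "score_screen",
    "plot_volcano",
]

#: IQR of a normal distribution in units of its SD: 2 * Phi^-1(0.75).
SD_PER_IQR = float(2.0 * sps.norm.ppf(0.75))  # 1.3489795...

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_Q_THRESHOLD = 0.1
DEFAULT_K_COMPONENTS = 3
DEFAULT_MIN_NULL_N = 8


@dataclasses.dataclass(frozen=True)
class CorrectionReport:
    """Bookkeeping for one principal-component removal."""

    k_removed: int
    variance_fraction_removed: float
    singular_values: np.ndarray


@dataclasses.dataclass(frozen=True)
class NullModel:
    """Per-metabolite no-signal model (robust centre and spread)."""

    metabolite_id: str
    center: float
    spread: float
    n: int


def remove_principal_components(
    matrix: pd.DataFrame, k: int = DEFAULT_K_COMPONENTS
) -> tuple[pd.DataFrame, CorrectionReport]:
    """Subtract the rank-k truncated SVD of the column-centred matrix.

    Rows are protein screens, columns are metabolites.  Columns are
    mean-centred, the top-k reconstruction is subtracted, and the column
    means are added back, so metabolite-level offsets survive for the
    downstream null model.  Missing cells are imputed to the column mean
    for the decomposition and restored to missing afterwards.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    X = matrix.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    if k == 0:
        report = CorrectionReport(0, 0.0, np.zeros(0))
        return matrix.copy(), report
    if k >= min(n_rows, n_cols):
        raise ValueError(f"k={k} must be < min(n_rows, n_cols)={min(n_rows, n_cols)}")
    if n_rows < k + 1:
        raise ValueError(f"need at least k+1={k + 1} rows, got {n_rows}")

    mask = ~np.isfinite(X)
    col_mean = np.nanmean(np.where(mask, np.nan, X), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    Xi = np.where(mask, col_mean[None, :], X)
    centered = Xi - col_mean[None, :]

    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    recon = (U[:, :k] * s[:k]) @ Vt[:k]
    corrected = centered - recon + col_mean[None, :]
    corrected[mask] = np.nan

    total = float((s**2).sum())
    frac = float((s[:k] ** 2).sum() / total) if total > 0 else 0.0
    report = CorrectionReport(k, frac, s.copy())
    return pd.DataFrame(corrected, index=matrix.index, columns=matrix.columns), report


def robust_null(
    values, metabolite_id: str = "", min_n: int = DEFAULT_MIN_NULL_N
) -> NullModel:
    """No-signal model for one metabolite across protein screens.

    centre = median; spread = (Q75 - Q25) / (2 * Phi^-1(0.75)), with
    quantiles by linear interpolation between order statistics.  The
    quantile-based spread is what makes the null robust to the genuine
    interactions sitting in the tails of the distribution.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < min_n:
        raise ValueError(
            f"metabolite {metabolite_id!r}: only {vals.size} values, "
            f"need >= {min_n} for a null model"
        )
    q25, q50, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError(f"metabolite {metabolite_id!r}: zero IQR, null undefined")
    return NullModel(metabolite_id, float(q50), float(iqr / SD_PER_IQR), int(vals.size))


def z_and_p(corrected_log2fc: float, null: NullModel) -> tuple[float, float]:
    """z against the no-signal model and its two-sided normal p value."""
    z = (float(corrected_log2fc) - null.center) / null.spread
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def storey_pi0(pvalues: np.ndarray, lambda_: float = 0.5, smoother: bool = False) -> float:
    """Estimate the null proportion pi0 from the flat right tail of p.

    Point estimate: ``#{p > lambda} / (m * (1 - lambda))``, capped at 1.
    With ``smoother=True`` the estimate is taken from a cubic smoothing of
    pi0(lambda) over a lambda grid evaluated at the grid maximum.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return 1.0
    if smoother:
        from scipy.interpolate import UnivariateSpline

        lams = np.arange(0.05, 0.96, 0.05)
        pi0s = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lams])
        spl = UnivariateSpline(lams, pi0s, k=3)
        pi0 = float(spl(lams[-1]))
    else:
        if not (0 <= lambda_ < 1):
            raise ValueError("lambda must be in [0, 1)")
        pi0 = float((p > lambda_).sum() / (m * (1.0 - lambda_)))
    pi0 = min(pi0, 1.0)
    if pi0 <= 0:
        warnings.warn(
            "pi0 estimate <= 0 (all p values small); falling back to pi0 = 1/m",
            RuntimeWarning,
        )
        pi0 = 1.0 / m
    return pi0


def storey_q(
    pvalues,
    lambda_: float = 0.5,
    pi0: float | None = None,
    smoother: bool = False,
) -> np.ndarray:
    """Storey q values for a family of p values.

    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over the ascending order
    statistics; output is returned in the input order.  With ``pi0`` forced
    to 1 this is exactly the Benjamini-Hochberg adjusted p value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = storey_pi0(p, lambda_=lambda_, smoother=smoother)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    return out


def call_interactions(
    results: pd.DataFrame,
    p_thresh: float = DEFAULT_P_THRESHOLD,
    q_thresh: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Apply the significance rule and rank by |z| descending.

    A pair is significant iff ``p < p_thresh`` and ``q < q_thresh``.
    """
    out = results.copy()
    out["significant"] = (out["p"] < p_thresh) & (out["q"] < q_thresh)
    out["significant"] = out["significant"].fillna(False)
    order = out["z"].abs().sort_values(ascending=False, kind="mergesort").index
    return out.loc[order].reset_index(drop=True)


def score_screen(
    matrix: pd.DataFrame,
    k_components: int = DEFAULT_K_COMPONENTS,
    min_null_n: int = DEFAULT_MIN_NULL_N,
    lambda_: float = 0.5,
    pi0: float | None = None,
    smoother: bool = False,
    p_thresh: float = DEFAULT_P_THRESHOLD,
    q_thresh: float = DEFAULT_Q_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, CorrectionReport]:
    """PC correction, per-metabolite nulls, z/p/q and calls for a screen matrix.

    ``matrix``: protein screens x metabolites, cells = mean log2 fold
    change.  q values are computed within one protein screen's metabolite
    family.  Metabolites whose null model is undefined (zero IQR or too few
    screens) are excluded with a warning and carry NaN statistics.

    Returns ``(results, corrected_matrix, correction_report)`` where
    ``results`` has one row per pair, ranked by |z| descending.
    """
    corrected, report = remove_principal_components(matrix, k_components)

    centers = np.full(corrected.shape[1], np.nan)
    spreads = np.full(corrected.shape[1], np.nan)
    excluded = []
    for j, met in enumerate(corrected.columns):
        try:
            null = robust_null(corrected.iloc[:, j].to_numpy(), str(met), min_null_n)
        except ValueError:
            excluded.append(str(met))
            continue
        centers[j] = null.center
        spreads[j] = null.spread
    if excluded:
        warnings.warn(
            f"{len(excluded)} metabolite(s) excluded (undefined null model): "
            + ", ".join(excluded[:5])
            + ("..." if len(excluded) > 5 else ""),
            RuntimeWarning,
        )

    C = corrected.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        Z = (C - centers[None, :]) / spreads[None, :]
    P = 2.0 * sps.norm.sf(np.abs(Z))
    P = np.minimum(P, 1.0)

    raw = matrix.to_numpy(dtype=float)
    n_prot, n_met = C.shape
    Q = np.full_like(P, np.nan)
    for i in range(n_prot):
        valid = np.isfinite(P[i])
        if valid.any():
            Q[i, valid] = storey_q(
                P[i, valid], lambda_=lambda_, pi0=pi0, smoother=smoother
            )

    results = pd.DataFrame(
        {
            "protein_id": np.repeat(matrix.index.to_numpy(), n_met),
            "metabolite_id": np.tile(matrix.columns.to_numpy(), n_prot),
            "log2fc": raw.ravel(),
            "corrected_log2fc": C.ravel(),
            "z": Z.ravel(),
            "p": P.ravel(),
            "q": Q.ravel(),
        }
    )
    results = call_interactions(results, p_thresh=p_thresh, q_thresh=q_thresh)
    return results, corrected, report


def plot_volcano(results: pd.DataFrame, path=None, ax=None):
    """Volcano plot: corrected log2 fold change vs -log10 p, calls highlighted."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = results.dropna(subset=["p"])
    sig = ok["significant"].astype(bool)
    ax.scatter(
        ok.loc[~sig, "corrected_log2fc"],
        -np.log10(ok.loc[~sig, "p"]),
        s=8,
        c="0.7",
        label="not significant",
    )
    ax.scatter(
        ok.loc[sig, "corrected_log2fc"],
        -np.log10(ok.loc[sig, "p"]),
        s=12,
        c="crimson",
        label="significant",
    )
    ax.set_xlabel("log2(corrected fold change)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
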