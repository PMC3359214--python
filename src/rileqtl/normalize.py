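"""Two-colour array normalization and parental differential-expression calls.

Pipeline per array: drop flagged spots, remove the intensity-dependent dye
bias by robust local regression of M on A, then subtract each print-tip
block's median log-ratio. Dye-swap pairs are averaged with the sign flip,
and the two co-hybridized samples' intensities are recovered as (2A - M)/2
and (2A + M)/2 — the former belonging to the sample labelled green on the
first array. Finally every array is shifted to a common mean intensity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import ExpressionMatrix, RileqtlError

SPOT_COLUMNS = ["spot", "probe", "block", "log2_red", "log2_green", "flag"]


def normalize_array(
    spots: pd.DataFrame, span: float = 0.3, robust_iters: int = 4
) -> pd.DataFrame:
    """Loess dye-bias and print-tip median correction of one array.

    Returns an MA table (probe, block, M, A). Flagged spots are excluded
    before fitting; at least 20 unflagged spots are required for the local
    regression to have support.
    """
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise RileqtlError(f"spot table missing columns {sorted(missing)}")
    ok = spots[spots["flag"] == "ok"].copy()
    if len(ok) == 0:
        raise RileqtlError("all spots flagged")
    if len(ok) < 20:
        raise RileqtlError(f"only {len(ok)} unflagged spots; need >= 20")
    M = (ok["log2_red"] - ok["log2_green"]).to_numpy(dtype=float)
    A = 0.5 * (ok["log2_red"] + ok["log2_green"]).to_numpy(dtype=float)
    if not (np.isfinite(M).all() and np.isfinite(A).all()):
        raise RileqtlError("non-finite intensity on unflagged spot")
    if np.ptp(A) > 0:
        fit = lowess(M, A, frac=span, it=robust_iters, return_sorted=False)
        M = M - fit
    else:  # constant A: the dye bias reduces to a global shift
        M = M - np.median(M)
    ma = pd.DataFrame({"probe": ok["probe"].to_numpy(), "block": ok["block"].to_numpy(),
                       "M": M, "A": A})
    ma["M"] = ma["M"] - ma.groupby("block")["M"].transform("median")
    return ma.reset_index(drop=True)


def dye_swap_combine(
    array1: pd.DataFrame, array2: pd.DataFrame, green_on_array1: str, other: str
) -> pd.DataFrame:
    """Average a dye-swap pair and split into per-sample intensities.

    Mbar = (M1 - M2)/2 and Abar = (A1 + A2)/2 cancel the dye bias; the
    green-on-array-1 sample's intensity is (2 Abar - Mbar)/2 and the other
    sample's is (2 Abar + Mbar)/2. Returns a frame indexed by probe with one
    intensity column per sample plus Mbar/Abar.
    """
    a1 = array1.groupby("probe")[["M", "A"]].mean()
    a2 = array2.groupby("probe")[["M", "A"]].mean()
    if not a1.index.equals(a2.index):
        raise RileqtlError("probe sets differ between the dye-swap arrays")
    if not green_on_array1 or not other:
        raise RileqtlError("pairing must name both samples")
    mbar = 0.5 * (a1["M"] - a2["M"])
    abar = 0.5 * (a1["A"] + a2["A"])
    out = pd.DataFrame(
        {
            green_on_array1: (2.0 * abar - mbar) / 2.0,
            other: (2.0 * abar + mbar) / 2.0,
            "Mbar": mbar,
            "Abar": abar,
        }
    )
    return out


def between_array_scale(expr: ExpressionMatrix, target: float = 8.5) -> ExpressionMatrix:
    """Shift each line (array) so its mean intensity equals ``target`` exactly."""
    vals = expr.values
    means = vals.mean(axis=0, skipna=True)
    if means.isna().any():
        empty = list(means.index[means.isna()])
        raise RileqtlError(f"line(s) with no values: {empty}")
    return ExpressionMatrix(vals - means + target)


def differential_expression(
    log_ratios: pd.DataFrame,
    trim: tuple[float, float] = (0.025, 0.975),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test per gene with a trimmed-variance moderation scheme.

    ``log_ratios`` is gene x biological replicate (dye-swaps already
    averaged). Genes whose variance falls outside the trimming quantiles are
    excluded from the shrinkage pool; pool members use a 50:50 blend of their
    own and the pooled mean variance, excluded genes their own variance.
    Two-sided p from t with df = n - 1; Bonferroni multiplier = number of
    genes; call = adjusted p < alpha.
    """
    n = log_ratios.shape[1]
    if n < 2:
        raise RileqtlError("need >= 2 biological replicates")
    means = log_ratios.mean(axis=1).to_numpy()
    variances = log_ratios.var(axis=1, ddof=1).to_numpy()
    m = len(means)

    lo, hi = np.quantile(variances, trim) if m > 1 else (variances[0], variances[0])
    in_pool = (variances >= lo) & (variances <= hi)
    pooled = variances[in_pool].mean() if in_pool.any() else variances.mean()
    s2 = np.where(in_pool, 0.5 * variances + 0.5 * pooled, variances)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(s2 / n)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = s2 <= 0
    t = np.where(zero_var & (means == 0), 0.0, t)
    p = np.where(zero_var, np.where(means == 0, 1.0, 0.0), p)
    p_adj = np.minimum(p * m, 1.0)
    return pd.DataFrame(
        {
            "mean_log2_ratio": means,
            "t": t,
            "p": p,
            "p_bonferroni": p_adj,
            "significant": p_adj < alpha,
        },
        index=log_ratios.index,
    )
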