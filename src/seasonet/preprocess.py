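"""Transformations applied before correlation analysis.

The pipeline order is: per-metabolite mean normalization over the monthly
time-point means, arcsine square-root transform of trait percentages, then
pareto scaling of every variable.  A 0-1 min-max scaler (for heatmap-style
summaries) and a fold-change helper for contrasts between seed states round
out the module.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def mean_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each column (metabolite) by its own mean across rows.

    The rows are the time-point measurements (monthly means in the default
    pipeline).  Output column means are exactly 1.  Missing values are
    ignored when computing the mean and propagate unchanged.
    """
    means = matrix.mean(axis=0, skipna=True)
    bad = means.index[(~np.isfinite(means)) | (means == 0)]
    if len(bad):
        raise ValueError(
            f"mean normalization undefined (zero or undefined mean) for: {list(bad)}"
        )
    return matrix / means


def arcsin_transform(percentage):
    """Angular transform of a percentage: arcsin(sqrt(p/100)), in radians.

    The standard variance stabilizer for percentage data; maps [0, 100]
    onto [0, pi/2] and is strictly monotone.  Accepts scalars or arrays.
    """
    arr = np.asarray(percentage, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    out = np.arcsin(np.sqrt(arr / 100.0))
    return out.item() if np.isscalar(percentage) or arr.ndim == 0 else out


def pareto_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pareto scaling: center each column and divide by sqrt(sd).

    sd is the sample standard deviation (n-1 denominator).  Compared with
    unit-variance scaling this compresses large fold changes less: the
    scaled column retains variance equal to sd(x) rather than 1.
    """
    means = matrix.mean(axis=0, skipna=True)
    sds = matrix.std(axis=0, ddof=1, skipna=True)
    bad = sds.index[(~np.isfinite(sds)) | (sds == 0)]
    if len(bad):
        raise ValueError(f"pareto scaling undefined (zero variance) for: {list(bad)}")
    return (matrix - means) / np.sqrt(sds)


def minmax_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column onto [0, 1] as used for heatmap display.

    Constant columns carry no contrast; they are mapped to 0.5 everywhere
    and reported through a warning so the flat entries are visible.
    """
    mins = matrix.min(axis=0, skipna=True)
    maxs = matrix.max(axis=0, skipna=True)
    span = maxs - mins
    flat = span.index[span == 0]
    if len(flat):
        warnings.warn(
            f"constant entries mapped to 0.5 in min-max scaling: {list(flat)}",
            UserWarning, stacklevel=2,
        )
        logger.warning("min-max scaling: constant entries %s set to 0.5", list(flat))
    out = (matrix - mins) / span.replace(0, np.nan)
    for col in flat:
        out[col] = np.where(matrix[col].isna(), np.nan, 0.5)
    return out


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of two group means, e.g. germinated over dry seeds.

    Values > 1 indicate accumulation in group a relative to group b.
    """
    if mean_b <= 0:
        raise ValueError("fold change undefined: reference mean must be positive")
    return float(mean_a) / float(mean_b)


def drop_sparse_metabolites(matrix: pd.DataFrame,
                            max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Drop metabolites missing in more than *max_missing_fraction* of rows.

    Remaining missing values are handled pairwise-complete downstream.
    Dropped columns are logged.
    """
    frac = matrix.isna().mean(axis=0)
    drop = frac.index[frac > max_missing_fraction]
    if len(drop):
        logger.warning("dropping %d metabolites missing in >%d%% of time points: %s",
                       len(drop), int(100 * max_missing_fraction), list(drop))
    return matrix.drop(columns=list(drop))
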