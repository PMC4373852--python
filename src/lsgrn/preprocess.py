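"""Missing-value interpolation and per-gene normalization.

Interpolation is linear along the observation axis within each gene row;
leading/trailing gaps take the nearest observed value.  Normalization is a
per-gene z-score with sample (n-1) standard deviation, matching the
covariance convention used by the mutual-information estimator.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


def interpolate_missing(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Fill NaN cells by linear interpolation within each gene row.

    Observed values are never altered.  A gene row with no observed value
    at all cannot be reconstructed and raises :class:`PreprocessError`.
    """
    values = expr.values.copy()
    idx = np.arange(expr.n_obs, dtype=float)
    for i, row in enumerate(values):
        missing = np.isnan(row)
        if not missing.any():
            continue
        if missing.all():
            raise PreprocessError(f"gene {expr.gene_ids[i]!r} has no observed values")
        # np.interp clamps to the boundary values, giving nearest-observed
        # fill for leading/trailing gaps.
        row[missing] = np.interp(idx[missing], idx[~missing], row[~missing])
    return expr.with_values(values)


def normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row (mean 0, sample sd 1).

    Constant rows carry no relational information; they map to all-zero
    with a warning rather than dividing by zero.
    """
    values = expr.values
    if np.isnan(values).any():
        raise PreprocessError("normalize requires a complete matrix; interpolate first")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        for gid in np.asarray(expr.gene_ids)[constant]:
            logger.warning("gene %s is constant; normalized to all-zero", gid)
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (values - mean) / safe_sd
    out[constant, :] = 0.0
    return expr.with_values(out)
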