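"""Pairwise mutual information under the Gaussian assumption.

For jointly Gaussian variables the mutual information has the closed
covariance-determinant form

    I(X, Y) = 0.5 * log( |C(X)| * |C(Y)| / |C(X, Y)| )        [nats]

with sample (n-1) covariances, which reduces to -0.5*log(1 - r^2) for the
sample Pearson correlation r.  The MI of a pair with singular joint
covariance (perfect collinearity, or a constant profile) is unbounded; such
pairs carry a +inf sentinel so that downstream thresholding still works.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class MIMatrix:
    """Symmetric gene x gene mutual information (nats).

    The diagonal is not a meaningful quantity and is stored as 0; every
    consumer treats only off-diagonal entries as MI values.
    """

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("MI matrix shape does not match gene count")

    def dump_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(self.gene_ids) + "\n")
            for gid, row in zip(self.gene_ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def mi_pair(x, y) -> float:
    """Gaussian MI (nats) between two equal-length sample vectors.

    Returns +inf with a warning when the joint sample covariance is
    singular (|C(X,Y)| <= 0).  Requires n >= 3 finite observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = dx @ dx / (n - 1)
    vy = dy @ dy / (n - 1)
    cxy = dx @ dy / (n - 1)
    det = vx * vy - cxy * cxy
    if vx <= 0 or vy <= 0 or det <= 0:
        logger.warning("singular joint covariance; MI sentinel +inf")
        return np.inf
    return max(0.5 * np.log(vx * vy / det), 0.0)


def pairwise_mi(expr: ExpressionMatrix) -> MIMatrix:
    """MI between every unordered gene pair, vectorized.

    Singular pairs (constant genes, perfectly collinear profiles) become
    +inf sentinels rather than aborting the matrix.
    """
    X = expr.values
    if X.shape[1] < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(X).any():
        raise ValueError("expression matrix contains missing values; interpolate first")
    n = X.shape[1]
    centered = X - X.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (n - 1)
    var = np.diag(cov).copy()
    vprod = np.outer(var, var)
    det = vprod - cov * cov
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = 0.5 * np.log(vprod / det)
    singular = (det <= 0) | (vprod <= 0)
    if singular[~np.eye(len(var), dtype=bool)].any():
        logger.warning(
            "%d gene pairs with singular joint covariance; MI sentinel +inf",
            int(singular[~np.eye(len(var), dtype=bool)].sum()) // 2,
        )
    mi[singular] = np.inf
    np.maximum(mi, 0.0, out=mi)
    np.fill_diagonal(mi, 0.0)
    return MIMatrix(list(expr.gene_ids), mi)
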