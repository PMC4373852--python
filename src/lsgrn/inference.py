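"""Per-module regulatory inference via linear-ODE least squares.

Within module C_i the dynamics of target gene j are modelled as

    dx_j/dt = sum_k a_jk x_k(t) + sum_l b_jl y_l(t)

with x_k the module's own genes and y_l the external candidate regulators
admitted through top-ranked cross-module MI pairs.  The derivative is
replaced by the first-order difference d_j(t_m) = x_j(t_m) - x_j(t_{m-1}),
giving one linear system H_i P = D per target.  Coefficients are estimated
by least squares (QR with column pivoting for ill-conditioned designs,
normal equations solved by Gaussian elimination with partial pivoting
otherwise) and thresholded by magnitude into directed edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .decomposition import ModulePartition
from .io import ExpressionMatrix, RunConfig
from .mutual_info import MIMatrix

logger = logging.getLogger(__name__)


class InferenceError(RuntimeError):
    pass


@dataclass
class CandidateSet:
    """External regressors for one module (the candidate set C-i)."""

    module_index: int
    external_genes: list[str]


@dataclass
class LinearSystem:
    """Design H_i = (X_i | Y_i) and difference response D_i^j for one target."""

    design: np.ndarray
    response: np.ndarray
    target_gene: str
    column_gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.design.shape[1] != len(self.column_gene_ids):
            raise ValueError("design column count does not match gene labels")
        if self.design.shape[0] != self.response.shape[0]:
            raise ValueError("design row count does not match response length")


@dataclass
class CoefficientVector:
    values: np.ndarray
    target_gene: str
    column_gene_ids: list[str]


@dataclass
class InferredNetwork:
    """Weighted directed adjacency plus its theta-binarized edge set.

    ``weights`` maps (regulator, target) to the estimated coefficient;
    self-regulation is estimated during the fit but never reported as an
    edge.  ``sources`` records which module produced each weight, which
    makes assembly of overlapping fragments deterministic.
    """

    weights: dict = field(default_factory=dict)
    sources: dict = field(default_factory=dict)
    theta: float = 0.0

    @property
    def binary_edges(self) -> set:
        return self.edges_at(self.theta)

    def edges_at(self, theta: float) -> set:
        return {e for e, w in self.weights.items() if abs(w) > theta}


def select_candidate_set(
    i: int, part: ModulePartition, mi: MIMatrix, fraction: float
) -> CandidateSet:
    """Top cross-module MI pairs define module i's external regulators.

    For every other module C_m, all cross pairs (x in C_i, y in C_m) are
    ranked by MI descending (ties by lexicographic gene IDs) and the top
    ceil(fraction * count) pairs kept; the candidate set is the union of
    the y endpoints in first-appearance rank order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    order = {g: k for k, g in enumerate(mi.gene_ids)}
    own = part.modules[i]
    own_idx = [order[g] for g in own]
    external: list[str] = []
    seen: set[str] = set()
    for m, other in enumerate(part.modules):
        if m == i:
            continue
        pairs = [
            (mi.values[xi, order[y]], x, y)
            for x, xi in zip(own, own_idx)
            for y in other
        ]
        # descending MI, ties by lexicographic (x, y)
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        keep = math.ceil(fraction * len(pairs))
        for _, _, y in pairs[:keep]:
            if y not in seen:
                seen.add(y)
                external.append(y)
    return CandidateSet(i, external)


def build_linear_system(
    j: str,
    i: int,
    part: ModulePartition,
    cand: CandidateSet,
    expr: ExpressionMatrix,
) -> LinearSystem:
    """Difference response and time-t regressor design for target gene j.

    Response rows are d_j(t_m) = x_j(t_m) - x_j(t_{m-1}) for m = 2..T;
    the matching design row holds the expression of the module genes
    (partition order) then the candidate genes, all at time t_m.
    """
    if j not in part.modules[i]:
        raise InferenceError(f"target gene {j} is not in module {i}")
    if expr.n_obs < 3:
        raise InferenceError("need at least 3 ordered observations")
    order = {g: k for k, g in enumerate(expr.gene_ids)}
    columns = list(part.modules[i]) + list(cand.external_genes)
    col_idx = [order[g] for g in columns]
    X = expr.values
    design = X[col_idx, 1:].T  # rows: t_2..t_T
    response = np.diff(X[order[j]])
    return LinearSystem(design, response, j, columns)


def solve_coefficients(
    sys: LinearSystem, cond_threshold: float = 1e6, ridge: float = 0.0
) -> CoefficientVector:
    """Least-squares coefficients for one target's linear system.

    The 2-norm condition number of the design decides the branch: above
    ``cond_threshold`` (or non-finite), QR with column pivoting solves the
    least-squares problem directly (minimum-norm on rank deficiency);
    otherwise the normal equations H'H P = H'D are formed and solved by
    Gaussian elimination with partial pivoting.  A singular normal system
    falls back to the QR branch with a warning.  An optional ridge term
    (default 0) regularizes the normal equations.
    """
    H, d = sys.design, sys.response
    if H.shape[1] == 0:
        raise InferenceError(f"empty design for target {sys.target_gene}")
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(H, 2)
    if not np.isfinite(cond) or cond > cond_threshold:
        values = _solve_qr(H, d)
    else:
        gram = H.T @ H
        if ridge > 0:
            gram = gram + ridge * np.eye(H.shape[1])
        try:
            values = scipy.linalg.solve(gram, H.T @ d, assume_a="sym")
            if not np.isfinite(values).all():
                raise np.linalg.LinAlgError("non-finite solution")
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
            logger.warning(
                "normal equations singular for target %s; falling back to QR",
                sys.target_gene,
            )
            values = _solve_qr(H, d)
    return CoefficientVector(values, sys.target_gene, list(sys.column_gene_ids))


def _solve_qr(H: np.ndarray, d: np.ndarray) -> np.ndarray:
    # gelsy = complete orthogonal decomposition via column-pivoted QR;
    # minimum-norm solution on rank deficiency.  The explicit relative
    # rank tolerance makes near-singular directions count as deficient.
    values, *_ = scipy.linalg.lstsq(H, d, cond=1e-10, lapack_driver="gelsy")
    return values


def binarize_coefficients(coef: CoefficientVector, theta: float) -> set:
    """Directed edges (regulator -> target) with |coefficient| > theta.

    Self-regulation is estimated but never reported as an edge; excluded
    coefficients remain available on the weighted network for ROC sweeps.
    """
    return {
        (g, coef.target_gene)
        for g, v in zip(coef.column_gene_ids, coef.values)
        if g != coef.target_gene and abs(v) > theta
    }


def infer_module(
    i: int,
    part: ModulePartition,
    cand: CandidateSet,
    expr: ExpressionMatrix,
    config: RunConfig,
) -> InferredNetwork:
    """Infer the rows of the global network targeting module i's genes.

    Builds, solves and thresholds one linear system per target gene in the
    module.  A failure on one target is logged and skipped, never fatal
    for the module.
    """
    net = InferredNetwork(theta=config.theta)
    for j in part.modules[i]:
        try:
            system = build_linear_system(j, i, part, cand, expr)
            coef = solve_coefficients(system, config.cond_threshold, config.ridge)
        except (InferenceError, np.linalg.LinAlgError) as exc:
            logger.warning("target %s in module %d skipped: %s", j, i, exc)
            continue
        for g, v in zip(coef.column_gene_ids, coef.values):
            if g == j:
                continue
            net.weights[(g, j)] = float(v)
            net.sources[(g, j)] = i
    return net
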