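"""Planted modular networks and linear-ODE expression series for testing.

The generator emulates the sparse, modular structure of real regulatory
networks: genes are split evenly into modules and a fixed number of
directed weights is planted, biased toward intra-module placement.  Weight
magnitudes avoid a dead zone around zero so that a separating coefficient
threshold always exists; the diagonal carries negative self-decay, the
standard first-order degradation term.

Expression follows the implicit-in-regressor recurrence

    x(t) - x(t-1) = A x(t)    i.e.    x(t) = (I - A)^{-1} x(t-1),

which makes the difference model used by the inference stage exactly
well-specified: at zero observation noise the planted coefficients solve
every per-target linear system to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GoldStandard

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


@dataclass
class SyntheticTruth:
    """Planted coefficient matrix A (rows = targets, columns = regulators)."""

    gene_ids: list[str]
    coefficient_matrix: np.ndarray
    module_labels: dict
    seed: int

    @property
    def edges(self) -> set:
        """Directed (regulator, target) pairs for nonzero off-diagonal weights."""
        out = set()
        A = self.coefficient_matrix
        for j, k in zip(*np.nonzero(A)):
            if j != k:
                out.add((self.gene_ids[k], self.gene_ids[j]))
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gold_standard(self) -> GoldStandard:
        return GoldStandard(frozenset(self.edges), frozenset(self.gene_ids))

    def min_edge_weight(self) -> float:
        A = self.coefficient_matrix.copy()
        np.fill_diagonal(A, 0.0)
        nz = np.abs(A[A != 0])
        return float(nz.min()) if nz.size else 0.0


def generate_truth(
    n_genes: int,
    n_modules: int,
    density: float,
    modularity_bias: float = 3.0,
    weight_range: tuple = (0.2, 1.0),
    decay_range: tuple = (0.1, 0.5),
    seed: int = 0,
) -> SyntheticTruth:
    """Plant a sparse modular coefficient matrix.

    ``density`` is the fraction of nonzero off-diagonal entries; the
    planted count is round(density * n * (n-1)), split between intra- and
    inter-module slots in proportion ``modularity_bias`` : 1 per slot.
    Weight magnitudes are uniform on ``weight_range`` (the lower bound is
    the dead zone guaranteeing a separable threshold), signs random.
    Self-decay is planted on the diagonal, uniform negative on
    ``decay_range``; pass ``decay_range=(0, 0)`` for none.
    """
    if not 1 <= n_modules <= n_genes:
        raise ValueError("need n_genes >= n_modules >= 1")
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    if modularity_bias <= 0:
        raise ValueError("modularity_bias must be > 0")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    groups = np.array_split(np.arange(n_genes), n_modules)
    labels = np.empty(n_genes, dtype=int)
    for m, idx in enumerate(groups):
        labels[idx] = m

    same = labels[:, None] == labels[None, :]
    offdiag = ~np.eye(n_genes, dtype=bool)
    intra = np.flatnonzero(same & offdiag)
    inter = np.flatnonzero(~same & offdiag)
    n_slots = intra.size + inter.size
    K = int(round(density * n_slots))
    if K > n_slots:
        raise ValueError("infeasible density")
    w_in = modularity_bias * intra.size
    k_in = int(round(K * w_in / (w_in + inter.size))) if (w_in + inter.size) else 0
    k_in = min(max(k_in, K - inter.size), intra.size, K)
    chosen = np.concatenate([
        rng.choice(intra, size=k_in, replace=False),
        rng.choice(inter, size=K - k_in, replace=False),
    ]).astype(int)

    A = np.zeros((n_genes, n_genes))
    lo, hi = weight_range
    mags = rng.uniform(lo, hi, size=K)
    signs = rng.choice([-1.0, 1.0], size=K)
    A.flat[chosen] = mags * signs
    d_lo, d_hi = decay_range
    if d_hi > 0:
        A[np.diag_indices(n_genes)] = -rng.uniform(d_lo, d_hi, size=n_genes)
    return SyntheticTruth(gene_ids, A, {gene_ids[i]: int(labels[i]) for i in range(n_genes)}, seed)


def simulate_expression(
    truth: SyntheticTruth,
    T: int,
    noise_sd: float = 0.0,
    x0_range: tuple = (0.5, 1.5),
    seed: int = 0,
    divergence_bound: float = 1e6,
) -> ExpressionMatrix:
    """Simulate T ordered observations of the planted dynamics.

    The latent trajectory follows x(t) = (I - A)^{-1} x(t-1) from a random
    positive x0; additive Gaussian observation noise of sd ``noise_sd`` is
    applied afterwards.  If the trajectory diverges past
    ``divergence_bound`` it is rescaled globally (linearity keeps the
    difference model exact) with a warning; non-finite values raise
    :class:`SimulationError`.
    """
    if T < 3:
        raise ValueError("need T >= 3 time points")
    rng = np.random.default_rng(seed)
    n = len(truth.gene_ids)
    A = truth.coefficient_matrix
    M = np.eye(n) - A
    import scipy.linalg

    lu, piv = scipy.linalg.lu_factor(M)
    X = np.empty((n, T))
    X[:, 0] = rng.uniform(*x0_range, size=n)
    rescued = False
    for t in range(1, T):
        X[:, t] = scipy.linalg.lu_solve((lu, piv), X[:, t - 1])
        if not np.isfinite(X[:, t]).all():
            raise SimulationError(
                "trajectory overflow; use smaller weights or shorter series"
            )
        peak = np.abs(X[:, t]).max()
        if peak > 1e100:
            # power-of-two scaling is exact in floats, so the scaled prefix
            # still satisfies the generating recurrence bit-for-bit
            X[:, : t + 1] *= 2.0 ** -int(np.ceil(np.log2(peak)))
            rescued = True
    peak = np.abs(X).max()
    if peak > divergence_bound:
        X *= 2.0 ** int(np.floor(np.log2(divergence_bound / peak)))
        rescued = True
    if rescued:
        logger.warning(
            "divergent trajectory rescaled below %.3g; consider smaller weights",
            divergence_bound,
        )
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    labels = [f"t{t}" for t in range(1, T + 1)]
    return ExpressionMatrix(list(truth.gene_ids), X, labels)
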