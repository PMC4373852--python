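"""Master/worker execution of the full pipeline and deterministic assembly.

The master performs preprocessing, MI computation, decomposition and
candidate selection, then dispatches per-module inference to a worker pool
and assembles the fragments.  Fragments are keyed by module index, so the
assembled network is identical for any worker count and any completion
order — the asynchrony contract.  The pool is an in-process thread pool
(the numerical kernels release the GIL); the algorithmic content does not
depend on the messaging layer.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor, as_completed
from dataclasses import dataclass

import numpy as np

from . import decomposition, evaluation, inference, mutual_info, preprocess
from .decomposition import DecompositionError, ModulePartition
from .evaluation import EvalResult
from .inference import InferredNetwork
from .io import ExpressionMatrix, GoldStandard, RunConfig, read_expression, read_gold_standard

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the failed stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    network: InferredNetwork
    partition: ModulePartition
    mi: mutual_info.MIMatrix
    config: RunConfig
    evaluation: EvalResult | None = None


def assign_modules(module_sizes, workers: int) -> dict:
    """Balance modules over workers: largest module first, to the least
    loaded worker (ties -> lowest worker index).  Returns
    {worker_index: [module_index, ...]}; every module appears exactly once.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    assignment: dict[int, list[int]] = {w: [] for w in range(workers)}
    loads = [0] * workers
    order = sorted(range(len(module_sizes)), key=lambda m: (-module_sizes[m], m))
    for m in order:
        w = min(range(workers), key=lambda k: (loads[k], k))
        assignment[w].append(m)
        loads[w] += module_sizes[m]
    return assignment


def assemble(fragments) -> InferredNetwork:
    """Union per-module fragments into the global network.

    *fragments* maps module index -> fragment (or is an iterable of
    (module_index, fragment) pairs).  When two fragments report the same
    directed pair — possible through candidate sets — the coefficient of
    larger magnitude wins; on an exact tie the one from the lower module
    index.  The rule depends only on the keyed contents, never on
    arrival order, and is associative.
    """
    items = fragments.items() if hasattr(fragments, "items") else list(fragments)
    merged = InferredNetwork()
    theta = None
    for idx, frag in sorted(items, key=lambda kv: kv[0]):
        if frag is None:
            raise StageError("assemble", f"missing fragment for module {idx}")
        theta = frag.theta if theta is None else theta
        for edge, w in frag.weights.items():
            src = frag.sources.get(edge, idx)
            if edge not in merged.weights:
                keep = True
            else:
                w0, s0 = merged.weights[edge], merged.sources[edge]
                keep = abs(w) > abs(w0) or (abs(w) == abs(w0) and src < s0)
            if keep:
                merged.weights[edge] = w
                merged.sources[edge] = src
    merged.theta = theta if theta is not None else 0.0
    return merged


def _infer_with_retry(i, part, cand, expr, config):
    try:
        return inference.infer_module(i, part, cand, expr, config)
    except Exception:  # noqa: BLE001 - worker crash policy: one retry
        logger.warning("module %d failed on a worker; retrying on master", i)
        return inference.infer_module(i, part, cand, expr, config)


def run_pipeline(
    expr: ExpressionMatrix,
    config: RunConfig,
    gold: GoldStandard | None = None,
) -> PipelineResult:
    """Run preprocess -> MI -> decomposition -> per-module inference -> assembly.

    MI is computed on the normalized matrix (Gaussian MI is invariant to
    per-gene affine rescaling, so normalization only stabilizes numerics);
    the linear systems use the interpolated un-normalized matrix, because
    the difference model is stated in expression units and mean-centering
    would introduce an intercept the model does not contain.
    """
    timings: dict[str, float] = {}

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %-12s %.3fs", name, timings[name])
        return out

    interpolated = stage("preprocess", preprocess.interpolate_missing, expr)
    normalized = stage("normalize", preprocess.normalize, interpolated)
    mi = stage("mutual_info", mutual_info.pairwise_mi, normalized)
    net_bin = stage("threshold", decomposition.threshold_adjacency, mi, config.lambda_mi)
    part = stage("cluster", decomposition.cluster_modules, net_bin)
    part = stage("reinsert", decomposition.reinsert_isolated, part, mi)
    candidates = stage(
        "candidates",
        lambda: [
            inference.select_candidate_set(i, part, mi, config.candidate_fraction)
            for i in range(part.n_modules)
        ],
    )

    t0 = time.perf_counter()
    fragments: dict[int, InferredNetwork] = {}
    if config.workers == 1:
        for i in range(part.n_modules):
            fragments[i] = _infer_with_retry(i, part, candidates[i], interpolated, config)
    else:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            futures = {
                pool.submit(_infer_with_retry, i, part, candidates[i], interpolated, config): i
                for i in range(part.n_modules)
            }
            for fut in as_completed(futures):  # unordered completion by design
                fragments[futures[fut]] = fut.result()
    timings["infer"] = time.perf_counter() - t0
    logger.info("stage %-12s %.3fs (%d modules, %d workers)",
                "infer", timings["infer"], part.n_modules, config.workers)

    network = stage("assemble", assemble, fragments)
    network.theta = config.theta

    result = PipelineResult(network, part, mi, config)
    if gold is not None:
        counts = evaluation.confusion_counts(network.binary_edges, gold)
        result.evaluation = evaluation.metrics(counts)
    return result


def run_lsgpa(expr_path, gold_path=None, config: RunConfig | None = None) -> PipelineResult:
    """File-path front end to :func:`run_pipeline` (the CLI entry point)."""
    config = config or RunConfig()
    try:
        expr = read_expression(expr_path)
    except Exception as exc:
        raise StageError("read_expression", str(exc)) from exc
    gold = None
    if gold_path is not None:
        try:
            gold = read_gold_standard(gold_path, expr.gene_ids)
        except Exception as exc:
            raise StageError("read_gold_standard", str(exc)) from exc
    return run_pipeline(expr, config, gold)
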