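"""Null Model II (CE) randomization and empirical significance testing.

In this null model each cell (i, j) of the presence-absence matrix is
occupied independently with probability (P_i + P_j) / 2, where P_i is the
fill proportion of row i (k_i / n_cols) and P_j the fill proportion of
column j (d_j / n_rows).  The expected number of presences of a null draw
therefore equals the observed number exactly:
sum_ij (P_i + P_j)/2 = (sum_i k_i + sum_j d_j) / 2 = F.

Empty rows or columns arising in a draw are kept as-is; discarding them
would bias the ensemble toward higher fill.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from . import metrics
from .exceptions import ConfigurationError, UndefinedMetricError
from .modularity import optimize_modularity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullEnsemble:
    observed: float
    null_values: tuple
    p_value: float
    z_score: float
    n_random: int
    seed: int
    tail: str


def null_probabilities(matrix) -> np.ndarray:
    """Cell occupancy probabilities (P_i + P_j)/2 from row/column fills."""
    b = (np.asarray(matrix) > 0).astype(np.float64)
    if b.ndim != 2 or b.sum() == 0:
        raise UndefinedMetricError("null model needs a 2-D matrix with at least one edge")
    p_row = b.mean(axis=1)
    p_col = b.mean(axis=0)
    return (p_row[:, None] + p_col[None, :]) / 2.0


def null_model_sample(matrix, seed: Union[int, np.random.Generator] = 0) -> np.ndarray:
    """One independent Bernoulli draw of the same shape as ``matrix``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = null_probabilities(matrix)
    return (rng.random(probs.shape) < probs).astype(np.int64)


def _resolve_metric(metric, seed: int) -> Callable:
    if callable(metric):
        return metric
    if metric == "nodf":
        return metrics.nodf
    if metric == "modularity":
        # each draw gets its own derived annealer seed so the ensemble is reproducible
        def _mod(mat, _counter=[0]):
            _counter[0] += 1
            return optimize_modularity(mat, seed=(seed + _counter[0]) % (2**31), n_restarts=1).best_q
        return _mod
    raise ConfigurationError(f"metric must be 'nodf', 'modularity' or a callable, got {metric!r}")


def significance_test(
    matrix,
    metric="nodf",
    n_random: int = 1000,
    seed: int = 0,
    tail: str = "upper",
    sampler: Callable = null_model_sample,
) -> NullEnsemble:
    """Empirical significance of a metric against the Null Model II ensemble.

    p uses the add-one correction p = (1 + #{null >= observed}) / (n + 1)
    for the upper tail (lower analogous), so p is never exactly 0.  Null
    draws on which the metric is undefined are scored 0 and logged.
    """
    if n_random < 1:
        raise ConfigurationError("n_random must be >= 1")
    if tail not in ("upper", "lower"):
        raise ConfigurationError(f"tail must be 'upper' or 'lower', got {tail!r}")
    fn = _resolve_metric(metric, seed)
    observed = float(fn(np.asarray(matrix)))
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_random)
    for i in range(n_random):
        draw = sampler(matrix, rng)
        try:
            nulls[i] = fn(draw)
        except UndefinedMetricError:
            logger.warning("metric undefined on null draw %d; scoring 0", i)
            nulls[i] = 0.0
    if tail == "upper":
        extreme = int((nulls >= observed).sum())
    else:
        extreme = int((nulls <= observed).sum())
    p = (1 + extreme) / (n_random + 1)
    sd = float(nulls.std(ddof=1)) if n_random > 1 else 0.0
    mean = float(nulls.mean())
    if sd > 0:
        z = (observed - mean) / sd
    else:
        z = 0.0 if observed == mean else math.copysign(math.inf, observed - mean)
    return NullEnsemble(observed, tuple(nulls.tolist()), p, z, n_random, seed, tail)
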