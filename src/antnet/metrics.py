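"""Network-level and species-level statistics.

Implements the descriptor battery used to characterise individual-based
ant-plant networks:

* **NODF** nestedness (0 = non-nested, 100 = perfectly nested): paired
  overlap between every pair of rows and every pair of columns with
  strictly decreasing marginal fill.
* **H2'** network specialization (0 = extreme generalization, 1 = extreme
  specialization): the observed interaction-frequency entropy normalized
  between the maximum and minimum entropies achievable under the observed
  marginal totals.
* **Jaccard similarity** between two species assemblages.
* **Gc** generalist-core classification: an ant species belongs to the
  core when its standardized degree (k_i - k_mean)/sigma_k exceeds 1.
* **Core turnover** between the diurnal and nocturnal generalist cores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DegenerateDegreeError, UndefinedMetricError, ValidationError
from .netcore import BipartiteNetwork, binarize

logger = logging.getLogger(__name__)

GENERALIST_CORE = "generalist_core"
PERIPHERAL = "peripheral"


@dataclass(frozen=True)
class CorePeriphery:
    """Per-ant standardized degrees and core/peripheral labels for one network."""

    ant_labels: tuple
    k: np.ndarray            # binary degree per ant (distinct plants visited)
    gc: np.ndarray           # standardized degree (k_i - k_mean) / sigma_k
    labels: tuple            # GENERALIST_CORE where gc > 1, else PERIPHERAL
    k_mean: float
    sigma_k: float

    @property
    def core(self) -> set:
        return {a for a, lab in zip(self.ant_labels, self.labels) if lab == GENERALIST_CORE}


@dataclass(frozen=True)
class H2Result:
    """Observed entropy and its margin-constrained extremes."""

    h2: float
    h2_min: float
    h2_max: float
    h2_prime: float


@dataclass(frozen=True)
class NetworkDescriptors:
    """One row of the per-network descriptor table."""

    n_plants: int
    n_ants: int
    mean_richness_per_plant: float
    richness_sd: float
    core_size: int
    h2prime: float
    nodf: float
    modularity: Optional[float] = None
    nodf_p: Optional[float] = None
    modularity_p: Optional[float] = None


def _pairwise_overlap_sum(binary: np.ndarray) -> float:
    """Sum of paired-overlap percentages over all ordered row pairs (i, j)
    with fill_i > fill_j > 0; each unordered decreasing-fill pair contributes
    exactly once."""
    fills = binary.sum(axis=1)
    overlap = binary @ binary.T
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = 100.0 * overlap / fills[None, :]
    mask = (fills[:, None] > fills[None, :]) & (fills[None, :] > 0)
    return float(contrib[mask].sum())


def nodf(matrix) -> float:
    """NODF nestedness of a presence-absence matrix, on the 0-100 scale.

    For each pair of rows (and of columns) with strictly decreasing fill,
    the paired overlap is 100 x (shared presences) / (fill of the sparser
    line); equal-fill pairs contribute 0.  NODF is the mean over all
    C(r,2) + C(c,2) pairs.
    """
    a = np.asarray(matrix)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise UndefinedMetricError("NODF needs at least 2 rows and 2 columns")
    b = (a > 0).astype(np.float64)
    r, c = b.shape
    total = _pairwise_overlap_sum(b) + _pairwise_overlap_sum(b.T)
    n_pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return total / n_pairs


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2min_allocation(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Greedy margin-preserving concentration: repeatedly place
    min(remaining row, remaining column) in the cell where that allocation
    is largest; ties broken by lowest row index then lowest column index."""
    r = row_totals.astype(np.int64).copy()
    c = col_totals.astype(np.int64).copy()
    alloc = np.zeros((len(r), len(c)), dtype=np.int64)
    while r.sum() > 0:
        cand = np.minimum(r[:, None], c[None, :])
        cand[r == 0, :] = -1
        cand[:, c == 0] = -1
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)  # row-major: row-then-col ties
        amount = cand[i, j]
        alloc[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    return alloc


def h2prime(weight_matrix) -> H2Result:
    """Network specialization H2' from a non-negative integer weight matrix.

    H2 is the Shannon entropy of the observed interaction frequencies
    p_ij = a_ij / m.  H2max is the entropy of the margin-product
    distribution p_i q_j (the perfectly opportunistic network); H2min comes
    from a greedy integer concentration of the margins (the most
    specialized arrangement reachable by the heuristic).  H2' =
    (H2max - H2) / (H2max - H2min), clamped to [0, 1]; degenerate margins
    (H2max = H2min) give 0.
    """
    a = np.asarray(weight_matrix, dtype=np.float64)
    if a.ndim != 2 or (a < 0).any():
        raise ValidationError("h2prime needs a non-negative 2-D matrix")
    if not np.allclose(a, np.round(a)):
        raise ValidationError("h2prime needs integer interaction counts")
    m = a.sum()
    if m == 0:
        raise UndefinedMetricError("H2' is undefined for an all-zero matrix")
    p = a / m
    h2 = _entropy(p.ravel())
    row_p = a.sum(axis=1) / m
    col_p = a.sum(axis=0) / m
    h2max = _entropy(row_p) + _entropy(col_p)  # entropy of the product distribution
    alloc = _h2min_allocation(np.round(a.sum(axis=1)), np.round(a.sum(axis=0)))
    h2min = _entropy(alloc.ravel() / m)
    denom = h2max - h2min
    if denom <= 1e-12:
        return H2Result(h2, h2min, h2max, 0.0)
    h2p = (h2max - h2) / denom
    if h2p < 0.0 or h2p > 1.0:
        logger.warning("H2' = %.6f outside [0, 1]; clamping", h2p)
        h2p = min(max(h2p, 0.0), 1.0)
    return H2Result(h2, h2min, h2max, h2p)


def jaccard(set_a, set_b) -> float:
    """Jaccard similarity |A n B| / |A u B| between two species sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise UndefinedMetricError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(a | b)


def gc_scores(net: BipartiteNetwork, sd: str = "sample") -> CorePeriphery:
    """Standardized-degree core/periphery classification of the ant species.

    k_i is the number of distinct plant individuals visited by ant i;
    Gc_i = (k_i - k_mean) / sigma_k.  Species with Gc > 1 (strictly) form
    the generalist core.  ``sd`` selects the sample (n-1, default) or
    population (n) standard deviation.
    """
    if sd not in ("sample", "population"):
        raise ValidationError(f"sd must be 'sample' or 'population', got {sd!r}")
    k = net.ant_degrees().astype(np.float64)
    if len(k) < 2:
        raise UndefinedMetricError("core classification needs at least 2 ant species")
    ddof = 1 if sd == "sample" else 0
    k_mean = float(k.mean())
    sigma = float(k.std(ddof=ddof))
    if sigma == 0:
        raise DegenerateDegreeError("all ant degrees equal: no core distinguishable")
    gc = (k - k_mean) / sigma
    labels = tuple(GENERALIST_CORE if g > 1 else PERIPHERAL for g in gc)
    return CorePeriphery(net.ant_labels, k.astype(np.int64), gc, labels, k_mean, sigma)


def core_turnover(day: CorePeriphery, night: CorePeriphery):
    """Replacement of generalist-core membership between two periods.

    Returns (shared core, day-only core, night-only core, turnover) where
    turnover = 1 - |intersection| / |union|; 1.0 means the core assemblage
    completely changed between day and night.
    """
    d, n = day.core, night.core
    if not d and not n:
        raise UndefinedMetricError("core turnover undefined: both cores empty")
    turnover = 1.0 - len(d & n) / len(d | n)
    return d & n, d - n, n - d, turnover


def core_percentage(core_size: int, richness: int) -> float:
    """Generalist core as a percentage of total ant richness."""
    if richness < 1 or core_size < 0 or core_size > richness:
        raise ValidationError("need 0 <= core_size <= richness, richness >= 1")
    return 100.0 * core_size / richness


def descriptors(
    net: BipartiteNetwork,
    modularity_result=None,
    null_results: Optional[dict] = None,
) -> NetworkDescriptors:
    """Assemble the per-network descriptor row.

    ``mean_richness_per_plant`` is the mean (+- sample SD) of per-plant
    binary degree.  A degenerate degree distribution (all ants equal) gives
    core_size 0 with a warning; other metric failures propagate.
    """
    richness = net.plant_degrees().astype(np.float64)
    sd = float(richness.std(ddof=1)) if len(richness) > 1 else 0.0
    try:
        core_size = len(gc_scores(net).core)
    except DegenerateDegreeError:
        logger.warning("all ant degrees equal; reporting core_size = 0")
        core_size = 0
    null_results = null_results or {}
    nodf_ens = null_results.get("nodf")
    mod_ens = null_results.get("modularity")
    return NetworkDescriptors(
        n_plants=net.n_plants,
        n_ants=net.n_ants,
        mean_richness_per_plant=float(richness.mean()),
        richness_sd=sd,
        core_size=core_size,
        h2prime=h2prime(net.weights).h2_prime,
        nodf=nodf(binarize(net)),
        modularity=None if modularity_result is None else modularity_result.best_q,
        nodf_p=None if nodf_ens is None else nodf_ens.p_value,
        modularity_p=None if mod_ens is None else mod_ens.p_value,
    )
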