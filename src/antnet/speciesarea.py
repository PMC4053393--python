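"""EFN-count estimation and species-area statistics.

A plant individual is treated as an "island of resources" for ants: the
total number of extrafloral nectaries (EFNs) is the island area, estimated
from a small branch sample scaled to the whole plant; the species-area
hypothesis is then a simple linear regression of per-plant ant richness on
estimated EFN count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegeneratePredictorError, ValidationError

PROTOCOLS = ("per_branch", "per_leaf")


@dataclass(frozen=True)
class BranchSample:
    """EFN counts from a few sampled branches (or leaves) of one plant.

    ``per_branch``: counts are whole-branch EFN totals; estimate =
    mean(count) x total_branches.  ``per_leaf`` (for plants with many small
    nectaries per leaf): counts are per-leaf, scaled by the number of
    leaves per branch and then by total branches.
    """

    plant_id: str
    branch_efn_counts: tuple
    total_branches: int
    protocol: str = "per_branch"
    leaves_per_branch_sampled: Optional[int] = None

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"protocol must be one of {PROTOCOLS}")
        counts = tuple(self.branch_efn_counts)
        if len(counts) < 1:
            raise ValidationError(f"{self.plant_id}: need at least one sampled count")
        if any(c <= 0 for c in counts):
            raise ValidationError(f"{self.plant_id}: counts must be positive")
        if self.total_branches < 1:
            raise ValidationError(f"{self.plant_id}: total_branches must be >= 1")
        if self.protocol == "per_leaf" and not self.leaves_per_branch_sampled:
            raise ValidationError(f"{self.plant_id}: per_leaf protocol needs leaves_per_branch_sampled")
        object.__setattr__(self, "branch_efn_counts", counts)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def estimate_efns(sample: BranchSample) -> float:
    """Whole-plant EFN total scaled up from the branch (or leaf) sample."""
    mean_count = float(np.mean(sample.branch_efn_counts))
    if sample.protocol == "per_branch":
        return mean_count * sample.total_branches
    return mean_count * sample.leaves_per_branch_sampled * sample.total_branches


def species_area_regression(efn_totals: Sequence[float], richness: Sequence[float]) -> RegressionResult:
    """OLS regression of per-plant ant richness on estimated EFN count.

    Returns the slope, intercept, R^2 and the two-sided t-test p-value for
    slope = 0.
    """
    x = np.asarray(efn_totals, dtype=np.float64)
    y = np.asarray(richness, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("efn_totals and richness must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("regression needs n >= 3 for a defined p-value")
    if np.var(x) == 0:
        raise DegeneratePredictorError("predictor (EFN counts) has zero variance")
    if np.var(y) == 0:
        # constant response: a flat fit with no explainable variance
        return RegressionResult(0.0, float(y.mean()), 0.0, 1.0, len(x))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def one_sample_t(values: Sequence[float], reference: float):
    """One-sample two-sided Student t-test of ``values`` against ``reference``.

    Returns (t, p).  Note that testing a sample against its own mean is
    vacuous (t = 0 identically), so the reference must be supplied
    explicitly.
    """
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValidationError("t-test needs n >= 2")
    if v.std(ddof=1) == 0:
        raise DegeneratePredictorError("t-test undefined: sample has zero standard deviation")
    res = stats.ttest_1samp(v, popmean=reference)
    return float(res.statistic), float(res.pvalue)
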