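"""Domain types and network construction.

An individual-based ant-plant network records which ant species collected
extrafloral nectar on which individual plants of a single plant species.
Rows of the adjacency matrix are ant species, columns are plant individuals,
and the weight ``a_ij`` is the number of interaction events observed between
ant species *i* and plant individual *j*.  Networks are built per sampling
period (diurnal, nocturnal) or with both periods pooled (whole day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyNetworkError, ValidationError

PERIODS = ("diurnal", "nocturnal")
PERIOD_FILTERS = ("diurnal", "nocturnal", "whole_day")

RECORD_COLUMNS = ("plant_id", "ant_species", "period", "count")


@dataclass(frozen=True)
class InteractionRecord:
    """One observed ant-species x plant-individual interaction.

    ``count`` is the number of interaction events tallied for that pair in
    the given sampling period (always at least 1).
    """

    plant_id: str
    ant_species: str
    period: str
    count: int

    def __post_init__(self):
        if self.period not in PERIODS:
            raise ValidationError(
                f"period must be one of {PERIODS}, got {self.period!r}"
            )
        if not isinstance(self.count, (int, np.integer)) or self.count < 1:
            raise ValidationError(f"count must be a positive integer, got {self.count!r}")


@dataclass(frozen=True)
class PlantAttributes:
    """Per-plant covariates: height (m) and estimated total extrafloral nectaries."""

    plant_id: str
    height_m: float
    efn_total: float

    def __post_init__(self):
        if not self.height_m > 0:
            raise ValidationError(f"height_m must be > 0 for {self.plant_id}")
        if not self.efn_total > 0:
            raise ValidationError(f"efn_total must be > 0 for {self.plant_id}")


@dataclass(frozen=True)
class BipartiteNetwork:
    """Weighted ant x plant-individual interaction matrix with ordered labels."""

    ant_labels: tuple
    plant_labels: tuple
    weights: np.ndarray
    period_tag: str

    def __post_init__(self):
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape != (len(self.ant_labels), len(self.plant_labels)):
            raise ValidationError(
                f"weight matrix shape {w.shape} does not match labels "
                f"({len(self.ant_labels)} ants, {len(self.plant_labels)} plants)"
            )
        if (w < 0).any():
            raise ValidationError("weights must be non-negative")
        if w.size and ((w.sum(axis=1) == 0).any() or (w.sum(axis=0) == 0).any()):
            raise ValidationError("network contains an all-zero row or column")
        if self.period_tag not in PERIOD_FILTERS:
            raise ValidationError(
                f"period_tag must be one of {PERIOD_FILTERS}, got {self.period_tag!r}"
            )
        object.__setattr__(self, "weights", w)

    @property
    def n_ants(self) -> int:
        return len(self.ant_labels)

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    def ant_degrees(self) -> np.ndarray:
        """Binary degree per ant species: number of distinct plants visited."""
        return (self.weights > 0).sum(axis=1)

    def plant_degrees(self) -> np.ndarray:
        """Binary degree per plant: ant richness on that individual."""
        return (self.weights > 0).sum(axis=0)


def _read_table(path, dialect: str) -> pd.DataFrame:
    if dialect not in ("csv", "tsv"):
        raise ConfigurationError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_records(path, dialect: str = "csv") -> list:
    """Parse a long-format interaction table into a list of records.

    The file must have a header naming ``plant_id, ant_species, period,
    count``.  Malformed rows are reported with their 1-based file line
    numbers (header is line 1).
    """
    df = _read_table(path, dialect)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"records file {path} missing columns: {missing}")

    records, problems = [], []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2
        try:
            count = int(str(row.count))
        except ValueError:
            problems.append(f"line {line_no}: count {row.count!r} is not an integer")
            continue
        try:
            records.append(
                InteractionRecord(
                    plant_id=str(row.plant_id),
                    ant_species=str(row.ant_species),
                    period=str(row.period),
                    count=count,
                )
            )
        except ValidationError as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return records


def read_attributes(path, dialect: str = "csv") -> list:
    """Parse the per-plant attribute table.

    Accepts either a precomputed ``efn_total`` column or the raw branch
    protocol (``branch_efn_counts`` as ';'-separated integers plus
    ``total_branches``), in which case the estimate mean(branch counts) x
    total branches is computed here.
    """
    df = _read_table(path, dialect)
    if "plant_id" not in df.columns or "height_m" not in df.columns:
        raise ConfigurationError(f"attributes file {path} needs plant_id and height_m")
    has_total = "efn_total" in df.columns
    has_branches = "branch_efn_counts" in df.columns and "total_branches" in df.columns
    if not has_total and not has_branches:
        raise ConfigurationError(
            f"attributes file {path} needs efn_total or branch_efn_counts + total_branches"
        )

    out, problems = [], []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2
        try:
            if has_total and str(row.efn_total) != "":
                efn = float(row.efn_total)
            else:
                counts = [float(x) for x in str(row.branch_efn_counts).split(";") if x != ""]
                if not counts:
                    raise ValidationError("no branch counts")
                efn = float(np.mean(counts)) * float(row.total_branches)
            out.append(
                PlantAttributes(
                    plant_id=str(row.plant_id), height_m=float(row.height_m), efn_total=efn
                )
            )
        except (ValueError, ValidationError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return out


def build_network(records: Iterable[InteractionRecord], period_filter: str) -> BipartiteNetwork:
    """Aggregate records into a weighted bipartite matrix for one period.

    ``whole_day`` pools both periods, summing counts per (ant, plant) pair.
    Species or plants without interactions in the filtered set are absent.
    Duplicate (ant, plant, period) rows are summed.  Label order is
    lexicographic, so the matrix is independent of record order.
    """
    if period_filter not in PERIOD_FILTERS:
        raise ConfigurationError(
            f"period_filter must be one of {PERIOD_FILTERS}, got {period_filter!r}"
        )
    totals: dict = {}
    for rec in records:
        if period_filter != "whole_day" and rec.period != period_filter:
            continue
        key = (rec.ant_species, rec.plant_id)
        totals[key] = totals.get(key, 0) + rec.count
    if not totals:
        raise EmptyNetworkError(f"no interactions for period {period_filter!r}")

    ants = tuple(sorted({a for a, _ in totals}))
    plants = tuple(sorted({p for _, p in totals}))
    weights = np.zeros((len(ants), len(plants)), dtype=np.int64)
    a_idx = {a: i for i, a in enumerate(ants)}
    p_idx = {p: j for j, p in enumerate(plants)}
    for (a, p), c in totals.items():
        weights[a_idx[a], p_idx[p]] = c
    return BipartiteNetwork(ants, plants, weights, period_filter)


def binarize(net_or_matrix) -> np.ndarray:
    """Presence-absence version of a network's weight matrix (1 iff weight > 0)."""
    w = net_or_matrix.weights if isinstance(net_or_matrix, BipartiteNetwork) else net_or_matrix
    return (np.asarray(w) > 0).astype(np.int64)


def exclusive_species(day: BipartiteNetwork, night: BipartiteNetwork):
    """Partition the union of ant labels into (shared, day-only, night-only)."""
    d, n = set(day.ant_labels), set(night.ant_labels)
    return d & n, d - n, n - d
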