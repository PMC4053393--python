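"""End-to-end analysis pipeline, matrix export, configuration and reporting.

``run_pipeline`` takes interaction records plus plant attributes, builds the
diurnal, nocturnal and whole-day networks, computes the full descriptor
battery (H2', NODF, SA modularity), Null-Model-II significance tests,
generalist-core tables, day/night Jaccard similarity and core turnover, and
the species-area regression; the report is a plain dict that serializes to
byte-identical JSON given the same inputs and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from typing import Optional

import numpy as np
import yaml

from . import metrics, nullmodels, speciesarea
from .exceptions import (
    AntNetError,
    ConfigurationError,
    DegenerateDegreeError,
    EmptyNetworkError,
    PipelineStageError,
    ValidationError,
)
from .modularity import SASchedule, optimize_modularity
from .netcore import (
    BipartiteNetwork,
    binarize,
    build_network,
    exclusive_species,
    read_attributes,
    read_records,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "n_random": 1000,
    "objective": "barber_bipartite",
    "sd": "sample",
    "sa_restarts": 5,
    "sa_cooling": 0.95,
    "t_reference": 0.0,
    "richness_period": "whole_day",
    "dialect": "csv",
}


def load_config(path: Optional[str] = None, **overrides) -> dict:
    """Merge defaults <- YAML config file <- explicit overrides."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must be a mapping")
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        config.update(loaded)
    config.update({k: v for k, v in overrides.items() if v is not None})
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, AntNetError) and not isinstance(
                exc, PipelineStageError
            ):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def _network_block(net: BipartiteNetwork, config: dict) -> dict:
    seed = int(config["seed"])
    schedule = SASchedule(cooling=float(config["sa_cooling"]))
    mod = optimize_modularity(
        binarize(net),
        objective=config["objective"],
        seed=seed,
        n_restarts=int(config["sa_restarts"]),
        schedule=schedule,
    )
    null_results = {}
    binary = binarize(net)
    if net.n_ants >= 2 and net.n_plants >= 2:
        null_results["nodf"] = nullmodels.significance_test(
            binary, "nodf", n_random=int(config["n_random"]), seed=seed
        )
        null_results["modularity"] = nullmodels.significance_test(
            binary, "modularity", n_random=int(config["n_random"]), seed=seed + 1
        )
    desc = metrics.descriptors(net, modularity_result=mod, null_results=null_results)
    try:
        cp = metrics.gc_scores(net, sd=config["sd"])
        gc_table = {
            ant: {"k": int(k), "gc": float(g), "label": lab}
            for ant, k, g, lab in zip(cp.ant_labels, cp.k, cp.gc, cp.labels)
        }
    except (DegenerateDegreeError, AntNetError) as exc:
        logger.warning("gc table unavailable: %s", exc)
        cp, gc_table = None, None
    block = {
        "descriptors": asdict(desc),
        "gc_table": gc_table,
        "null_tests": {
            name: {
                "observed": ens.observed,
                "p_value": ens.p_value,
                "z_score": ens.z_score,
                "n_random": ens.n_random,
                "seed": ens.seed,
                "tail": ens.tail,
            }
            for name, ens in null_results.items()
        },
    }
    return block, cp


def run_pipeline(
    records_path,
    attributes_path,
    config_path: Optional[str] = None,
    **overrides,
) -> dict:
    """Full analysis of one records + attributes dataset.  Returns the report dict."""
    config = load_config(config_path, **overrides)

    with _stage("read_inputs"):
        records = read_records(records_path, dialect=config["dialect"])
        attributes = read_attributes(attributes_path, dialect=config["dialect"])
        if not records:
            raise ValidationError("no interaction records in input")

    networks, cps = {}, {}
    for period in ("diurnal", "nocturnal", "whole_day"):
        with _stage(f"network_{period}"):
            try:
                net = build_network(records, period)
            except EmptyNetworkError:
                logger.warning("no %s interactions; marking period absent", period)
                networks[period] = None
                continue
            block, cp = _network_block(net, config)
            networks[period] = block
            cps[period] = (net, cp)

    comparison = None
    if networks.get("diurnal") and networks.get("nocturnal"):
        with _stage("day_night_comparison"):
            day_net, day_cp = cps["diurnal"]
            night_net, night_cp = cps["nocturnal"]
            shared, day_only, night_only = exclusive_species(day_net, night_net)
            comparison = {
                "jaccard": metrics.jaccard(set(day_net.ant_labels), set(night_net.ant_labels)),
                "shared_species": sorted(shared),
                "day_only": sorted(day_only),
                "night_only": sorted(night_only),
            }
            if day_cp is not None and night_cp is not None and (day_cp.core or night_cp.core):
                core_shared, core_day, core_night, turnover = metrics.core_turnover(
                    day_cp, night_cp
                )
                comparison["core_turnover"] = {
                    "shared_core": sorted(core_shared),
                    "day_only_core": sorted(core_day),
                    "night_only_core": sorted(core_night),
                    "turnover": turnover,
                }
            else:
                comparison["core_turnover"] = None

    species_area = None
    t_test = None
    richness_net = cps.get(config["richness_period"], (None, None))[0]
    if richness_net is not None:
        with _stage("species_area"):
            efn_by_plant = {a.plant_id: a.efn_total for a in attributes}
            missing = [p for p in richness_net.plant_labels if p not in efn_by_plant]
            if missing:
                raise ValidationError(f"plants without attributes: {missing[:5]}")
            efn = [efn_by_plant[p] for p in richness_net.plant_labels]
            richness = richness_net.plant_degrees().tolist()
            reg = speciesarea.species_area_regression(efn, richness)
            species_area = asdict(reg)
            t, p = speciesarea.one_sample_t(efn, float(config["t_reference"]))
            t_test = {"t": t, "p": p, "reference": float(config["t_reference"]), "n": len(efn)}

    return {
        "metadata": {
            "seed": int(config["seed"]),
            "n_random": int(config["n_random"]),
            "objective": config["objective"],
            "sd": config["sd"],
            "config_hash": config_hash(config),
        },
        "networks": networks,
        "day_night": comparison,
        "species_area": species_area,
        "efn_t_test": t_test,
    }


def report_to_json(report: dict) -> str:
    """Canonical JSON rendering (sorted keys), byte-stable given equal reports."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"


def render_report(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["Individual-based ant-plant network analysis", "=" * 44]
    meta = report["metadata"]
    lines.append(
        f"seed={meta['seed']}  n_random={meta['n_random']}  objective={meta['objective']}"
        f"  config={meta['config_hash']}"
    )
    for period in ("diurnal", "nocturnal", "whole_day"):
        block = report["networks"].get(period)
        lines.append("")
        lines.append(f"[{period}]")
        if block is None:
            lines.append("  absent (no interactions in this period)")
            continue
        d = block["descriptors"]
        lines.append(
            f"  plants={d['n_plants']}  ants={d['n_ants']}  "
            f"richness/plant={d['mean_richness_per_plant']:.2f}+-{d['richness_sd']:.2f}"
        )
        lines.append(
            f"  H2'={d['h2prime']:.3f}  NODF={d['nodf']:.2f}"
            + (f" (p={d['nodf_p']:.4f})" if d["nodf_p"] is not None else "")
            + (f"  M={d['modularity']:.3f}" if d["modularity"] is not None else "")
            + (f" (p={d['modularity_p']:.4f})" if d["modularity_p"] is not None else "")
        )
        if block["gc_table"]:
            core = sorted(a for a, r in block["gc_table"].items() if r["label"] == "generalist_core")
            lines.append(f"  generalist core ({len(core)}): {', '.join(core) if core else '-'}")
    comp = report.get("day_night")
    if comp:
        lines.append("")
        lines.append("[day vs night]")
        lines.append(f"  Jaccard similarity = {comp['jaccard']:.3f}")
        ct = comp.get("core_turnover")
        if ct:
            lines.append(f"  core turnover = {ct['turnover']:.3f}")
    if report.get("species_area"):
        sa = report["species_area"]
        lines.append("")
        lines.append("[species-area]")
        lines.append(
            f"  richness ~ EFNs: slope={sa['slope']:.3g}  R2={sa['r_squared']:.3f}"
            f"  p={sa['p_value']:.4f}  n={sa['n']}"
        )
    if report.get("efn_t_test"):
        tt = report["efn_t_test"]
        lines.append(
            f"  EFN one-sample t vs {tt['reference']:g}: t={tt['t']:.3f}  p={tt['p']:.4g}"
        )
    return "\n".join(lines) + "\n"


def export_matrix(net: BipartiteNetwork, path, format: str = "aninhado_txt") -> None:
    """Write the weight matrix as plain text.

    ``aninhado_txt``: first line "R C", then R space-separated integer rows
    (the legacy nestedness-software exchange format).  ``csv``: labeled
    matrix with plant columns and ant rows.
    """
    if net.weights.size == 0:
        raise EmptyNetworkError("cannot export an empty network")
    if format == "aninhado_txt":
        with open(path, "w") as fh:
            fh.write(f"{net.n_ants} {net.n_plants}\n")
            for row in net.weights:
                fh.write(" ".join(str(int(x)) for x in row) + "\n")
    elif format == "csv":
        with open(path, "w") as fh:
            fh.write("ant_species," + ",".join(net.plant_labels) + "\n")
            for ant, row in zip(net.ant_labels, net.weights):
                fh.write(ant + "," + ",".join(str(int(x)) for x in row) + "\n")
    else:
        raise ConfigurationError(f"format must be 'aninhado_txt' or 'csv', got {format!r}")


def import_matrix(path) -> np.ndarray:
    """Read a matrix written in the aninhado_txt format."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValidationError(f"{path}: first line must be 'rows cols'")
        r, c = int(header[0]), int(header[1])
        rows = [[int(x) for x in fh.readline().split()] for _ in range(r)]
    mat = np.array(rows, dtype=np.int64)
    if mat.shape != (r, c):
        raise ValidationError(f"{path}: matrix shape {mat.shape} does not match header {(r, c)}")
    return mat
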