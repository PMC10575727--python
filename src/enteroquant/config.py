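"""Pipeline configuration and orchestrated simulate→analyze runs.

A single structured configuration carries one parameter block per
stage; every default equals the documented default of the corresponding
analysis function. File values (YAML) are merged over defaults and
unknown keys are rejected, so typos fail loudly. ``run_pipeline``
executes simulate-then-analyze round trips per modality and records a
manifest (parameters, seeds, input digests, outputs) for audit.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("enteroquant")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "enteroquant_out",
    "verbosity": 1,
    "mxif": {
        "nuclei_prominence": 15.0,
        "marker_prominences": {"pEGFR": 40.0, "CGA": 100.0},
        "min_branch_length": 10,
        "threshold": "otsu",
        "normalize_low_percentile": 0.1,
        "normalize_high_percentile": 99.9,
        "linkage": "average",
    },
    "isc": {
        "mode": "plateau",
        "baseline_window": 60.0,
        "response_window": 180.0,
        "floor_bounds": [0.0, 100.0],
        "ceiling_bounds": [0.0, 100.0],
    },
    "ph": {
        "baseline_window": 30.0,
        "rate_window": 60.0,
        "recovery_window": 300.0,
    },
    "swell": {
        "min_area": 50.0,
        "min_circularity": 0.6,
        "max_displacement": 20.0,
        "time": 1.0,
    },
    "rescue": {
        "fdr_cutoff": 0.05,
        "min_abs_log2fc": 1.0,
        "max_fdr": 0.05,
        "min_basemean": 10.0,
    },
}

STAGES = ("mxif", "isc", "ph", "swell", "rescue")


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and key != "marker_prominences":
            if not isinstance(value, dict):
                raise TypeError(f"{where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class PipelineConfig:
    """Validated per-stage parameters plus global seed and output dir."""

    params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, override: dict) -> "PipelineConfig":
        return cls(params=_merge(DEFAULTS, override))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def __getitem__(self, key: str):
        return self.params[key]

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.params["outdir"])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, stages: list[str]) -> dict:
    """Run simulate-then-analyze round trips for the requested stages.

    Each stage generates its modality with the global seed, writes the
    dataset plus truth sidecar, runs the corresponding analysis, and
    writes its result tables. The returned (and saved) manifest records
    parameters, seeds, input digests and output paths; a stage failure
    is recorded and re-raised after the manifest is written.
    """
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; available: {STAGES}")
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {
        "package": "enteroquant",
        "version": __version__,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "parameters": config.params,
        "stages": {},
    }
    failure: Exception | None = None
    for stage in stages:
        logger.info("stage %s: start (seed=%d)", stage, config.seed)
        record: dict = {"status": "ok", "inputs": {}, "outputs": [], "results": {}}
        try:
            runner = _STAGE_RUNNERS[stage]
            runner(config, outdir, record)
            logger.info("stage %s: done", stage)
        except Exception as exc:  # recorded, then re-raised after saving
            record["status"] = "failed"
            record["error"] = f"{type(exc).__name__}: {exc}"
            failure = exc
            logger.error("stage %s: failed: %s", stage, exc)
        manifest["stages"][stage] = record
        if failure is not None:
            break
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if failure is not None:
        raise failure
    return manifest


# ---------------------------------------------------------------------------
# stage runners


def _register_io(record: dict, outdir: Path, *paths: Path) -> None:
    for p in paths:
        record["inputs"][p.name] = _digest(p)
        record["outputs"].append(str(p))


def _run_mxif(config: PipelineConfig, outdir: Path, record: dict) -> None:
    from . import io as eio
    from .mxif import (cell_type_fractions, channel_cross_correlation,
                       feret_distances, skeletonize_marker)
    from .simulate import ChannelSpec, SyntheticImageConfig, gen_mxif_image

    p = config["mxif"]
    img_cfg = SyntheticImageConfig(
        channels={
            "DAPI": ChannelSpec("nuclei", n_spots=50),
            "pEGFR": ChannelSpec("marker", n_spots=10, amplitude=120.0),
            "CGA": ChannelSpec("marker", n_spots=15, amplitude=160.0),
            "CD10": ChannelSpec("ribbon", n_fragments=8, fragment_length=60.0),
        },
        seed=config.seed,
    )
    image, truth = gen_mxif_image(img_cfg)
    tiff = eio.write_multichannel_tiff(image, outdir / "mxif.tif")
    tpath = eio.write_truth(truth, outdir / "mxif.truth.yaml")
    _register_io(record, outdir, tiff, tpath)

    fractions = cell_type_fractions(
        image, "DAPI", p["marker_prominences"], p["nuclei_prominence"]
    )
    skel = skeletonize_marker(
        image["CD10"], p["threshold"], p["min_branch_length"], channel="CD10"
    )
    feret = feret_distances(skel)
    corr = channel_cross_correlation(image)
    corr.matrix.to_csv(outdir / "mxif_correlation.tsv", sep="\t")
    record["outputs"].append(str(outdir / "mxif_correlation.tsv"))
    record["results"] = {
        "cell_type_fractions": fractions,
        "feret_mean_px": feret.mean_px,
        "feret_count": feret.count,
    }


def _run_isc(config: PipelineConfig, outdir: Path, record: dict) -> None:
    from . import io as eio
    from .analysis import measure_dose_inhibition
    from .electrophys import fit_dose_response
    from .simulate import crofelemer_dose_config, gen_isc_trace

    p = config["isc"]
    trace, truth = gen_isc_trace(crofelemer_dose_config(seed=config.seed))
    tr = eio.write_trace(trace, outdir / "isc_doses.tsv")
    tpath = eio.write_truth(truth, outdir / "isc_doses.truth.yaml")
    _register_io(record, outdir, tr, tpath)
    doses, inhib = measure_dose_inhibition(trace)
    fit = fit_dose_response(
        doses, inhib,
        floor_bounds=tuple(p["floor_bounds"]),
        ceiling_bounds=tuple(p["ceiling_bounds"]),
    )
    record["results"] = {
        "ic50_uM": fit.ic50,
        "max_inhibition_pct": fit.ceiling,
        "converged": fit.converged,
    }


def _run_ph(config: PipelineConfig, outdir: Path, record: dict) -> None:
    from . import io as eio
    from .analysis import analyze_ph_trace
    from .simulate import gen_ph_trace, nhe_config

    p = config["ph"]
    trace, truth = gen_ph_trace(nhe_config("healthy", seed=config.seed))
    tr = eio.write_trace(trace, outdir / "ph_trace.tsv")
    tpath = eio.write_truth(truth, outdir / "ph_trace.truth.yaml")
    _register_io(record, outdir, tr, tpath)
    result = analyze_ph_trace(
        trace,
        baseline_window=p["baseline_window"],
        rate_window=p["rate_window"],
        window=p["recovery_window"],
    )
    record["results"] = {
        "delta_ph": result.delta_ph,
        "initial_rate": result.initial_rate,
    }


def _run_swell(config: PipelineConfig, outdir: Path, record: dict) -> None:
    from . import io as eio
    from .analysis import swelling_ratios
    from .simulate import gen_swelling_series, swelling_config
    from .swelling import swelling_inhibition

    p = config["swell"]
    results = {}
    ratios = {}
    for arm in ("agonist", "agonist+crofelemer"):
        frames, truth = gen_swelling_series(
            swelling_config("healthy", arm, seed=config.seed)
        )
        stem = "swell_" + arm.replace("+", "_")
        fpath = eio.write_label_stack(frames, outdir / f"{stem}.tif")
        tpath = eio.write_truth(truth, outdir / f"{stem}.truth.yaml")
        _register_io(record, outdir, fpath, tpath)
        ratios[arm] = swelling_ratios(
            frames, truth.data["times"], p["time"],
            min_area=p["min_area"], min_circularity=p["min_circularity"],
            max_displacement=p["max_displacement"],
        )
    results["percent_inhibition"] = swelling_inhibition(
        ratios["agonist"], ratios["agonist+crofelemer"]
    )
    record["results"] = results


def _run_rescue(config: PipelineConfig, outdir: Path, record: dict) -> None:
    from . import io as eio
    from .rescue import opposite_direction_filter, prioritize
    from .simulate import SyntheticDeConfig, gen_de_tables

    p = config["rescue"]
    tables, truth = gen_de_tables(SyntheticDeConfig(seed=config.seed))
    paths = []
    for name, tab in tables.items():
        paths.append(eio.write_de_table(tab, outdir / f"de_{name}.tsv"))
    tpath = eio.write_truth(truth, outdir / "de.truth.yaml")
    _register_io(record, outdir, *paths, tpath)
    hits = opposite_direction_filter(
        tables["baseline"], tables["treatment"], p["fdr_cutoff"]
    )
    ranked = prioritize(
        hits, p["min_abs_log2fc"], p["max_fdr"], p["min_basemean"]
    )
    ranked.table.to_csv(outdir / "rescue_ranked.tsv", sep="\t", index=False)
    record["outputs"].append(str(outdir / "rescue_ranked.tsv"))
    record["results"] = {
        "n_filtered": len(hits),
        "n_ranked": len(ranked),
        "top_genes": ranked.genes[:10],
    }


_STAGE_RUNNERS = {
    "mxif": _run_mxif,
    "isc": _run_isc,
    "ph": _run_ph,
    "swell": _run_swell,
    "rescue": _run_rescue,
}
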