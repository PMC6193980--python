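"""File formats, run configuration, seed plumbing and pipeline execution.

Conventions: image data as multi-page TIFF with a JSON sidecar carrying the
synthetic truth; tabular data (measurements, tracks, curves, titrations) as
CSV with fixed, unit-suffixed headers; results as JSON with a provenance
block.  Distances are in nm, track positions in px (pixel size carried in
metadata), times in seconds, densities per µm².  All stage randomness
derives from a master seed combined with the stage name, so re-running a
config reproduces stochastic outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .flimp import FLImPDataset

logger = logging.getLogger("oligoscope")

SCHEMAS = {
    "flimp": ["r_obs_nm", "sigma_nm", "ci_lo_nm", "ci_hi_nm", "condition"],
    "tracks": ["track_id", "channel", "frame", "x_px", "y_px"],
    "bleach_curve": ["p", "cd"],
    "fret": ["cell_id", "density_um2", "efficiency"],
    "composition": ["size", "fraction"],
}


class SchemaError(ValueError):
    """A table's header does not match the expected schema."""


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from (master seed, stage)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate its header against a named schema.

    Zero data rows is not an error; a missing or unknown column is, and the
    error names the offending column.
    """
    cols = SCHEMAS[schema]
    df = pd.read_csv(path)
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"missing column {c!r} for schema {schema!r}")
    for c in df.columns:
        if c not in cols:
            raise SchemaError(f"unknown column {c!r} for schema {schema!r}")
    return df[cols]


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    cols = SCHEMAS[schema]
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"missing column {c!r} for schema {schema!r}")
    df[cols].to_csv(path, index=False)


def write_stack(frames: np.ndarray, path, sidecar: str | None = None) -> None:
    """Write an image stack as multi-page TIFF, with an optional JSON sidecar
    (truth/metadata) at <path>.json."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))
    if sidecar is not None:
        Path(str(path) + ".json").write_text(sidecar)


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


@dataclass
class RunConfig:
    """Configuration of one pipeline stage run."""

    stage: str
    out: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)

    def stage_seed(self, substage: str | None = None) -> int:
        return derive_seed(self.seed, substage or self.stage)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Stage outputs plus provenance (config hash, version, timestamp)."""

    stage: str
    results: dict
    config: RunConfig

    def to_json(self, with_timestamp: bool = True) -> str:
        payload = {
            "stage": self.stage,
            "results": _jsonable(self.results),
            "provenance": {
                "config_hash": self.config.config_hash,
                "package_version": __version__,
                "seed": self.config.seed,
            },
        }
        if with_timestamp:
            payload["provenance"]["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute one named stage: simulate the inputs it needs (or load them
    from ``config.inputs``), run the analysis, and return a ResultBundle."""
    logging.basicConfig(level=config.log_level)
    stage = config.stage
    runners = {
        "flimp": _run_flimp,
        "pbics": _run_pbics,
        "coloc": _run_coloc,
        "fret": _run_fret,
    }
    if stage not in runners:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(runners)}")
    _validate(config)
    logger.info("stage %s seed %d params %s", stage, config.seed, config.params)
    results = runners[stage](config)
    bundle = ResultBundle(stage, results, config)
    if config.out:
        bundle.write(config.out)
    return bundle


def _validate(config: RunConfig) -> None:
    p = config.params
    if p.get("ci_max_nm", 1) <= 0:
        raise ValueError("ci_max_nm must be > 0")
    if p.get("n_boot", 2) < 2:
        raise ValueError("n_boot must be >= 2")


def _run_flimp(config: RunConfig) -> dict:
    from . import chain, flimp, synth

    p = config.params
    if "dataset_csv" in config.inputs:
        ds = FLImPDataset.from_frame(read_table(config.inputs["dataset_csv"], "flimp"))
    else:
        geom = chain.ChainGeometry(
            p.get("repeat_spacing_nm", 9.0), p.get("turn_angle_deg", 22.0)
        )
        comp = chain.OligomerComposition.exponential(
            p.get("composition_rate", 1.0), p.get("j_max", 8)
        )
        scheme = chain.LabelingScheme("internal_1to1", p.get("p_label", 0.2))
        ds = synth.simulate_flimp_measurements(
            geom, comp, scheme,
            p.get("loc_sigma_nm", 2.0), p.get("n_measurements", 100),
            seed=config.stage_seed("flimp-sim"),
        )
    ds = flimp.filter_ci(ds, p.get("ci_max_nm", 7.0))
    if len(ds) == 0:
        raise ValueError("no measurements survive the CI filter")
    result = flimp.decompose(
        ds,
        K_max=p.get("k_max", 8),
        n_boot=p.get("n_boot", 200),
        seed=config.stage_seed("flimp-fit"),
    )
    return {"n_measurements": len(ds), **result.to_dict()}


def _run_pbics(config: RunConfig) -> dict:
    from . import chain, pbics, synth

    p = config.params
    if "curve_csv" in config.inputs:
        df = read_table(config.inputs["curve_csv"], "bleach_curve")
        curve = pbics.BleachCurve(df["p"].to_numpy(), df["cd"].to_numpy())
    else:
        comp = chain.OligomerComposition.exponential(
            p.get("composition_rate", 1.0), p.get("j_max", 8)
        )
        stack = synth.simulate_pbics_stack(
            comp,
            p.get("cluster_density_per_px2", 0.005),
            p.get("survival_per_round", 0.7),
            p.get("n_rounds", 7),
            beam_waist_px=p.get("omega_px", 2.5),
            seed=config.stage_seed("pbics-sim"),
        )
        curve = pbics.bleach_curve_from_stack(stack)
    fit = pbics.fit_composition(
        curve, j_max=p.get("j_max", 8), seed=config.stage_seed("pbics-fit")
    )
    return {
        "c": fit.c,
        "species_fractions": fit.species_fractions,
        "molecular_fractions": fit.molecular_fractions,
        "oligomer_fraction": fit.oligomer_fraction,
        "residual_norm": fit.residual_norm,
    }


def _run_coloc(config: RunConfig) -> dict:
    from . import sptcoloc, synth

    p = config.params
    if "tracks_csv" in config.inputs:
        df = read_table(config.inputs["tracks_csv"], "tracks")
        fov = tuple(p.get("fov_px", (100.0, 100.0)))
        all_tracks = sptcoloc.TrackSet.from_frame(df, fov)
        set_a = sptcoloc.TrackSet(
            [t for t in all_tracks.tracks if t.channel == "A"], fov
        )
        set_b = sptcoloc.TrackSet(
            [t for t in all_tracks.tracks if t.channel == "B"], fov
        )
    else:
        set_a, set_b, _ = synth.simulate_tracks(
            p.get("n_free_per_channel", 50),
            p.get("n_pairs", 20),
            seed=config.stage_seed("coloc-sim"),
        )
    summary = sptcoloc.coloc_analysis(
        set_a, set_b,
        dist_px=p.get("dist_px", 1.0),
        min_total_frames=p.get("min_frames", 5),
        n_rand=p.get("n_rand", 50),
        fwhm_frames=p.get("fwhm_frames", 4.0),
        seed=config.stage_seed("coloc-null"),
    )
    return {
        "raw_fraction_a": summary.raw_fraction_a,
        "raw_fraction_b": summary.raw_fraction_b,
        "coincidental_fraction_a": summary.coincidental_fraction_a,
        "coincidental_fraction_b": summary.coincidental_fraction_b,
        "corrected_fraction": summary.corrected_fraction,
        "n_events": len(summary.events),
        "tau_on_mean_s": float(np.mean(summary.tau_on)) if summary.events else None,
    }


def _run_fret(config: RunConfig) -> dict:
    from . import fretdoca, synth

    p = config.params
    if "fret_csv" in config.inputs:
        obs = fretdoca.observations_from_frame(read_table(config.inputs["fret_csv"], "fret"))
    else:
        obs, _ = synth.simulate_fret(
            p.get("h_true_nm", 8.0),
            p.get("densities_per_um2", list(fretdoca.DEFAULT_DENSITIES_UM2)),
            R0_nm=p.get("r0_nm", 5.0),
            n_cells_per_density=p.get("n_cells_per_density", 10),
            seed=config.stage_seed("fret-sim"),
        )
    est = fretdoca.fit_doca(
        obs,
        R0_nm=p.get("r0_nm", 5.0),
        n_boot=p.get("n_boot", 3000),
        seed=config.stage_seed("fret-fit"),
        n_config=p.get("n_config", 400),
    )
    return {"n_observations": len(obs), **est.to_dict()}
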