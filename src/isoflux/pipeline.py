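"""Declarative end-to-end runs: configuration, stage execution, and manifests.

A run is described by a YAML file (or an equivalent dict).  Inputs can be
paths to MID/plate/ranked-list tables, or a synthetic scenario generated on
the fly by :mod:`isoflux.synthdata`.  Outputs are tidy CSV tables, each
carrying the run seed and a constants hash in its header comments, plus a
machine-readable ``manifest.json``.  Identical configurations produce
byte-identical outputs.

Config schema (all keys optional unless noted)::

    seed: 0                 # master seed for synthetic stages
    outdir: out/            # required: output directory
    stages: [mid, plate, ranklist]
    synthetic:              # generate inputs instead of reading files
      sigma_mid: 0.01
      n_replicates: 4
      rho: 0.5
      ...                   # any ScenarioSpec field
    inputs:
      mid_table: path.csv
      plate_table: path.csv
      list_a: path.csv      # columns: id, score
      list_b: path.csv
    constants:              # AssayConstants overrides
      buffering_power: 0.1
    tracer:                 # TracerConfig overrides
      purity: 0.99
    overlap:
      depths: [10, 50, 100]
      n_perm: 1000
      ends: top
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioenergetics import AssayConstants, compute_jatp, space_profile, summarize_phases
from .errors import IsofluxError, ParameterError
from .io import read_mid_table, read_plate, write_mid_table, write_plate
from .isocorrect import TracerConfig, build_correction_matrix, correct_mid
from .isotopes import NATURAL_ABUNDANCE_VERSION
from .ranklist import RankedList, ordered_overlap_test
from .synthdata import ScenarioSpec, make_mid_dataset, make_plate, make_ranked_pair
from .tracesim import FluxParams, TracerScenario, estimate_flux_indices

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: Sequence[str] = ("mid", "plate", "ranklist")
    synthetic: Mapping[str, object] | None = None
    inputs: Mapping[str, str] = field(default_factory=dict)
    constants: AssayConstants = field(default_factory=AssayConstants)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    overlap: Mapping[str, object] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - {"mid", "plate", "ranklist"}
        if unknown:
            raise ParameterError(f"unknown stage(s) {sorted(unknown)}")
        if self.synthetic is None:
            for stage, key in (("mid", "mid_table"), ("plate", "plate_table")):
                if stage in self.stages and key not in self.inputs:
                    raise ParameterError(f"stage {stage!r} needs inputs.{key} or a synthetic block")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, object]) -> RunConfig:
    raw = dict(raw)
    if "outdir" not in raw:
        raise ParameterError("config requires an 'outdir'")
    constants = AssayConstants(**raw.pop("constants", {}) or {})
    tracer = TracerConfig(**raw.pop("tracer", {}) or {})
    return RunConfig(
        outdir=Path(str(raw.pop("outdir"))),
        seed=int(raw.pop("seed", 0)),
        stages=tuple(raw.pop("stages", ("mid", "plate", "ranklist"))),
        synthetic=raw.pop("synthetic", None),
        inputs=dict(raw.pop("inputs", {}) or {}),
        constants=constants,
        tracer=tracer,
        overlap=dict(raw.pop("overlap", {}) or {}),
        log_level=str(raw.pop("log_level", "INFO")),
    )


def _constants_hash(constants: AssayConstants) -> str:
    payload = json.dumps(dataclasses.asdict(constants), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _scenario(config: RunConfig) -> ScenarioSpec:
    raw = dict(config.synthetic or {})
    flux = FluxParams(**(raw.pop("flux", {}) or {}))
    scenario_kwargs = raw.pop("tracer_scenario", {}) or {}
    tracer_scenario = TracerScenario(**scenario_kwargs)
    return ScenarioSpec(
        seed=config.seed, flux=flux, tracer_scenario=tracer_scenario,
        tracer=config.tracer, **raw,
    )


def _stage_mid(config: RunConfig, meta: Dict[str, object], outdir: Path) -> Dict[str, str]:
    if config.synthetic is not None:
        spec = _scenario(config)
        raws, truth, matrices = make_mid_dataset(spec)
        write_mid_table(raws, outdir / "raw_mids.csv", metadata=meta)
        truth_df = pd.DataFrame(
            [
                {"metabolite": fe.metabolite, "time_min": fe.time_min, "mass_shift": s,
                 "fraction": repr(float(f))}
                for fe in truth
                for s, f in enumerate(fe.fractions)
            ]
        )
        with open(outdir / "mid_truth.csv", "w", newline="") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            truth_df.to_csv(fh, index=False, lineterminator="\n")
    else:
        raws = read_mid_table(config.inputs["mid_table"])
        matrices = {}

    corrected = []
    for raw in raws:
        if raw.metabolite not in matrices:
            matrices[raw.metabolite] = build_correction_matrix(
                raw.formula, config.tracer, K=len(raw.intensities) - 1
            )
        corrected.append(correct_mid(raw, matrices[raw.metabolite]))
    enr_rows = [
        {"metabolite": fe.metabolite, "time_min": fe.time_min, "replicate": fe.replicate,
         "mass_shift": s, "fraction": repr(float(f))}
        for fe in corrected
        for s, f in enumerate(fe.fractions)
    ]
    with open(outdir / "fractional_enrichment.csv", "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(enr_rows).to_csv(fh, index=False, lineterminator="\n")

    indices = estimate_flux_indices(corrected)
    idx_rows = [
        {"index": name, "value": "" if value is None else repr(float(value)),
         "missing": name in indices.missing}
        for name, value in indices.as_dict().items()
    ]
    with open(outdir / "flux_indices.csv", "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(idx_rows).to_csv(fh, index=False, lineterminator="\n")
    return {"fractional_enrichment": "fractional_enrichment.csv", "flux_indices": "flux_indices.csv"}


def _stage_plate(config: RunConfig, meta: Dict[str, object], outdir: Path) -> Dict[str, str]:
    if config.synthetic is not None:
        spec = _scenario(config)
        plate, truth = make_plate(spec)
        write_plate(plate, outdir / "plate.csv", metadata=meta)
        with open(outdir / "plate_truth.csv", "w", newline="") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            truth.to_csv(fh, index=False, lineterminator="\n")
    else:
        plate = read_plate(config.inputs["plate_table"])

    summary = summarize_phases(plate)
    rows = []
    for group, rates in summary.groups.items():
        basal = compute_jatp(rates, config.constants, "basal")
        profile = None
        if summary.has_monensin:
            maximal = compute_jatp(rates, config.constants, "max", has_monensin=True)
            profile = space_profile(basal, maximal)
        row = {
            "group": group,
            "j_atp_ox": repr(basal.j_atp_ox),
            "j_atp_glyc": repr(basal.j_atp_glyc),
            "j_atp_total": repr(basal.j_atp_total),
        }
        if profile is not None:
            row.update(
                j_atp_ox_max=repr(profile.maximal.j_atp_ox),
                j_atp_glyc_max=repr(profile.maximal.j_atp_glyc),
                capacity=repr(profile.capacity),
                flexibility=repr(profile.flexibility),
                pct_oxphos_basal=repr(profile.pct_oxphos_basal),
                pct_oxphos_max=repr(profile.pct_oxphos_max),
                fraction_capacity_used=repr(profile.fraction_capacity_used),
                glycolytic_index=repr(profile.glycolytic_index),
            )
        rows.append(row)
    with open(outdir / "space_profiles.csv", "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(rows).to_csv(fh, index=False, lineterminator="\n")
    with open(outdir / "rate_summary.csv", "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        summary.to_frame().to_csv(fh, lineterminator="\n")
    return {"space_profiles": "space_profiles.csv", "rate_summary": "rate_summary.csv"}


def _read_ranked_csv(path: str) -> RankedList:
    df = pd.read_csv(path, comment="#")
    if not {"id", "score"} <= set(df.columns):
        raise IsofluxError(f"{path}: ranked-list table needs columns id, score")
    return RankedList(df["id"].to_numpy(dtype=object), df["score"].to_numpy(dtype=float))


def _stage_ranklist(config: RunConfig, meta: Dict[str, object], outdir: Path) -> Dict[str, str]:
    if config.synthetic is not None:
        spec = _scenario(config)
        list_a, list_b, _ = make_ranked_pair(spec)
    else:
        if not {"list_a", "list_b"} <= set(config.inputs):
            raise ParameterError("ranklist stage needs inputs.list_a and inputs.list_b")
        list_a = _read_ranked_csv(config.inputs["list_a"])
        list_b = _read_ranked_csv(config.inputs["list_b"])
    depths = list(config.overlap.get("depths", [10, 50, 100]))
    n_perm = int(config.overlap.get("n_perm", 1000))
    ends = str(config.overlap.get("ends", "top"))
    result = ordered_overlap_test(list_a, list_b, depths, n_perm=n_perm, seed=config.seed, ends=ends)
    df = pd.DataFrame(
        {
            "depth": result.depths,
            "observed": result.observed,
            "null_mean": [repr(float(v)) for v in result.null_mean],
            "null_q025": result.null_q025,
            "null_q975": result.null_q975,
            "p_value": [repr(float(v)) for v in result.p_values],
        }
    )
    with open(outdir / "overlap.csv", "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return {"overlap": "overlap.csv"}


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the configured stages and write the report bundle.

    Returns the manifest (also written to ``outdir/manifest.json``).  Stage
    errors propagate annotated with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: Dict[str, object] = {
        "isoflux_version": __version__,
        "seed": config.seed,
        "constants_hash": _constants_hash(config.constants),
        "isotope_table": NATURAL_ABUNDANCE_VERSION,
    }
    outputs: Dict[str, str] = {}
    runners = {"mid": _stage_mid, "plate": _stage_plate, "ranklist": _stage_ranklist}
    for stage in config.stages:
        try:
            outputs.update(runners[stage](config, meta, outdir))
        except Exception as exc:
            raise IsofluxError(
                f"stage {stage!r} failed on inputs "
                f"{config.inputs or 'synthetic scenario'}: {exc}"
            ) from exc
    manifest = {
        **meta,
        "stages": list(config.stages),
        "inputs": dict(config.inputs),
        "synthetic": dict(config.synthetic) if config.synthetic is not None else None,
        "constants": dataclasses.asdict(config.constants),
        "tracer": dataclasses.asdict(config.tracer),
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
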