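"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator is a pure function of a :class:`ScenarioSpec` (seed included)
and returns the generated object together with a *truth sidecar* sufficient to
compute the expected output of every downstream stage without re-simulation.
Pseudo-random streams are split from the master seed per data kind, so adding
a generator never perturbs the outputs of the existing ones.

Default sizes mirror the study conditions the generators emulate: 4 tracer
replicates, plates with 9 wells per group and 5 injection phases of 3
measurement cycles, and ranked-list pairs over 1,000 genes (the 19,038-gene
intersection of the original microarray comparison, scaled down for speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .bioenergetics import CANONICAL_PHASES, PlateAssay
from .errors import ParameterError
from .isocorrect import CorrectionMatrix, FractionalEnrichment, RawMID, TracerConfig
from .ranklist import RankedList
from .tracesim import FluxParams, TracerScenario, generate_raw_mids, simulate_isotopologues

__all__ = ["ScenarioSpec", "make_mid_dataset", "make_plate", "make_ranked_pair"]

# fixed stream keys: adding a data kind appends a key, never renumbers
_STREAM_MID = 1
_STREAM_PLATE = 2
_STREAM_RANKED = 3

#: Phase-wise truth per group, in per-µg units (OCR pmol O2/min/µg, ECAR
#: mpH/min/µg).  The two groups sketch a drug-sensitive line and a resistant
#: line with raised respiration and bioenergetic capacity.
DEFAULT_PLATE_TRUTH: Dict[str, Dict[str, Tuple[float, float]]] = {
    "control": {
        "basal": (5.0, 1.0),
        "oligomycin": (2.0, 1.5),
        "fccp": (9.0, 1.2),
        "rotmyx": (0.5, 1.1),
        "monensin": (0.5, 2.0),
    },
    "resistant": {
        "basal": (7.5, 0.9),
        "oligomycin": (2.8, 1.3),
        "fccp": (15.0, 1.1),
        "rotmyx": (0.6, 1.0),
        "monensin": (0.6, 1.8),
    },
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of a synthetic study scenario."""

    seed: int = 0
    # tracer data
    flux: FluxParams = field(default_factory=FluxParams)
    tracer_scenario: TracerScenario = field(default_factory=TracerScenario)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    n_replicates: int = 4
    sigma_mid: float = 0.01
    # plate data
    plate_truth: Mapping[str, Mapping[str, Tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PLATE_TRUTH.items()}
    )
    wells_per_group: int = 9
    cycles_per_phase: int = 3
    sigma_plate: float = 0.05  # relative noise on well rates
    drift_per_min: float = 0.0  # additive linear drift on OCR, pmol/min^2 per µg
    protein_mean_ug: float = 20.0
    protein_cv: float = 0.1
    # ranked-list pair
    n_genes: int = 1000
    rho: float = 0.0
    planted_top: int = 100

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ParameterError("rho must lie in [-1, 1]")
        if self.planted_top > self.n_genes:
            raise ParameterError("planted_top cannot exceed n_genes")
        if self.n_replicates < 1 or self.wells_per_group < 1:
            raise ParameterError("replicate and well counts must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def make_mid_dataset(
    spec: ScenarioSpec,
) -> tuple[List[RawMID], List[FractionalEnrichment], Dict[str, CorrectionMatrix]]:
    """Simulated raw MID table plus its ground-truth enrichment sidecar."""
    truth = simulate_isotopologues(spec.tracer_scenario, spec.flux)
    # generate_raw_mids re-derives its generator from the stream seed so the
    # dataset is a pure function of the spec
    stream_seed = int(spec.rng(_STREAM_MID).integers(0, 2**31 - 1))
    raws, matrices = generate_raw_mids(
        truth,
        spec.tracer_scenario.formulas(),
        spec.tracer,
        sigma=spec.sigma_mid,
        seed=stream_seed,
        n_replicates=spec.n_replicates,
    )
    return raws, truth, matrices


def make_plate(spec: ScenarioSpec) -> tuple[PlateAssay, pd.DataFrame]:
    """Synthetic plate assay plus a per-group phase-truth sidecar.

    Well traces are the per-µg phase truth times the well's protein, plus
    optional linear drift and relative Gaussian noise.  The sidecar holds the
    protein-normalized truth that phase summarization should recover.
    """
    rng = spec.rng(_STREAM_PLATE)
    rows = []
    protein: Dict[str, float] = {}
    cycle_minutes = 6.5
    for g_idx, (group, phases) in enumerate(spec.plate_truth.items()):
        ordered = [p for p in CANONICAL_PHASES if p in phases]
        if ordered != [p for p in CANONICAL_PHASES if p in set(phases)]:
            raise ParameterError(f"group {group}: phase truth must follow the canonical order")
        for w in range(spec.wells_per_group):
            well = f"{group}_w{w + 1:02d}"
            sigma_ln = np.sqrt(np.log(1.0 + spec.protein_cv**2))
            protein[well] = float(
                rng.lognormal(np.log(spec.protein_mean_ug) - 0.5 * sigma_ln**2, sigma_ln)
            )
            measurement = 0
            for phase in ordered:
                ocr_true, ecar_true = phases[phase]
                for _ in range(spec.cycles_per_phase):
                    t = measurement * cycle_minutes
                    ocr = ocr_true * protein[well]
                    ecar = ecar_true * protein[well]
                    ocr += spec.drift_per_min * t * protein[well]
                    if spec.sigma_plate > 0:
                        ocr *= 1.0 + rng.normal(0.0, spec.sigma_plate)
                        ecar *= 1.0 + rng.normal(0.0, spec.sigma_plate)
                    rows.append(
                        {
                            "well": well,
                            "group": group,
                            "measurement": measurement,
                            "time_min": t,
                            "phase": phase,
                            "ocr": max(0.0, ocr),
                            "ecar": max(0.0, ecar),
                        }
                    )
                    measurement += 1
    plate = PlateAssay(data=pd.DataFrame(rows), protein_ug=protein)
    truth_rows = [
        {"group": group, "phase": phase, "ocr_per_ug": v[0], "ecar_per_ug": v[1]}
        for group, phases in spec.plate_truth.items()
        for phase, v in phases.items()
    ]
    return plate, pd.DataFrame(truth_rows)


def make_ranked_pair(spec: ScenarioSpec) -> tuple[RankedList, RankedList, Dict[str, float]]:
    """Two ranked gene lists with planted score correlation ``rho``.

    Scores are bivariate standard normal with correlation rho; rho=1 gives
    identical orderings and rho=0 independent ones.  The sidecar records the
    generative correlation and the expected independent-overlap mean
    ``planted_top^2 / n_genes``.
    """
    rng = spec.rng(_STREAM_RANKED)
    n = spec.n_genes
    ids = np.array([f"gene{i:05d}" for i in range(n)], dtype=object)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = spec.rho
    scores_a = z1
    scores_b = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2
    sidecar = {
        "rho": rho,
        "expected_independent_overlap": spec.planted_top**2 / n,
    }
    return (
        RankedList(ids.copy(), scores_a),
        RankedList(ids.copy(), scores_b),
        sidecar,
    )
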