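"""First-turn label-propagation model for [U-13C]-glucose / [U-13C]-glutamine tracing.

The simulator produces ground-truth fractional enrichments for a small panel
of central-carbon metabolites under a first-turn approximation of glycolysis
and the citric acid cycle, the regime in which single isotopologues are read
as pathway activities:

* glucose tracer — fully labeled glucose yields m+3 pyruvate (fraction ``g``);
  pyruvate dehydrogenase passes two labeled carbons to acetyl-CoA
  (m+2 fraction ``a2 = g * f_pdh``) while pyruvate carboxylase / malic enzymes
  pass three to oxaloacetate (m+3 fraction ``o3 = g * f_pc``).  Citrate
  condenses the two independently: m+2 = a2(1-o3), m+3 = o3(1-a2),
  m+5 = a2*o3.  Four-carbon intermediates (malate, fumarate, aspartate) carry
  the anaplerotic m+3 signature directly and acquire m+2 after one oxidative
  turn of the citrate pool.
* glutamine tracer — glutaminolysis yields m+5 glutamate and 2-ketoglutarate
  (fraction ``f_glnox``); oxidative decarboxylation makes citrate m+4 while
  reductive carboxylation (reverse IDH flux) preserves all five carbons and
  makes citrate m+5.  Newly synthesized glutathione inherits the glutamate
  label (GSH m+5); glutathione disulfide is the random pairing of two GSH
  units, so GSSG m+10 = p5^2 and m+5 = 2 p5 (1 - p5).

Each metabolite approaches its steady-state labeling mono-exponentially with
rate ``k_met``; the remaining mass stays at m+0.  Multi-turn scrambling
species (e.g. GSH m+3 from second-turn glutamate) are deliberately not
modeled — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .isocorrect import (
    CorrectionMatrix,
    ElementFormula,
    FractionalEnrichment,
    RawMID,
    TracerConfig,
    build_correction_matrix,
    parse_formula,
)

__all__ = [
    "FluxParams",
    "TracerScenario",
    "FluxIndices",
    "GLUCOSE_PANEL",
    "GLUTAMINE_PANEL",
    "simulate_isotopologues",
    "generate_raw_mids",
    "estimate_flux_indices",
]

#: Representative TBDMS-derivatized GC/MS fragments (tracer positions are the
#: metabolite backbone carbons) and underivatized LC/MS species for the
#: glutathione branch.
GLUCOSE_PANEL: Dict[str, str] = {
    "pyruvate": "C9H19NO3Si@3",
    "citrate": "C20H39O7Si3@6",
    "malate": "C18H39O5Si3@4",
    "fumarate": "C12H23O4Si2@4",
    "aspartate": "C18H40N2O4Si3@4",
    "glutamate": "C19H42N2O4Si3@5",
}

GLUTAMINE_PANEL: Dict[str, str] = {
    "glutamate": "C19H42N2O4Si3@5",
    "2-ketoglutarate": "C14H27NO5Si2@5",
    "citrate": "C20H39O7Si3@6",
    "malate": "C18H39O5Si3@4",
    "GSH": "C10H17N3O6S@5",
    "GSSG": "C20H32N6O12S2@10",
}


@dataclass(frozen=True)
class FluxParams:
    """Pathway split fractions of the first-turn model.

    g
        fraction of the pyruvate pool that is m+3 from glucose.
    f_pdh
        fraction of acetyl-CoA made from labeled pyruvate (PDH flux).
    f_pc
        fraction of oxaloacetate made by pyruvate carboxylation / malic
        enzyme exchange (the anaplerotic m+3 route).
    f_glnox
        fraction of the 2-ketoglutarate pool that is m+5 from glutamine.
    f_red
        fraction of citrate made by reductive carboxylation of 2-KG.
    f_gsh
        fraction of the glutathione pool newly synthesized from labeled
        glutamate over the labeling window.
    k_met
        mono-exponential labeling rate shared by the panel (per minute).
    """

    g: float = 0.8
    f_pdh: float = 0.6
    f_pc: float = 0.15
    f_glnox: float = 0.7
    f_red: float = 0.15
    f_gsh: float = 0.3
    k_met: float = 0.1

    def __post_init__(self) -> None:
        for name in ("g", "f_pdh", "f_pc", "f_glnox", "f_red", "f_gsh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.k_met < 0:
            raise ParameterError("k_met must be non-negative")


@dataclass(frozen=True)
class TracerScenario:
    """A tracer choice, sampling schedule, and metabolite panel."""

    tracer: str = "U13C-glutamine"
    timepoints: Sequence[float] = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)
    panel: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.tracer not in ("U13C-glucose", "U13C-glutamine"):
            raise ParameterError(f"unknown tracer {self.tracer!r}")
        t = list(self.timepoints)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ParameterError("timepoints must be strictly increasing")
        if self.panel is None:
            default = GLUCOSE_PANEL if self.tracer == "U13C-glucose" else GLUTAMINE_PANEL
            object.__setattr__(self, "panel", dict(default))

    def formulas(self) -> Dict[str, ElementFormula]:
        return {met: parse_formula(f) for met, f in self.panel.items()}


def _steady_state(tracer: str, p: FluxParams) -> Dict[str, Dict[int, float]]:
    """Steady-state labeled fractions per metabolite (m+0 is the remainder)."""
    if tracer == "U13C-glucose":
        a2 = p.g * p.f_pdh
        o3 = p.g * p.f_pc
        c2 = a2 * (1.0 - o3)
        four_carbon = {3: o3, 2: c2}  # m+2 arrives after one oxidative turn of citrate
        return {
            "pyruvate": {3: p.g},
            "citrate": {2: c2, 3: o3 * (1.0 - a2), 5: a2 * o3},
            "malate": dict(four_carbon),
            "fumarate": dict(four_carbon),
            "aspartate": dict(four_carbon),
            "glutamate": {2: c2},  # via PDH-labeled citrate -> 2-KG
        }
    # U13C-glutamine
    glu5 = p.f_glnox
    gsh5 = p.f_gsh * glu5
    return {
        "glutamate": {5: glu5},
        "2-ketoglutarate": {5: glu5},
        "citrate": {4: (1.0 - p.f_red) * glu5, 5: p.f_red * glu5},
        "malate": {3: (1.0 - p.f_red) * glu5},  # oxidative route, CO2 lost twice
        "GSH": {5: gsh5},
        "GSSG": {},  # filled by pairing after kinetic scaling
    }


def _pair_gssg(p5: float) -> Dict[int, float]:
    """Random disulfide pairing of two GSH units with m+5 fraction p5."""
    return {5: 2.0 * p5 * (1.0 - p5), 10: p5 * p5}


def simulate_isotopologues(
    scenario: TracerScenario, params: FluxParams
) -> List[FractionalEnrichment]:
    """Ground-truth fractional enrichments for each panel metabolite and timepoint."""
    ss = _steady_state(scenario.tracer, params)
    unknown = set(scenario.panel) - set(ss)
    if unknown:
        raise ParameterError(
            f"no labeling rules for panel metabolites {sorted(unknown)} under {scenario.tracer}"
        )
    formulas = scenario.formulas()
    out: List[FractionalEnrichment] = []
    for met in scenario.panel:
        n_tracer = formulas[met].n_tracer
        for t in scenario.timepoints:
            scale = 1.0 - np.exp(-params.k_met * t)
            fractions = np.zeros(n_tracer + 1)
            if met == "GSSG":
                gsh_ss = ss["GSH"].get(5, 0.0)
                labeled = _pair_gssg(gsh_ss * scale)
            else:
                labeled = {k: v * scale for k, v in ss[met].items()}
            for shift, frac in labeled.items():
                if shift > n_tracer:
                    raise ParameterError(f"{met}: shift {shift} exceeds n_tracer={n_tracer}")
                fractions[shift] = frac
            fractions[0] = 1.0 - fractions[1:].sum()
            out.append(FractionalEnrichment(metabolite=met, time_min=float(t), fractions=fractions))
    return out


def generate_raw_mids(
    truth: Sequence[FractionalEnrichment],
    formulas: Mapping[str, ElementFormula],
    tracer: TracerConfig,
    sigma: float,
    seed: int,
    n_replicates: int = 4,
    K_extra: int = 3,
) -> tuple[List[RawMID], Dict[str, CorrectionMatrix]]:
    """Forward-convolve truth into noisy instrument-like raw MIDs.

    Each replicate is the correction-matrix image of the true fractions plus
    i.i.d. Gaussian noise of standard deviation ``sigma`` (on the normalized
    scale, clipped at zero), scaled by a random per-sample total-intensity
    factor.  Fully deterministic for a given seed.
    """
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    matrices = {
        met: build_correction_matrix(f, tracer, K=f.n_tracer + K_extra)
        for met, f in formulas.items()
    }
    raws: List[RawMID] = []
    for fe in truth:
        cm = matrices[fe.metabolite]
        expected = cm.matrix @ fe.fractions
        for r in range(n_replicates):
            noisy = expected + rng.normal(0.0, sigma, size=expected.shape)
            noisy = np.clip(noisy, 0.0, None)
            intensity = rng.lognormal(mean=np.log(1e5), sigma=0.2)
            raws.append(
                RawMID(
                    metabolite=fe.metabolite,
                    formula=cm.formula,
                    time_min=fe.time_min,
                    replicate=f"rep{r + 1}",
                    intensities=noisy * intensity,
                )
            )
    return raws, matrices


@dataclass
class FluxIndices:
    """Flux-ratio readouts; an index is None when its denominator vanished."""

    pc_index: float | None = None
    reductive_index: float | None = None
    gsh_synthesis_index: float | None = None
    missing: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, float | None]:
        return {
            "pc_index": self.pc_index,
            "reductive_index": self.reductive_index,
            "gsh_synthesis_index": self.gsh_synthesis_index,
        }


def _mean_fractions(
    panel: Sequence[FractionalEnrichment], metabolite: str
) -> np.ndarray | None:
    """Average fractions at the latest timepoint across replicates."""
    entries = [fe for fe in panel if fe.metabolite == metabolite]
    if not entries:
        return None
    t_max = max(fe.time_min for fe in entries)
    stack = [fe.fractions for fe in entries if fe.time_min == t_max]
    return np.mean(stack, axis=0)


def _ratio(num: float, denom: float) -> float | None:
    if denom <= 0:
        return None
    return float(np.clip(num / denom, 0.0, 1.0))


def estimate_flux_indices(panel: Sequence[FractionalEnrichment]) -> FluxIndices:
    """Flux-ratio indices from a corrected enrichment panel.

    * ``pc_index`` — citrate m+3 / (m+2 + m+3): anaplerotic (pyruvate
      carboxylase / malic enzyme) share of citrate labeling from glucose.
    * ``reductive_index`` — citrate m+5 / (m+4 + m+5): reductive-carboxylation
      share of citrate labeling from glutamine.
    * ``gsh_synthesis_index`` — GSH m+5 / glutamate m+5: fraction of the
      glutathione pool newly made from labeled glutamate.

    Uses replicate means at the latest sampled timepoint.  Indices whose
    denominator is zero (or whose metabolites are absent) are flagged missing
    rather than raising.
    """
    result = FluxIndices()
    cit = _mean_fractions(panel, "citrate")
    if cit is not None and len(cit) > 3:
        result.pc_index = _ratio(cit[3], cit[2] + cit[3])
    if cit is not None and len(cit) > 5:
        result.reductive_index = _ratio(cit[5], cit[4] + cit[5])
    gsh = _mean_fractions(panel, "GSH")
    glu = _mean_fractions(panel, "glutamate")
    if gsh is not None and glu is not None and len(gsh) > 5 and len(glu) > 5:
        if glu[5] > 0:
            result.gsh_synthesis_index = float(np.clip(gsh[5] / glu[5], 0.0, 1.0))
    for name, value in result.as_dict().items():
        if value is None:
            result.missing.append(name)
    return result
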