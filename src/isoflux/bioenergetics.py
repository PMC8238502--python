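"""Extracellular-flux bioenergetics: respiration components, ATP rates, and
the bioenergetic-space geometry.

A plate assay records oxygen consumption (OCR, pmol O2/min) and extracellular
acidification (ECAR, mpH/min) through a canonical injection sequence —
basal, oligomycin (ATP-synthase inhibition), FCCP (maximal respiration),
rotenone+myxothiazol (non-mitochondrial), and optionally monensin (maximal
glycolytic ATP demand).  From the phase-wise, protein-normalized rates the
module derives:

* respiration components (mitochondrial, coupled, leak, maximal);
* proton production rates, correcting ECAR for medium buffering power and the
  CO2/bicarbonate contribution of respiration;
* ATP production rates J_ATPox and J_ATPglyc under basal and maximal states;
* the bioenergetic-space summary: plotting the basal operating point in the
  (J_ATPglyc, J_ATPox) plane inside the rectangle spanned by the two maxima,
  capacity is the rectangle's area and flexibility is the length of the
  constant-total-ATP segment through the basal point clipped to the
  rectangle — how far ATP supply can shift between glycolysis and OXPHOS
  without changing total output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PhaseError

__all__ = [
    "CANONICAL_PHASES",
    "PlateAssay",
    "AssayConstants",
    "GroupRates",
    "RateSummary",
    "ATPFlux",
    "SpaceProfile",
    "summarize_phases",
    "ppr_from_ecar",
    "compute_jatp",
    "space_profile",
]

logger = logging.getLogger(__name__)

#: Injection phases in their mandatory order; monensin is optional.
CANONICAL_PHASES: tuple[str, ...] = ("basal", "oligomycin", "fccp", "rotmyx", "monensin")
MANDATORY_PHASES: tuple[str, ...] = ("basal", "oligomycin", "fccp", "rotmyx")


@dataclass
class PlateAssay:
    """Tidy per-well OCR/ECAR time series with an injection schedule.

    ``data`` columns: well, group, measurement (cycle index within the run),
    time_min, phase, ocr, ecar.  ``protein_ug`` maps well id to total protein.
    """

    data: pd.DataFrame
    protein_ug: Dict[str, float]
    medium_ph: float = 7.4

    def __post_init__(self) -> None:
        required = {"well", "group", "measurement", "time_min", "phase", "ocr", "ecar"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"plate data missing columns {sorted(missing)}")
        for well, protein in self.protein_ug.items():
            if protein <= 0:
                raise ParameterError(f"well {well}: protein must be positive")
        self._check_phase_order()

    def _check_phase_order(self) -> None:
        for well, sub in self.data.sort_values("measurement").groupby("well"):
            seen = list(dict.fromkeys(sub["phase"]))
            expected = [p for p in CANONICAL_PHASES if p in seen]
            if seen != expected:
                raise PhaseError(f"well {well}: phases {seen} violate canonical order")

    @property
    def phases(self) -> List[str]:
        return [p for p in CANONICAL_PHASES if p in set(self.data["phase"])]

    @property
    def groups(self) -> List[str]:
        return sorted(self.data["group"].unique())


@dataclass(frozen=True)
class AssayConstants:
    """Coefficients of the ATP-rate bookkeeping (all configurable).

    buffering_power
        medium buffering power in mpH per pmol H+ in the effective measurement
        chamber; must be calibrated per medium/instrument.
    atp_per_lactate
        ATP yielded per lactate extruded (1 for glycolysis from glucose).
    po_ox
        ATP per O atom for coupled respiration (P/O ratio, mixed substrate).
    co2_h_per_o2
        protons from CO2 hydration per O2 consumed (respiratory quotient times
        the bicarbonate dissociation fraction at the assay pH).
    glyc_ox_coupling
        ATP per O atom credited to the glycolytic pathway when glycolytic
        pyruvate is oxidized (substrate-level phosphorylation bookkeeping).
    pk1
        CO2/bicarbonate equilibrium pK, recorded for provenance.
    """

    buffering_power: float = 0.1
    atp_per_lactate: float = 1.0
    po_ox: float = 2.486
    co2_h_per_o2: float = 1.0
    glyc_ox_coupling: float = 0.167
    pk1: float = 6.093

    def __post_init__(self) -> None:
        for name in ("buffering_power", "atp_per_lactate", "po_ox", "co2_h_per_o2",
                     "glyc_ox_coupling", "pk1"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class GroupRates:
    """Protein-normalized phase means (per µg) for one well group."""

    group: str
    n_wells: int
    ocr: Dict[str, float]
    ecar: Dict[str, float]
    ocr_sem: Dict[str, float] = field(default_factory=dict)
    ecar_sem: Dict[str, float] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def _floored(self, value: float, name: str) -> float:
        if value < 0:
            msg = f"{self.group}: derived rate {name} was negative ({value:.3g}); floored at 0"
            if msg not in self.warnings:
                self.warnings.append(msg)
                logger.warning(msg)
            return 0.0
        return value

    @property
    def ocr_mito(self) -> float:
        return self._floored(self.ocr["basal"] - self.ocr["rotmyx"], "ocr_mito")

    @property
    def ocr_coupled(self) -> float:
        return self._floored(self.ocr["basal"] - self.ocr["oligomycin"], "ocr_coupled")

    @property
    def ocr_leak(self) -> float:
        return self._floored(self.ocr["oligomycin"] - self.ocr["rotmyx"], "ocr_leak")

    @property
    def ocr_mito_max(self) -> float:
        return self._floored(self.ocr["fccp"] - self.ocr["rotmyx"], "ocr_mito_max")


@dataclass
class RateSummary:
    """Per-group phase summaries for a plate."""

    groups: Dict[str, GroupRates]
    cycles_per_phase: int
    has_monensin: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups.values():
            row: Dict[str, object] = {"group": g.group, "n_wells": g.n_wells}
            for phase, v in g.ocr.items():
                row[f"ocr_{phase}"] = v
                row[f"ocr_{phase}_sem"] = g.ocr_sem.get(phase, math.nan)
            for phase, v in g.ecar.items():
                row[f"ecar_{phase}"] = v
                row[f"ecar_{phase}_sem"] = g.ecar_sem.get(phase, math.nan)
            row["ocr_mito"] = g.ocr_mito
            row["ocr_coupled"] = g.ocr_coupled
            row["ocr_leak"] = g.ocr_leak
            row["ocr_mito_max"] = g.ocr_mito_max
            rows.append(row)
        return pd.DataFrame(rows).set_index("group")


@dataclass
class ATPFlux:
    """ATP production rates (pmol ATP/min/µg protein) in one metabolic state."""

    j_atp_ox: float
    j_atp_glyc: float
    state: str  # "basal" or "max"

    @property
    def j_atp_total(self) -> float:
        return self.j_atp_ox + self.j_atp_glyc


@dataclass
class SpaceProfile:
    """Bioenergetic-space geometry for one group."""

    basal: ATPFlux
    maximal: ATPFlux
    capacity: float
    flexibility: float
    pct_oxphos_basal: float
    pct_oxphos_max: float
    fraction_capacity_used: float
    glycolytic_index: float
    warnings: List[str] = field(default_factory=list)


def summarize_phases(plate: PlateAssay, cycles_per_phase: int = 3) -> RateSummary:
    """Average the last ``cycles_per_phase`` measurement cycles of each phase.

    Rates are divided by well protein before aggregating per group
    (mean +/- SEM across wells).  All mandatory phases must be present;
    monensin is optional and its absence is recorded on the summary.
    """
    if cycles_per_phase < 1:
        raise ParameterError("cycles_per_phase must be >= 1")
    present = set(plate.data["phase"])
    missing = [p for p in MANDATORY_PHASES if p not in present]
    if missing:
        raise PhaseError(f"plate is missing mandatory phase(s) {missing}")
    has_monensin = "monensin" in present

    df = plate.data.copy()
    df["protein"] = df["well"].map(plate.protein_ug)
    if df["protein"].isna().any():
        bad = sorted(df.loc[df["protein"].isna(), "well"].unique())
        raise ParameterError(f"no protein value for wells {bad}")
    df["ocr_norm"] = df["ocr"] / df["protein"]
    df["ecar_norm"] = df["ecar"] / df["protein"]

    # last N cycles of each phase, per well
    df = df.sort_values("measurement")
    tail = df.groupby(["well", "phase"], sort=False).tail(cycles_per_phase)
    per_well = tail.groupby(["group", "well", "phase"], sort=False)[
        ["ocr_norm", "ecar_norm"]
    ].mean().reset_index()

    groups: Dict[str, GroupRates] = {}
    for group, sub in per_well.groupby("group"):
        ocr: Dict[str, float] = {}
        ecar: Dict[str, float] = {}
        ocr_sem: Dict[str, float] = {}
        ecar_sem: Dict[str, float] = {}
        warn: List[str] = []
        n_wells = sub["well"].nunique()
        for phase, ph in sub.groupby("phase"):
            ocr[str(phase)] = float(ph["ocr_norm"].mean())
            ecar[str(phase)] = float(ph["ecar_norm"].mean())
            if len(ph) > 1:
                ocr_sem[str(phase)] = float(ph["ocr_norm"].sem())
                ecar_sem[str(phase)] = float(ph["ecar_norm"].sem())
            else:
                ocr_sem[str(phase)] = math.nan
                ecar_sem[str(phase)] = math.nan
                msg = f"{group}: single well; SEM undefined"
                if msg not in warn:
                    warn.append(msg)
        groups[str(group)] = GroupRates(
            group=str(group), n_wells=int(n_wells), ocr=ocr, ecar=ecar,
            ocr_sem=ocr_sem, ecar_sem=ecar_sem, warnings=warn,
        )
    return RateSummary(groups=groups, cycles_per_phase=cycles_per_phase,
                       has_monensin=has_monensin)


def ppr_from_ecar(
    ecar: float, ocr_mito: float, constants: AssayConstants
) -> tuple[float, float]:
    """Convert ECAR (mpH/min) to proton production rates (pmol H+/min).

    Total PPR is ECAR over the medium buffering power; the glycolytic PPR
    subtracts the respiratory CO2/bicarbonate contribution (floored at 0).
    """
    if constants.buffering_power <= 0:
        raise ParameterError("buffering_power must be positive")
    ppr_total = ecar / constants.buffering_power
    ppr_glyc = max(0.0, ppr_total - ocr_mito * constants.co2_h_per_o2)
    return ppr_total, ppr_glyc


def compute_jatp(
    rates: GroupRates, constants: AssayConstants, state: str = "basal",
    has_monensin: bool = True,
) -> ATPFlux:
    """ATP production rates for one group in the basal or maximal state.

    basal:
        ``J_ATPox = OCR_coupled * 2 * po_ox`` (two O atoms per O2);
        ``J_ATPglyc = PPR_glyc * atp_per_lactate + OCR_mito * 2 * glyc_ox_coupling``.
    max:
        oxidative — coupled respiration under FCCP is ``OCR_mito_max - OCR_leak``;
        glycolytic — ECAR under rotenone/myxothiazol + monensin with the
        respiratory acidification term at zero (mitochondria inhibited).
    """
    if state == "basal":
        _, ppr_glyc = ppr_from_ecar(rates.ecar["basal"], rates.ocr_mito, constants)
        j_ox = rates.ocr_coupled * 2.0 * constants.po_ox
        j_glyc = (ppr_glyc * constants.atp_per_lactate
                  + rates.ocr_mito * 2.0 * constants.glyc_ox_coupling)
        return ATPFlux(j_atp_ox=j_ox, j_atp_glyc=j_glyc, state="basal")
    if state == "max":
        if "fccp" not in rates.ocr:
            raise PhaseError("maximal state requires the fccp phase")
        if not has_monensin or "monensin" not in rates.ecar:
            raise PhaseError("maximal glycolytic state requires the monensin phase")
        coupled_max = max(0.0, rates.ocr_mito_max - rates.ocr_leak)
        j_ox_max = coupled_max * 2.0 * constants.po_ox
        _, ppr_glyc_max = ppr_from_ecar(rates.ecar["monensin"], 0.0, constants)
        j_glyc_max = ppr_glyc_max * constants.atp_per_lactate
        return ATPFlux(j_atp_ox=j_ox_max, j_atp_glyc=j_glyc_max, state="max")
    raise ParameterError(f"state must be 'basal' or 'max', got {state!r}")


def flexibility_length(basal_total: float, glyc_max: float, ox_max: float) -> float:
    """Length of {(x, y): x + y = basal_total, 0 <= x <= glyc_max, 0 <= y <= ox_max}.

    The segment of the constant-total-ATP line inside the capacity rectangle;
    closed form: x ranges over [max(0, T - ox_max), min(glyc_max, T)] and the
    line has slope -1, so the length is sqrt(2) times the x extent.
    """
    t = basal_total
    x_lo = max(0.0, t - ox_max)
    x_hi = min(glyc_max, t)
    if x_hi <= x_lo:
        return 0.0
    return math.sqrt(2.0) * (x_hi - x_lo)


def space_profile(basal: ATPFlux, maximal: ATPFlux) -> SpaceProfile:
    """Bioenergetic-space summary from basal and maximal ATP fluxes.

    capacity = glyc_max * ox_max (rectangle area, (pmol ATP/min/µg)^2);
    flexibility = clipped constant-sum segment length (pmol ATP/min/µg);
    percentages are shares of the respective total; fraction_capacity_used is
    basal total over the sum of the two maxima.  Percentages are NaN (with a
    warning recorded) when the basal total is zero.
    """
    warnings_: List[str] = []
    glyc_max, ox_max = maximal.j_atp_glyc, maximal.j_atp_ox
    if glyc_max < basal.j_atp_glyc or ox_max < basal.j_atp_ox:
        warnings_.append(
            "maximal flux below basal flux for at least one axis; "
            "capacity rectangle does not contain the basal point"
        )
    capacity = glyc_max * ox_max
    flexibility = flexibility_length(basal.j_atp_total, glyc_max, ox_max)

    basal_total = basal.j_atp_total
    if basal_total > 0:
        pct_ox_basal = 100.0 * basal.j_atp_ox / basal_total
        glyc_index = 100.0 * basal.j_atp_glyc / basal_total
    else:
        pct_ox_basal = math.nan
        glyc_index = math.nan
        warnings_.append("basal total ATP rate is zero; percentage shares undefined")
    max_total = maximal.j_atp_total
    pct_ox_max = 100.0 * ox_max / max_total if max_total > 0 else math.nan
    frac_used = basal_total / max_total if max_total > 0 else math.nan

    return SpaceProfile(
        basal=basal,
        maximal=maximal,
        capacity=capacity,
        flexibility=flexibility,
        pct_oxphos_basal=pct_ox_basal,
        pct_oxphos_max=pct_ox_max,
        fraction_capacity_used=frac_used,
        glycolytic_index=glyc_index,
        warnings=warnings_,
    )
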