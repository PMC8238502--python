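"""Closed-form assay normalizations: ddCt expression, tumor volume, media
exchange fluxes, fold changes, background subtraction, and ChIP enrichment."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import ParameterError

__all__ = [
    "QpcrMeasurement",
    "MediaExchange",
    "ddct_expression",
    "tumor_volume",
    "media_flux",
    "fold_vs_control",
    "background_subtract",
    "chip_relative_enrichment",
    "doubling_time",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR sample: target and reference (housekeeping) cycle thresholds."""

    sample_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ParameterError(f"{self.sample_id}: Ct values must be finite")


@dataclass(frozen=True)
class MediaExchange:
    """Spent-vs-blank media concentrations for one metabolite over one incubation."""

    metabolite: str
    conc_blank_end_mm: float
    conc_spent_end_mm: float
    volume_ml: float
    duration_h: float
    mean_viable_cells: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.duration_h <= 0:
            raise ParameterError("volume and duration must be positive")


def ddct_expression(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression by the ddCt method, 2^-((dCt_sample) - (dCt_calibrator)).

    Assumes an amplification efficiency of 2 per cycle and normalization to a
    reference (housekeeping) gene measured in the same samples.
    """
    d_sample = sample.ct_target - sample.ct_reference
    d_cal = calibrator.ct_target - calibrator.ct_reference
    return float(2.0 ** (-(d_sample - d_cal)))


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-approximation tumor volume, length x width^2 x pi/6 (mm^3)."""
    if length_mm < 0 or width_mm < 0:
        raise ParameterError("caliper measurements must be non-negative")
    if width_mm > length_mm:
        logger.warning("tumor_volume: width %.3g > length %.3g; swapping", width_mm, length_mm)
        length_mm, width_mm = width_mm, length_mm
    return float(length_mm * width_mm**2 * math.pi / 6.0)


def media_flux(x: MediaExchange) -> float:
    """Signed exchange flux in mol/cell/hour (negative = consumption).

    Blank wells incubated without cells provide the degradation-corrected
    reference: flux = (spent - blank) [mM] x volume [mL] / (cells x hours).
    mM x mL = µmol, hence the 1e-6 factor to mol.
    """
    if x.mean_viable_cells <= 0:
        raise ParameterError("mean_viable_cells must be positive")
    umol = (x.conc_spent_end_mm - x.conc_blank_end_mm) * x.volume_ml
    return float(umol * 1e-6 / (x.mean_viable_cells * x.duration_h))


def fold_vs_control(
    values: Sequence[float],
    control: Sequence[float],
    log2: bool = False,
    paired: bool = False,
) -> Tuple[float, float]:
    """Fold change of ``values`` over ``control``, with an SEM.

    Unpaired (default): ratio of means; the SEM propagates the replicate
    variation of ``values`` against the control mean.  Paired: per-replicate
    ratios are averaged (requires equal lengths).  With ``log2=True`` the fold
    (and its SEM, by the delta method) is reported on the log2 scale.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(control, dtype=float)
    if v.size == 0 or c.size == 0:
        raise ParameterError("values and control must be non-empty")
    c_mean = c.mean()
    if c_mean == 0:
        raise ParameterError("control mean is zero; fold change undefined")
    if paired:
        if v.shape != c.shape:
            raise ParameterError("paired mode requires equal-length replicate vectors")
        ratios = v / c
        fold = float(ratios.mean())
        sem = float(ratios.std(ddof=1) / math.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    else:
        fold = float(v.mean() / c_mean)
        sem = float(v.std(ddof=1) / math.sqrt(len(v)) / abs(c_mean)) if len(v) > 1 else 0.0
    if log2:
        if fold <= 0:
            raise ParameterError("log2 fold change undefined for non-positive fold")
        sem = sem / (fold * math.log(2.0))
        fold = math.log2(fold)
    return fold, sem


def background_subtract(signal_with_probe: float, signal_without_probe: float) -> float:
    """Probe-free background subtraction, floored at zero."""
    return max(0.0, signal_with_probe - signal_without_probe)


def chip_relative_enrichment(
    signal: float, igg: float, neg_regions: Sequence[Tuple[float, float]]
) -> float:
    """ChIP fold enrichment as a ratio of ratios.

    The region's signal/IgG ratio is divided by the mean signal/IgG ratio over
    negative-control (unbound) regions.
    """
    if igg <= 0:
        raise ParameterError("IgG control signal must be positive")
    if not neg_regions:
        raise ParameterError("at least one negative-control region is required")
    neg_ratios = []
    for ns, ni in neg_regions:
        if ni <= 0:
            raise ParameterError("negative-region IgG signal must be positive")
        neg_ratios.append(ns / ni)
    denom = float(np.mean(neg_ratios))
    if denom == 0:
        raise ParameterError("mean negative-region ratio is zero; enrichment undefined")
    return float((signal / igg) / denom)


def doubling_time(times_h: Sequence[float], counts: Sequence[float]) -> float:
    """Population doubling time from a log-linear fit of counts over time (hours)."""
    t = np.asarray(times_h, dtype=float)
    n = np.asarray(counts, dtype=float)
    if len(t) < 2 or np.any(n <= 0):
        raise ParameterError("need >= 2 timepoints with positive counts")
    slope, _ = np.polyfit(t, np.log2(n), 1)
    if slope <= 0:
        return math.inf
    return float(1.0 / slope)
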