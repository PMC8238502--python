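"""Natural-abundance / tracer-purity correction of mass isotopologue distributions.

GC/MS or LC/MS intensities of a metabolite fragment measured after a stable
isotope labeling experiment mix three signals: the biological incorporation of
tracer atoms, the natural occurrence of heavy isotopes in every atom of the
(often derivatized) fragment, and the imperfect isotopic purity of the tracer
itself.  This module builds the linear operator mapping the true label
distribution onto the observed mass-shift distribution and inverts it by
non-negative least squares, yielding fractional enrichments that sum to one.

The convention for column ``j`` of the correction matrix (true label count
``j``) is the standard one: natural abundance applies to every atom of the
fragment except the ``j`` labeled positions, and the labeled positions retain
their label with probability equal to the tracer's isotopic purity
(a Binomial(j, p) mass-shift distribution).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit, nnls
from scipy.stats import binom

from .errors import (
    EmptyMeasurementError,
    InsufficientRangeError,
    InvalidFormulaError,
    ParameterError,
)
from .isotopes import NATURAL_ABUNDANCE, IsotopeTable, validate_isotope_table

__all__ = [
    "ElementFormula",
    "TracerConfig",
    "RawMID",
    "FractionalEnrichment",
    "CorrectionMatrix",
    "parse_formula",
    "build_correction_matrix",
    "correct_mid",
    "labeled_fraction",
    "fit_labeling_kinetics",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementFormula:
    """Elemental composition of a measured fragment.

    ``n_tracer`` counts the positions that can carry tracer label — for a
    TBDMS-derivatized citrate fragment measured under a 13C tracer this is the
    number of citrate backbone carbons, not the total carbon count of the
    derivatized ion.
    """

    counts: Mapping[str, int]
    n_tracer: int

    def __post_init__(self) -> None:
        for element, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise InvalidFormulaError(f"count for {element} must be a non-negative integer")
        if self.n_tracer < 0:
            raise InvalidFormulaError("n_tracer must be non-negative")
        object.__setattr__(self, "counts", dict(self.counts))

    def count(self, element: str) -> int:
        return int(self.counts.get(element, 0))

    def __str__(self) -> str:
        body = "".join(f"{el}{n}" for el, n in sorted(self.counts.items()) if n > 0)
        return f"{body}@{self.n_tracer}"


def parse_formula(text: str) -> ElementFormula:
    """Parse ``"C6H12O6@6"`` into an :class:`ElementFormula`.

    The optional ``@n`` suffix gives the number of tracer-labelable positions;
    without it, every atom of the tracer element is assumed labelable (the
    right default for underivatized metabolites, wrong for silylated
    fragments, which should always carry an explicit suffix).
    """
    text = text.strip()
    if "@" in text:
        body, _, suffix = text.partition("@")
        n_tracer = int(suffix)
    else:
        body, n_tracer = text, -1
    counts: dict[str, int] = {}
    consumed = 0
    for match in _FORMULA_RE.finditer(body):
        if not match.group(0):
            continue
        consumed += len(match.group(0))
        element = match.group(1)
        counts[element] = counts.get(element, 0) + (int(match.group(2)) if match.group(2) else 1)
    if consumed != len(body) or not counts:
        raise InvalidFormulaError(f"cannot parse formula {text!r}")
    if n_tracer < 0:
        n_tracer = counts.get("C", 0)
    return ElementFormula(counts=counts, n_tracer=n_tracer)


@dataclass(frozen=True)
class TracerConfig:
    """Identity and purity of the stable-isotope tracer.

    Defaults describe a uniformly 13C-labeled tracer such as [U-13C]-glucose
    or [U-13C]-glutamine at 99% isotopic purity.
    """

    element: str = "C"
    purity: float = 0.99
    shift_per_label: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ParameterError("tracer purity must be in (0, 1]")
        if self.shift_per_label < 1:
            raise ParameterError("shift_per_label must be a positive integer")


@dataclass
class RawMID:
    """Measured isotopologue intensities for one fragment at one timepoint."""

    metabolite: str
    formula: ElementFormula
    time_min: float
    replicate: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be a 1-D vector over mass shifts")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class FractionalEnrichment:
    """Corrected label distribution: fractions over m+0..m+n_tracer summing to 1."""

    metabolite: str
    time_min: float
    fractions: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ValueError("fractions must be non-negative")
        total = float(self.fractions.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, expected 1 +/- 1e-6")

    @property
    def n_tracer(self) -> int:
        return len(self.fractions) - 1


@dataclass
class CorrectionMatrix:
    """Linear map from true label counts (columns) to observed mass shifts (rows)."""

    matrix: np.ndarray
    formula: ElementFormula
    tracer: TracerConfig
    isotope_version: str = "custom"

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tracer(self) -> int:
        return self.matrix.shape[1] - 1


def _element_shift_distribution(isotopes: Sequence[tuple[int, float]], n_atoms: int) -> np.ndarray:
    """Mass-shift distribution of ``n_atoms`` i.i.d. atoms of one element."""
    max_shift = max(shift for shift, _ in isotopes)
    single = np.zeros(max_shift + 1)
    for shift, abundance in isotopes:
        single[shift] += abundance
    dist = np.array([1.0])
    for _ in range(n_atoms):
        dist = np.convolve(dist, single)
    return dist


def _natural_distribution(
    formula: ElementFormula, isotopes: IsotopeTable, exclude: Mapping[str, int]
) -> np.ndarray:
    dist = np.array([1.0])
    for element, n in formula.counts.items():
        n_eff = n - exclude.get(element, 0)
        if n_eff < 0:
            raise InvalidFormulaError(f"cannot exclude more {element} atoms than present")
        if n_eff == 0:
            continue
        if element not in isotopes:
            raise InvalidFormulaError(f"no isotope data for element {element}")
        dist = np.convolve(dist, _element_shift_distribution(isotopes[element], n_eff))
    return dist


def build_correction_matrix(
    formula: ElementFormula,
    tracer: TracerConfig | None = None,
    isotopes: IsotopeTable | None = None,
    K: int | None = None,
) -> CorrectionMatrix:
    """Build the (K+1) x (n_tracer+1) correction matrix for one fragment.

    Column ``j`` is the observed mass-shift distribution of a molecule with
    exactly ``j`` truly labeled positions: the natural-abundance distribution
    of all atoms except those ``j`` positions, convolved with a
    Binomial(j, purity) distribution of retained labels, truncated to mass
    shifts ``0..K``.  ``K`` defaults to ``n_tracer + 3`` to cover the Si/S
    isotope envelopes of silylated fragments.
    """
    tracer = tracer or TracerConfig()
    table = isotopes if isotopes is not None else NATURAL_ABUNDANCE
    if isotopes is not None:
        validate_isotope_table(table)
    n_tracer = formula.n_tracer
    if n_tracer > formula.count(tracer.element):
        raise InvalidFormulaError(
            f"n_tracer={n_tracer} exceeds {tracer.element} count {formula.count(tracer.element)}"
        )
    if K is None:
        K = n_tracer + 3
    if K < n_tracer:
        raise InsufficientRangeError(f"K={K} is smaller than n_tracer={n_tracer}")

    matrix = np.zeros((K + 1, n_tracer + 1))
    for j in range(n_tracer + 1):
        natural = _natural_distribution(formula, table, exclude={tracer.element: j})
        # Binomial(j, p) labels retained; each adds shift_per_label mass units.
        label = np.zeros(j * tracer.shift_per_label + 1)
        label[:: tracer.shift_per_label or 1][: j + 1] = binom.pmf(np.arange(j + 1), j, tracer.purity)
        column = np.convolve(natural, label)
        n = min(len(column), K + 1)
        matrix[:n, j] = column[:n]
    version = "custom" if isotopes is not None else "natural:" + _default_version()
    return CorrectionMatrix(matrix=matrix, formula=formula, tracer=tracer, isotope_version=version)


def _default_version() -> str:
    from .isotopes import NATURAL_ABUNDANCE_VERSION

    return NATURAL_ABUNDANCE_VERSION


def correct_mid(raw: RawMID, cm: CorrectionMatrix) -> FractionalEnrichment:
    """Deconvolve a raw MID into fractional enrichments.

    Solves ``argmin_{x >= 0} || cm @ x - raw/sum(raw) ||_2`` with
    :func:`scipy.optimize.nnls`, then renormalizes the solution to sum to 1 so
    that noise-truncated solutions remain valid probability vectors.
    """
    if len(raw.intensities) != cm.n_rows:
        raise ValueError(
            f"intensity vector length {len(raw.intensities)} does not match "
            f"correction-matrix rows {cm.n_rows}"
        )
    total = float(raw.intensities.sum())
    if total <= 0:
        raise EmptyMeasurementError(
            f"{raw.metabolite} ({raw.replicate}, t={raw.time_min}) has zero total intensity"
        )
    observed = raw.intensities / total
    x, _ = nnls(cm.matrix, observed)
    s = x.sum()
    if s <= 0:
        raise EmptyMeasurementError(f"NNLS returned an all-zero solution for {raw.metabolite}")
    return FractionalEnrichment(
        metabolite=raw.metabolite, time_min=raw.time_min, fractions=x / s, replicate=raw.replicate
    )


def labeled_fraction(fe: FractionalEnrichment, shifts: Iterable[int]) -> float:
    """Sum of selected isotopologue fractions, e.g. the m+3 anaplerotic species."""
    shifts = set(shifts)
    bad = [s for s in shifts if s < 0 or s > fe.n_tracer]
    if bad:
        raise ParameterError(f"mass shifts {sorted(bad)} outside 0..{fe.n_tracer}")
    return float(sum(fe.fractions[s] for s in shifts))


def fit_labeling_kinetics(
    timepoints: Sequence[float], fractions: Sequence[float]
) -> tuple[float, float]:
    """Fit the mono-exponential approach-to-plateau x(t) = x_ss (1 - exp(-k t)).

    Returns ``(plateau, rate)`` with the plateau constrained to [0, 1] and the
    rate to be non-negative.  At least three timepoints including t=0 are
    required; grossly non-monotone data are fit anyway (least squares).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("timepoints and fractions must be 1-D vectors of equal length")
    if len(t) < 3:
        raise ParameterError("kinetic fit needs at least 3 timepoints")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if np.allclose(y, 0.0):
        return 0.0, 0.0

    def model(tt: np.ndarray, x_ss: float, k: float) -> np.ndarray:
        return x_ss * (1.0 - np.exp(-k * tt))

    plateau0 = float(np.clip(y.max(), 1e-6, 1.0))
    positive = t > 0
    k0 = 1.0 / max(float(np.median(t[positive])), 1e-6) if positive.any() else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # curve_fit warns on flat directions at the bounds
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(plateau0, k0),
            bounds=([0.0, 0.0], [1.0, np.inf]),
            maxfev=10000,
        )
    return float(popt[0]), float(popt[1])
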