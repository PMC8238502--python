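"""Phase summaries, ATP rates, and the bioenergetic-space geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoflux.bioenergetics import (
    ATPFlux,
    AssayConstants,
    GroupRates,
    PlateAssay,
    compute_jatp,
    flexibility_length,
    ppr_from_ecar,
    space_profile,
    summarize_phases,
)
from isoflux.errors import ParameterError, PhaseError
from isoflux.synthdata import ScenarioSpec, make_plate

# explicit test constants: nothing external is ground truth
TEST_CONSTANTS = AssayConstants(
    buffering_power=0.1, atp_per_lactate=1.0, po_ox=2.0, co2_h_per_o2=0.5,
    glyc_ox_coupling=0.0,
)


def segment_length_bruteforce(total, glyc_max, ox_max, n=200_001):
    """Independent oracle: discretize the line x+y=total and sum in-rectangle steps."""
    if total <= 0:
        return 0.0
    x = np.linspace(0.0, total, n)
    y = total - x
    inside = (x <= glyc_max) & (y <= ox_max)
    step = (x[1] - x[0]) * math.sqrt(2.0)
    # count steps whose both endpoints are inside
    return float(np.sum(inside[:-1] & inside[1:]) * step)


class TestPhases:
    def test_constant_noiseless_traces_recovered_exactly(self):
        spec = ScenarioSpec(seed=0, sigma_plate=0.0, protein_cv=0.0)
        plate, truth = make_plate(spec)
        summary = summarize_phases(plate)
        for _, row in truth.iterrows():
            g = summary.groups[row["group"]]
            assert g.ocr[row["phase"]] == pytest.approx(row["ocr_per_ug"], rel=1e-12)
            assert g.ecar[row["phase"]] == pytest.approx(row["ecar_per_ug"], rel=1e-12)

    def test_derived_components_match_generator_truth(self):
        spec = ScenarioSpec(seed=0, sigma_plate=0.0, protein_cv=0.0)
        plate, _ = make_plate(spec)
        g = summarize_phases(plate).groups["control"]
        phases = spec.plate_truth["control"]
        assert g.ocr_coupled == pytest.approx(phases["basal"][0] - phases["oligomycin"][0])
        assert g.ocr_leak == pytest.approx(phases["oligomycin"][0] - phases["rotmyx"][0])
        assert g.ocr_mito_max == pytest.approx(phases["fccp"][0] - phases["rotmyx"][0])

    def test_missing_mandatory_phase_raises(self):
        spec = ScenarioSpec(seed=0)
        plate, _ = make_plate(spec)
        crippled = PlateAssay(
            data=plate.data[plate.data["phase"] != "fccp"].copy(),
            protein_ug=plate.protein_ug,
        )
        with pytest.raises(PhaseError):
            summarize_phases(crippled)

    def test_out_of_order_phases_rejected(self):
        spec = ScenarioSpec(seed=0)
        plate, _ = make_plate(spec)
        shuffled = plate.data.copy()
        shuffled.loc[shuffled.index[:3], "phase"] = "monensin"
        with pytest.raises(PhaseError):
            PlateAssay(data=shuffled, protein_ug=plate.protein_ug)

    def test_single_well_group_flags_sem(self):
        spec = ScenarioSpec(seed=0, wells_per_group=1)
        plate, _ = make_plate(spec)
        summary = summarize_phases(plate)
        g = next(iter(summary.groups.values()))
        assert math.isnan(g.ocr_sem["basal"])
        assert any("SEM undefined" in w for w in g.warnings)

    def test_negative_derived_rates_floored_with_warning(self):
        g = GroupRates(
            group="g", n_wells=2,
            ocr={"basal": 1.0, "oligomycin": 2.0, "fccp": 3.0, "rotmyx": 0.5},
            ecar={"basal": 1.0},
        )
        assert g.ocr_coupled == 0.0
        assert any("ocr_coupled" in w for w in g.warnings)


class TestPPR:
    @pytest.mark.parametrize(
        "ecar, ocr_mito, expected",
        [(20.0, 0.0, (200.0, 200.0)), (20.0, 50.0, (200.0, 175.0)), (0.0, 0.0, (0.0, 0.0))],
    )
    def test_examples(self, ecar, ocr_mito, expected):
        assert ppr_from_ecar(ecar, ocr_mito, TEST_CONSTANTS) == pytest.approx(expected)

    def test_zero_buffering_power_rejected(self):
        with pytest.raises(ParameterError):
            ppr_from_ecar(1.0, 0.0, AssayConstants(buffering_power=0.0))


class TestJatp:
    def test_basal_arithmetic(self):
        rates = GroupRates(
            group="g", n_wells=3,
            ocr={"basal": 100.0, "oligomycin": 0.0, "fccp": 150.0, "rotmyx": 0.0},
            ecar={"basal": 0.0},
        )
        flux = compute_jatp(rates, TEST_CONSTANTS, "basal")
        assert flux.j_atp_ox == pytest.approx(400.0)  # coupled 100 * 2 * po_ox 2
        assert flux.j_atp_glyc == pytest.approx(0.0)
        assert flux.j_atp_total == pytest.approx(400.0)

    def test_all_zero_rates(self):
        rates = GroupRates(
            group="g", n_wells=3,
            ocr=dict.fromkeys(["basal", "oligomycin", "fccp", "rotmyx"], 0.0),
            ecar=dict.fromkeys(["basal", "oligomycin", "fccp", "rotmyx", "monensin"], 0.0),
        )
        for state in ("basal", "max"):
            flux = compute_jatp(rates, TEST_CONSTANTS, state)
            assert flux.j_atp_total == 0.0

    def test_max_without_monensin_raises(self):
        rates = GroupRates(
            group="g", n_wells=3,
            ocr=dict.fromkeys(["basal", "oligomycin", "fccp", "rotmyx"], 1.0),
            ecar={"basal": 1.0},
        )
        with pytest.raises(PhaseError):
            compute_jatp(rates, TEST_CONSTANTS, "max", has_monensin=False)

    def test_noiseless_plate_recovers_true_j(self):
        spec = ScenarioSpec(seed=0, sigma_plate=0.0, protein_cv=0.0)
        plate, _ = make_plate(spec)
        g = summarize_phases(plate).groups["control"]
        flux = compute_jatp(g, TEST_CONSTANTS, "basal")
        truth = spec.plate_truth["control"]
        ocr_coupled = truth["basal"][0] - truth["oligomycin"][0]
        ocr_mito = truth["basal"][0] - truth["rotmyx"][0]
        ppr_glyc = truth["basal"][1] / 0.1 - ocr_mito * 0.5
        assert flux.j_atp_ox == pytest.approx(ocr_coupled * 2 * 2.0, abs=1e-9)
        assert flux.j_atp_glyc == pytest.approx(ppr_glyc, abs=1e-9)


class TestSpaceGeometry:
    def test_worked_rectangle_example(self):
        profile = space_profile(
            ATPFlux(j_atp_ox=10.0, j_atp_glyc=5.0, state="basal"),
            ATPFlux(j_atp_ox=20.0, j_atp_glyc=10.0, state="max"),
        )
        assert profile.capacity == pytest.approx(200.0)
        assert profile.pct_oxphos_basal == pytest.approx(66.67, abs=0.01)
        assert profile.flexibility == pytest.approx(math.dist((0, 15), (10, 5)), abs=1e-9)
        assert profile.fraction_capacity_used == pytest.approx(0.5)

    def test_degenerate_points(self):
        zero_basal = space_profile(ATPFlux(0, 0, "basal"), ATPFlux(10, 10, "max"))
        assert zero_basal.flexibility == 0.0
        assert math.isnan(zero_basal.pct_oxphos_basal)
        assert any("zero" in w for w in zero_basal.warnings)
        zero_max = space_profile(ATPFlux(1, 1, "basal"), ATPFlux(0, 0, "max"))
        assert zero_max.capacity == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_flexibility_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        glyc_max, ox_max = rng.uniform(0, 50, 2)
        total = rng.uniform(0, glyc_max + ox_max)
        closed = flexibility_length(total, glyc_max, ox_max)
        brute = segment_length_bruteforce(total, glyc_max, ox_max)
        assert closed == pytest.approx(brute, abs=1e-3)

    def test_scale_equivariance(self):
        basal = ATPFlux(j_atp_ox=8.0, j_atp_glyc=4.0, state="basal")
        maximal = ATPFlux(j_atp_ox=16.0, j_atp_glyc=10.0, state="max")
        p1 = space_profile(basal, maximal)
        k = 2.0
        p2 = space_profile(
            ATPFlux(basal.j_atp_ox * k, basal.j_atp_glyc * k, "basal"),
            ATPFlux(maximal.j_atp_ox * k, maximal.j_atp_glyc * k, "max"),
        )
        assert p2.flexibility == pytest.approx(k * p1.flexibility)
        assert p2.capacity == pytest.approx(k**2 * p1.capacity)
        assert p2.pct_oxphos_basal == pytest.approx(p1.pct_oxphos_basal)
        assert p2.fraction_capacity_used == pytest.approx(p1.fraction_capacity_used)

    def test_additivity_invariant(self):
        flux = ATPFlux(j_atp_ox=3.25, j_atp_glyc=1.75, state="basal")
        assert flux.j_atp_total == flux.j_atp_ox + flux.j_atp_glyc
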