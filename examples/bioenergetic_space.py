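"""Bioenergetic-space analysis of a synthetic extracellular-flux plate.

Generates a two-group plate (a drug-sensitive line and a resistant line with
raised respiration), summarizes the injection phases, and derives ATP
production rates, capacity, and flexibility per group.
"""

from isoflux import AssayConstants, compute_jatp, space_profile, summarize_phases
from isoflux.synthdata import ScenarioSpec, make_plate

spec = ScenarioSpec(seed=3, sigma_plate=0.03)
plate, truth = make_plate(spec)
summary = summarize_phases(plate)
constants = AssayConstants()  # documented defaults; calibrate buffering_power per assay

for group, rates in summary.groups.items():
    basal = compute_jatp(rates, constants, "basal")
    maximal = compute_jatp(rates, constants, "max")
    profile = space_profile(basal, maximal)
    print(
        f"{group:10s} J_ATPox={basal.j_atp_ox:7.1f}  J_ATPglyc={basal.j_atp_glyc:7.1f} "
        f"%OXPHOS={profile.pct_oxphos_basal:5.1f}  capacity={profile.capacity:9.0f} "
        f"flexibility={profile.flexibility:7.1f}"
    )
# Rates are pmol ATP/min/ug protein.  The resistant group shows a higher
# oxidative share and a larger capacity rectangle: the hallmark of a cell line
# that has expanded its OXPHOS headroom.
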