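"""The small closed-form assay normalizations, on worked numbers."""

from isoflux.assay_metrics import (
    MediaExchange,
    QpcrMeasurement,
    background_subtract,
    chip_relative_enrichment,
    ddct_expression,
    fold_vs_control,
    media_flux,
    tumor_volume,
)

# qPCR: one cycle later than the calibrator at equal reference = half the expression
rel = ddct_expression(QpcrMeasurement("treated", 25, 20), QpcrMeasurement("control", 24, 20))
print(f"ddCt relative expression: {rel:.2f}")

# caliper tumor volume, ellipsoid approximation
print(f"tumor volume (10 x 5 mm): {tumor_volume(10, 5):.1f} mm^3")

# media exchange: 1 mM glutamine drawn down over 72 h by a million cells
flux = media_flux(MediaExchange("glutamine", 4.0, 3.0, volume_ml=2.0,
                                duration_h=72.0, mean_viable_cells=1e6))
print(f"glutamine flux: {flux * 1e15:.1f} fmol/cell/h (negative = consumption)")

# ROS fold over control after probe-free background subtraction
treated = background_subtract(5000, 500)
control = background_subtract(3000, 500)
fold, _ = fold_vs_control([treated], [control])
print(f"ROS fold vs control: {fold:.2f}")

# ChIP enrichment as ratio-of-ratios over negative control regions
print(f"ChIP fold enrichment: {chip_relative_enrichment(10, 1, [(2, 1), (2, 1)]):.2f}")
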