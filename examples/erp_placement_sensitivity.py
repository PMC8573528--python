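"""How much does electrode misplacement change a measured ERP?

Simulates five participants' stimulus-locked epochs on the five marked
electrodes (a vertex-focused component peaking at 300 ms), interpolates each
participant's ERP to a template whose ring electrodes sit at a different
inclination, and runs the per-timepoint paired comparison with Bonferroni
correction over the 512 samples of the 1 s trial.

With only five sampling sites the interpolation domain is their convex
hull; the template ring here lies inside it, so values are true barycentric
interpolates (no nearest-neighbour fallback, ``extrapolated_labels`` empty).
"""

from sparsecap import (
    ERPComponent,
    LabeledPoints,
    SyntheticERPConfig,
    erp_sensitivity,
    generate_erp_dataset,
)

actual = LabeledPoints({
    "Cz": (0.0, 0.0, 90.0), "FPz": (0.0, 90.0, 0.0), "Oz": (0.0, -90.0, 0.0),
    "T7": (-90.0, 0.0, 0.0), "T8": (90.0, 0.0, 0.0),
})
# the template believes the ring sat higher on the head (toward the vertex)
shifted = LabeledPoints({
    "Cz": (0.0, 0.0, 90.0),
    "FPz": (0.0, 58.0, 22.0), "Oz": (0.0, -58.0, 22.0),
    "T7": (-58.0, 0.0, 22.0), "T8": (58.0, 0.0, 22.0),
})

cfg = SyntheticERPConfig(
    n_participants=5, n_trials=60, noise_sd=3.0, seed=7,
    components=(ERPComponent(latency_ms=300.0, width_ms=60.0, amplitude_uv=15.0,
                             focus_label="Cz", spread_mm=60.0),))
epochs = generate_erp_dataset(cfg, actual)

res = erp_sensitivity(epochs, actual, shifted, alpha=0.05)
cmp = res.comparison
times = res.actual_erps[0].times

print(f"epochs kept per participant : {res.n_kept}")
print(f"Bonferroni-corrected alpha  : {cmp.alpha_corrected:.6g}  (= 0.05/512)")
print(f"fallback-extrapolated labels: {res.template_erps[0].extrapolated_labels or 'none'}")
for i, lab in enumerate(cmp.channel_labels):
    sig = cmp.sig_mask[i]
    span = f"{times[sig][0]:.0f}..{times[sig][-1]:.0f} ms" if sig.any() else "-"
    print(f"  {lab:4s}: {int(sig.sum()):3d}/512 samples significant   {span}")
print("Ring channels diverge around the 300 ms peak: a ring placed closer to")
print("the vertex picks up more of the vertex-focused field than the spot the")
print("electrode actually occupied. Cz itself is unmoved, so it shows nothing.")
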