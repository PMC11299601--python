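"""Compare ePIE, rPIE and CRISP on the same noise-free dataset.

All three engines share the forward model and the per-iteration random
update order; they differ only in the per-sample step.  The table reports
convergence (final R_F), illumination recovery (reciprocal-space probe
correlation inside the aperture support) and image accuracy (worst Fourier
ring correlation against truth below half-Nyquist, after removing the
global phase/translation ambiguities, over the illuminated region).
"""

import ptycrisp as pc

sim = pc.simulate(pc.SimSpec(noise="clean"))
O0, P0 = pc.default_initializers(sim.dataset)
box = pc.scan_coverage_box(sim.scan, sim.truth_probe, sim.truth_object.shape)
ref = sim.truth_object.values[box]

runs = {
    "epie": lambda: pc.run_pie(sim.dataset, sim.scan, O0, P0,
                               pc.PieParams(K=300, seed=3), "epie"),
    "rpie": lambda: pc.run_pie(sim.dataset, sim.scan, O0, P0,
                               pc.PieParams(K=300, seed=3), "rpie"),
    "crisp": lambda: pc.run_crisp(sim.dataset, sim.scan, O0, P0,
                                  pc.CrispParams(c=0.01, K=300, seed=3))[0],
}

print("engine   final R_F   probe corr   min FRC (< Nyquist/2)")
for name, run in runs.items():
    res = run()
    pcorr = pc.probe_correlation(res.probe, sim.truth_probe)
    aligned, _ = pc.align_global(res.object.values[box], ref)
    fmin = pc.frc(aligned, ref).min_below(0.25)
    print(f"{name:7s}  {res.r_factor_trace[-1]:.2e}   {pcorr:.5f}      {fmin:.4f}")
# All engines identify the specimen on clean data; differences between
# them appear under noise and unlucky update orders.
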