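"""Blind CRISP reconstruction of a noise-free synthetic dataset.

Starts from an all-ones object and a nominal soft-disk probe, and runs the
subgradient-projection engine with ePIE-like clipping (nu = 1) and
automatic threshold tuning.  R_F is the normalized discrepancy between
measured and modeled diffraction moduli (0 = perfect fit); xi is the
auto-tuned cost threshold, which tracks c times the mean per-sample cost.
"""

import ptycrisp as pc

sim = pc.simulate(pc.SimSpec(noise="clean"))
O0, P0 = pc.default_initializers(sim.dataset)

params = pc.CrispParams(lambda_o=1.0, lambda_p=0.4, nu_o=1.0, nu_p=1.0,
                        c=0.01, K=300, seed=0)
result, state = pc.run_crisp(sim.dataset, sim.scan, O0, P0, params)

print("  k      R_F        mean cost      xi")
for k in (0, 9, 49, 99, 199, 299):
    print(f"{k + 1:4d}  {result.r_factor_trace[k]:.3e}  "
          f"{result.cost_trace[k]:.6e}  {result.xi_trace[k]:.6e}")

pcorr = pc.probe_correlation(result.probe, sim.truth_probe)
print(f"\nfinal R_F          : {result.r_factor_trace[-1]:.3e}")
print(f"probe correlation  : {pcorr:.5f}")
# R_F below 1e-3 and probe correlation ~1 mean the blind run recovered
# both the object and the illumination from the diffraction data alone.
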