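"""The three regimes of the subgradient-projection step on toy costs.

The update x' = x - lam (g(x) - xi)_+ / ||grad g||^2 grad g keeps moving
while the cost exceeds the threshold xi.  On a cost whose minimum is 0 it
behaves like gradient descent; if the minimum E is positive and xi = 0 the
coefficient blows up near the minimizer and the iteration diverges; with
xi > E it stops as soon as it enters the sublevel set {g <= xi}.  Clipping
the coefficient tames the divergent regime — the same mechanism the full
reconstruction engine uses.
"""

import numpy as np

from ptycrisp.toy import ToyProblem, run_toy_subgradient

bowl = run_toy_subgradient(ToyProblem.quadratic_bowl(offset=0.0), K=200)
print(f"E=0,  xi=0   : diverged={bowl.diverged}, "
      f"final |x| = {np.linalg.norm(bowl.points[-1]):.2e}  (converges to the minimizer)")

well = run_toy_subgradient(ToyProblem.gaussian_well(offset=1.0, xi=0.0), K=200)
print(f"E=1,  xi=0   : diverged={well.diverged}, "
      f"{len(well.points) - 1} steps before blow-up")

stop = run_toy_subgradient(ToyProblem.quadratic_bowl(offset=1.0, xi=1.5), K=500)
print(f"E=1,  xi=1.5 : diverged={stop.diverged}, "
      f"final g = {stop.values[-1]:.3f} <= xi  (stopped in the sublevel set)")

clipped = run_toy_subgradient(ToyProblem.gaussian_well(offset=1.0, xi=0.0),
                              clip=1.0, K=200)
print(f"E=1,  xi=0, clipped: diverged={clipped.diverged}  (clipping prevents the blow-up)")
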