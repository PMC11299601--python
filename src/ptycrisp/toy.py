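"""Toy 2-D cost harness for studying the subgradient-projection step.

Isolates the step-size behavior of the CRISP update on small differentiable
costs g(x) >= E with analytic gradients, away from the full ptychographic
problem.  Three regimes matter:

* minimum value E = 0, threshold xi = 0: the iteration converges to the
  minimizer, like gradient descent;
* E > 0, xi = 0: the coefficient (g - 0)/||grad||^2 blows up near the
  minimum (the gradient vanishes while the cost does not) and the iteration
  diverges — the failure mode that motivates clipping and xi > 0;
* xi > E: the iteration terminates as soon as it enters {x : g(x) <= xi}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .crisp import DegenerateDirectionError, subgradient_step

__all__ = ["ToyProblem", "ToyTrajectory", "run_toy_subgradient"]


@dataclass
class ToyProblem:
    """A differentiable scalar cost over 2-D points with analytic gradient.

    ``offset`` is the minimum value E of g (g >= E everywhere).
    """

    g: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    offset: float
    start: np.ndarray
    lam: float = 1.0
    xi: float = 0.0

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        if self.offset < 0:
            raise ValueError("offset E must be nonnegative")

    @classmethod
    def quadratic_bowl(cls, offset: float = 0.0, start=(3.0, 2.0),
                       lam: float = 1.0, xi: float = 0.0) -> "ToyProblem":
        """g(x) = ||x||^2 + E, minimum E at the origin.

        With xi = 0 and E > 0 the radial update reduces to a cotangent
        doubling map: the step coefficient (r^2+E)/(4 r^2) blows up whenever
        an iterate lands near the minimizer, and the excursions are unbounded
        in supremum, but between blow-ups the quadratic tails pull the
        iterate back.  For a cost whose trajectory runs away monotonically
        use :meth:`gaussian_well`.
        """
        return cls(
            g=lambda x: float(np.dot(x, x)) + offset,
            grad=lambda x: 2.0 * np.asarray(x, dtype=float),
            offset=offset, start=np.asarray(start, float), lam=lam, xi=xi,
        )

    @classmethod
    def gaussian_well(cls, offset: float = 0.0, start=(0.6, 0.4),
                      lam: float = 1.0, xi: float = 0.0) -> "ToyProblem":
        """g(x) = E + 1 - exp(-||x||^2 / 2), minimum E at the origin.

        The gradient decays exponentially away from the minimum while the
        thresholded cost does not, so with xi < E every sufficiently large
        step launches the iterate into ever flatter territory and the
        trajectory diverges — the cleanest exhibit of the blow-up that
        step clipping and xi > E both prevent.
        """
        def g(x):
            return offset + 1.0 - float(np.exp(-0.5 * np.dot(x, x)))

        def grad(x):
            x = np.asarray(x, dtype=float)
            return x * np.exp(-0.5 * np.dot(x, x))

        return cls(g=g, grad=grad, offset=offset,
                   start=np.asarray(start, float), lam=lam, xi=xi)


@dataclass
class ToyTrajectory:
    points: np.ndarray          # (n_steps+1, 2)
    values: np.ndarray          # g at each point
    diverged: bool
    stopped_in_sublevel: bool   # final g <= xi


def run_toy_subgradient(problem: ToyProblem, clip: float | None = None,
                        K: int = 100, bound: float = 1e6) -> ToyTrajectory:
    """Iterate the subgradient projection on a toy cost.

    ``clip`` optionally caps the step coefficient (g - xi)_+/||grad||^2,
    mirroring the engine's clipping.  The ``diverged`` flag is set when an
    iterate leaves the norm ``bound`` (or goes non-finite), and also when
    the gradient vanishes while the cost still exceeds xi: there the step
    coefficient is unbounded and the (unclipped) update escapes to
    infinity.  Reaching the sublevel set {g <= xi} is a regular fixed point
    and stops the loop.
    """
    x = problem.start.copy()
    points = [x.copy()]
    values = [problem.g(x)]
    diverged = False
    for _ in range(K):
        gx = problem.g(x)
        if gx <= problem.xi:
            break
        grad = problem.grad(x)
        if clip is not None:
            norm2 = float(np.dot(grad, grad))
            if norm2 == 0.0:
                break
            coeff = min((gx - problem.xi) / norm2, clip)
            x = x - problem.lam * coeff * grad
        else:
            try:
                x = subgradient_step(x, grad, gx, problem.xi, problem.lam)
            except DegenerateDirectionError:
                # step coefficient (g - xi)/||grad||^2 is +inf: blow-up
                diverged = True
                break
        if not np.all(np.isfinite(x)) or np.linalg.norm(x) > bound:
            diverged = True
            points.append(x.copy())
            values.append(problem.g(x) if np.all(np.isfinite(x)) else np.inf)
            break
        points.append(x.copy())
        values.append(problem.g(x))
    return ToyTrajectory(
        points=np.asarray(points),
        values=np.asarray(values),
        diverged=diverged,
        stopped_in_sublevel=bool(values[-1] <= problem.xi),
    )
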