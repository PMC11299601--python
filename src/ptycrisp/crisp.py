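"""CRISP: clipped reliable iterative subgradient projection.

The engine replaces ePIE's fixed step with the subgradient-projection step

    x' = x - lambda * (g(x) - xi)_+ / ||grad g(x)||^2 * grad g(x),

applied per sample to the object patch and probe.  Whenever the per-sample
cost e = ||psi' - psi||_F^2 exceeds the threshold xi the iterate keeps
moving, even where the gradient is small — which is exactly where plain
gradient descent stalls in shallow local minima.  Two auxiliary devices make
this practical:

* **step clipping** — near a stagnation point the coefficient
  (e - xi)_+ / ||conj(Q).delta||^2 blows up; it is capped at nu/|Q|^2_max.
  With nu = 1 the cap equals ePIE's coefficient, so a fully clipped CRISP
  update with lambda = alpha reproduces ePIE exactly ("ePIE-like" clipping).
  The "scale_adaptive" mode uses nu = |Q|_max instead, i.e. a cap of
  1/|Q|_max that follows the scale of the fields.
* **automatic xi tuning** — after every full sweep, xi <- c * mean(e) with
  c in (0, 1), so the threshold tracks (and stays below) the current average
  cost; no manual threshold is needed.  xi is initialized the same way from
  the initial object and probe.

A single scalar xi is shared by all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fields import DiffractionSet, ObjectField, ProbeField, ScanPlan
from .forward import (
    exit_wave,
    object_patch,
    revised_exit_wave,
    shift_probe_subpixel,
    write_patch,
)
from .pie import ReconResult, _prepare_sample

__all__ = [
    "CrispParams",
    "XiState",
    "sample_cost",
    "subgradient_step",
    "step_size_G",
    "clip_G",
    "crisp_direction",
    "update_xi",
    "initialize_xi",
    "run_crisp",
]

SCALE_ADAPTIVE = "scale_adaptive"


@dataclass
class CrispParams:
    """Hyperparameters of the CRISP engine.

    lambda_o, lambda_p : step sizes, same role as ePIE's alpha.  The
        subgradient projection admits (0, 2); values above 1 trigger a
        warning since the stability range used in practice is (0, 1].
    nu_o, nu_p : clipping parameters (> 0), or the string "scale_adaptive"
        for the cap 1/|Q|_max.
    c    : xi tuning parameter in (0, 1); xi' = c * mean(e) per iteration.
    K    : outer iterations; seed : permutation stream seed.
    fixed_xi : if not None, pin xi to this constant instead of auto-tuning
        (used to study the threshold; also exposes the raw subgradient
        projection at fixed_xi = 0).
    force_cap : always apply the clipping cap as the coefficient, bypassing
        G entirely (diagnostic switch; with nu = 1 this *is* ePIE).
    """

    lambda_o: float = 1.0
    lambda_p: float = 0.4
    nu_o: float | str = 1.0
    nu_p: float | str = 1.0
    c: float = 0.5
    K: int = 100
    seed: int = 0
    fixed_xi: float | None = None
    force_cap: bool = False

    def __post_init__(self) -> None:
        for lam in (self.lambda_o, self.lambda_p):
            if not 0 < lam < 2:
                raise ValueError("lambda must lie in (0, 2)")
            if lam > 1:
                warnings.warn("lambda > 1 is admissible but rarely stable",
                              stacklevel=3)
        for nu in (self.nu_o, self.nu_p):
            if nu != SCALE_ADAPTIVE and (not isinstance(nu, (int, float)) or nu <= 0):
                raise ValueError("nu must be positive or 'scale_adaptive'")
        if not 0 < self.c < 1:
            raise ValueError("c must lie in (0, 1)")
        if self.K < 1:
            raise ValueError("need at least one iteration")
        if self.fixed_xi is not None and self.fixed_xi < 0:
            raise ValueError("xi must be nonnegative")


@dataclass
class XiState:
    """Threshold bookkeeping: current xi, its per-iteration trace, and the
    per-sample cost vector e recorded at the latest visit."""

    xi: float
    trace: list = field(default_factory=list)
    errors: np.ndarray | None = None


def sample_cost(psi: np.ndarray, psi_prime: np.ndarray) -> float:
    """Per-sample cost e = ||psi' - psi||_F^2."""
    if psi.shape != psi_prime.shape:
        raise ValueError("shape mismatch between psi and psi'")
    return float(np.sum(np.abs(psi_prime - psi) ** 2))


def subgradient_step(x, grad, g_value: float, xi: float, lam: float):
    """One subgradient-projection update of a generic differentiable cost.

    Returns x unchanged when g(x) <= xi (the positive part clips to zero).
    A zero gradient with g(x) > xi has no defined direction and raises.
    """
    if not 0 < lam < 2:
        raise ValueError("lambda must lie in (0, 2)")
    thresholded = max(g_value - xi, 0.0)
    if thresholded == 0.0:
        return np.array(x, copy=True)
    grad = np.asarray(grad)
    norm2 = float(np.sum(np.abs(grad) ** 2))
    if norm2 == 0.0:
        raise DegenerateDirectionError("zero gradient with cost above threshold")
    return x - lam * thresholded / norm2 * grad


class DegenerateDirectionError(ValueError):
    """No update direction exists: vanishing denominator with positive cost."""


def step_size_G(Q: np.ndarray, delta: np.ndarray, e: float, xi: float) -> float:
    """Subgradient-projection step-size function.

        G = (e - xi)_+ / ||conj(Q) . delta||_F^2

    ``Q`` is the co-factor field of the update (probe for the object update,
    object patch for the probe update) and ``delta = psi' - psi``.
    """
    thresholded = max(e - xi, 0.0)
    if thresholded == 0.0:
        return 0.0
    denom = float(np.sum((np.abs(Q) * np.abs(delta)) ** 2))
    if denom == 0.0:
        raise DegenerateDirectionError("zero direction norm with cost above threshold")
    return thresholded / denom


def clip_G(G: float, Q: np.ndarray, nu) -> float:
    """Clip the step size at nu/|Q|^2_max.

    With nu = 1 the cap equals ePIE's coefficient 1/|Q|^2_max; with
    nu = "scale_adaptive" the cap is 1/|Q|_max.
    """
    qmax = float(np.max(np.abs(Q)))
    if qmax == 0.0:
        raise DegenerateDirectionError("cannot clip against an all-zero field")
    nu_val = qmax if nu == SCALE_ADAPTIVE else float(nu)
    return min(G, nu_val / qmax**2)


def crisp_direction(O_n, P_n, psi_prime, xi, nu_o, nu_p, force_cap=False):
    """Update directions for one sample.

    Returns ``(D_o, D_p, e)`` with ``O_n' = O_n + lambda_o * D_o`` and
    ``P_n' = P_n + lambda_p * D_p``; both directions read the pre-update
    fields.  A direction whose denominator vanishes while the cost exceeds
    xi is returned as None (the caller skips and logs that visit).
    """
    psi = exit_wave(O_n, P_n)
    delta = psi_prime - psi
    e = sample_cost(psi, psi_prime)

    def direction(Q, nu):
        if force_cap:
            coeff = clip_G(np.inf, Q, nu)
        else:
            try:
                coeff = clip_G(step_size_G(Q, delta, e, xi), Q, nu)
            except DegenerateDirectionError:
                return None
        return coeff * np.conj(Q) * delta

    return direction(P_n, nu_o), direction(O_n, nu_p), e


def update_xi(e: np.ndarray, c: float) -> float:
    """Auto-tuned threshold for the next iteration: xi' = c * mean(e)."""
    e = np.asarray(e, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    if np.any(e < 0):
        raise ValueError("per-sample costs must be nonnegative")
    if not 0 < c < 1:
        raise ValueError("c must lie in (0, 1)")
    return float(c * e.mean())


def initialize_xi(dataset: DiffractionSet, scan: ScanPlan, obj0: ObjectField,
                  probe0: ProbeField, c: float) -> float:
    """Initial threshold from the starting fields.

    Computes the per-sample cost e_n of every pattern with the initial
    object and probe (no fields are modified) and returns c * mean(e).
    """
    window = dataset.pattern_shape
    O, P = obj0.values, probe0.values
    errors = np.empty(len(dataset))
    for n in range(len(dataset)):
        _, _, O_n, P_n = _prepare_sample(O, P, scan.positions[n], window)
        psi = exit_wave(O_n, P_n)
        psi_prime = revised_exit_wave(psi, dataset.intensities[n])
        errors[n] = sample_cost(psi, psi_prime)
    return update_xi(errors, c)


def run_crisp(dataset: DiffractionSet, scan: ScanPlan, obj0: ObjectField,
              probe0: ProbeField, params: CrispParams) -> tuple[ReconResult, XiState]:
    """Run the full CRISP reconstruction.

    xi starts from :func:`initialize_xi` (or ``params.fixed_xi``); each outer
    iteration visits the samples in a fresh random order, updates object
    patch and probe along :func:`crisp_direction`, stores the pre-update cost
    e_n, and finally re-tunes xi from the stored costs.  The trace records
    R_F, mean cost and xi per iteration.
    """
    from .metrics import r_factor

    N = len(dataset)
    if len(scan) != N:
        raise ValueError("scan plan and dataset disagree on N")
    window = dataset.pattern_shape
    scan.validate_geometry(obj0.shape, window)

    O = obj0.values.copy()
    P = probe0.values.copy()
    rng = np.random.default_rng(params.seed)

    if params.fixed_xi is not None:
        xi = float(params.fixed_xi)
    else:
        xi = initialize_xi(dataset, scan, obj0, probe0, params.c)
    state = XiState(xi=xi)

    rf_trace = np.empty(params.K)
    cost_trace = np.empty(params.K)
    xi_trace = np.empty(params.K)
    skipped = 0
    for k in range(params.K):
        order = rng.permutation(N)
        errors = np.empty(N)
        for n in order:
            s_int, s_sub, O_n, P_n = _prepare_sample(O, P, scan.positions[n], window)
            psi = exit_wave(O_n, P_n)
            psi_prime = revised_exit_wave(psi, dataset.intensities[n])
            D_o, D_p, e = crisp_direction(O_n, P_n, psi_prime, state.xi,
                                          params.nu_o, params.nu_p,
                                          force_cap=params.force_cap)
            errors[n] = e
            if D_o is None or D_p is None:
                skipped += 1
            if D_o is not None:
                write_patch(O, s_int, O_n + params.lambda_o * D_o)
            if D_p is not None:
                P = shift_probe_subpixel(P_n + params.lambda_p * D_p, -s_sub)
        state.errors = errors
        if params.fixed_xi is None:
            state.xi = update_xi(errors, params.c)
        xi_trace[k] = state.xi
        state.trace.append(state.xi)
        cost_trace[k] = errors.mean()
        rf_trace[k] = r_factor(dataset, O, P, scan)

    result = ReconResult(
        object=ObjectField(O, obj0.pixel_pitch),
        probe=ProbeField(P, probe0.pixel_pitch),
        r_factor_trace=rf_trace,
        cost_trace=cost_trace,
        xi_trace=xi_trace,
        algorithm="crisp",
        iterations=params.K,
        seed=params.seed,
        skipped_samples=skipped,
    )
    return result, state
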