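"""Sequential ptychographic iterative engines (ePIE and rPIE).

Both engines sweep the diffraction patterns in a freshly permuted order each
iteration and update object patch and probe from the residual between the
exit wave psi and its magnitude-projected revision psi'.

ePIE is gradient descent on the per-sample cost g(O_n) = ||psi' - P_n.O_n||_F^2
with step eta = alpha / |P_n|^2_max (the reciprocal Lipschitz constant of the
gradient, scaled by alpha in (0, 1], which guarantees descent); the probe
update is the mirror image with |O_n|^2_max.  rPIE replaces the uniform
denominator with the element-wise blend (1-gamma)|P_n|^2 + gamma|P_n|^2_max,
recovering ePIE with alpha = 1 at gamma = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DiffractionSet, ObjectField, ProbeField, ScanPlan
from .forward import (
    exit_wave,
    object_patch,
    revised_exit_wave,
    shift_probe_subpixel,
    write_patch,
)

__all__ = [
    "DegenerateSampleError",
    "PieParams",
    "ReconResult",
    "epie_step",
    "rpie_step",
    "gradient_step_object",
    "gradient_step_probe",
    "run_pie",
]


class DegenerateSampleError(ValueError):
    """Raised when an update direction is undefined (vanishing denominator)."""


@dataclass
class PieParams:
    """Hyperparameters of the PIE engines.

    alpha_o, alpha_p : object/probe step sizes, stable in (0, 1]
    gamma_o, gamma_p : rPIE balancing parameters (> 0); gamma = 1 gives the
        ePIE denominator
    K    : number of outer iterations (full sweeps)
    seed : seed of the per-iteration permutation stream (independent of any
        noise stream used to simulate the data)
    """

    alpha_o: float = 1.0
    alpha_p: float = 0.4
    gamma_o: float = 0.1
    gamma_p: float = 1.0
    K: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_o, self.alpha_p):
            if not 0 < a <= 1:
                raise ValueError("alpha must lie in (0, 1]")
        for g in (self.gamma_o, self.gamma_p):
            if g <= 0:
                raise ValueError("gamma must be positive")
        if self.K < 1:
            raise ValueError("need at least one iteration")


@dataclass
class ReconResult:
    """Output of a reconstruction run: final fields plus per-iteration traces."""

    object: ObjectField
    probe: ProbeField
    r_factor_trace: np.ndarray      # length K
    cost_trace: np.ndarray          # length K, mean per-sample ||psi'-psi||^2
    xi_trace: np.ndarray | None = None  # length K, CRISP only
    algorithm: str = ""
    iterations: int = 0
    seed: int = 0
    skipped_samples: int = 0        # visits skipped for lack of a direction


def epie_step(O_n, P_n, psi, psi_prime, alpha_o, alpha_p):
    """One ePIE update of an object patch and the (shifted) probe.

    Both updates read the pre-update fields, so the probe increment uses the
    object patch as it was before the object update.
    """
    pmax2 = np.max(np.abs(P_n)) ** 2
    omax2 = np.max(np.abs(O_n)) ** 2
    if pmax2 == 0 or omax2 == 0:
        raise DegenerateSampleError("object or probe patch is identically zero")
    delta = psi_prime - psi
    O_new = O_n + alpha_o * np.conj(P_n) / pmax2 * delta
    P_new = P_n + alpha_p * np.conj(O_n) / omax2 * delta
    return O_new, P_new


def rpie_step(O_n, P_n, psi, psi_prime, gamma_o, gamma_p):
    """One rPIE update; the denominator blend is computed element-wise."""
    absP2 = np.abs(P_n) ** 2
    absO2 = np.abs(O_n) ** 2
    pmax2 = absP2.max()
    omax2 = absO2.max()
    denom_o = (1 - gamma_o) * absP2 + gamma_o * pmax2
    denom_p = (1 - gamma_p) * absO2 + gamma_p * omax2
    if np.any(denom_o == 0) or np.any(denom_p == 0):
        raise DegenerateSampleError("vanishing rPIE denominator")
    delta = psi_prime - psi
    O_new = O_n + np.conj(P_n) * delta / denom_o
    P_new = P_n + np.conj(O_n) * delta / denom_p
    return O_new, P_new


def gradient_step_object(O_n, P_n, psi_prime, eta):
    """Generic gradient step on g(O) = ||psi' - P.O||_F^2 with step size eta.

    With eta = alpha/|P_n|^2_max this coincides with the ePIE object update;
    kept separate as the reference form for descent checks.
    """
    grad = np.conj(P_n) * (P_n * O_n - psi_prime)
    return O_n - eta * grad


def gradient_step_probe(O_n, P_n, psi_prime, eta):
    """Mirror-image gradient step on the probe subproblem."""
    grad = np.conj(O_n) * (P_n * O_n - psi_prime)
    return P_n - eta * grad


def _prepare_sample(O, P, r, window):
    """Shift probe / window object for one scan position."""
    from .forward import split_shift

    s_int, s_sub = split_shift(r)
    P_n = shift_probe_subpixel(P, s_sub)
    O_n = object_patch(O, s_int, window)
    return s_int, s_sub, O_n, P_n


def run_pie(dataset: DiffractionSet, scan: ScanPlan, obj0: ObjectField,
            probe0: ProbeField, params: PieParams,
            variant: str = "epie") -> ReconResult:
    """Run a sequential PIE reconstruction.

    Each outer iteration draws a fresh random permutation of the sample
    indices, then visits every sample: form the shifted probe and object
    patch, compute the exit wave and its magnitude projection, apply the
    variant's update, write the patch back and un-shift the probe.  The
    per-iteration trace records the pooled R_F factor (recomputed from the
    updated fields) and the mean pre-update sample cost.
    """
    if variant not in ("epie", "rpie"):
        raise ValueError(f"unknown PIE variant {variant!r}")
    from .metrics import r_factor

    N = len(dataset)
    if len(scan) != N:
        raise ValueError("scan plan and dataset disagree on N")
    window = dataset.pattern_shape
    scan.validate_geometry(obj0.shape, window)

    O = obj0.values.copy()
    P = probe0.values.copy()
    rng = np.random.default_rng(params.seed)

    rf_trace = np.empty(params.K)
    cost_trace = np.empty(params.K)
    for k in range(params.K):
        order = rng.permutation(N)
        costs = np.empty(N)
        for n in order:
            s_int, s_sub, O_n, P_n = _prepare_sample(O, P, scan.positions[n], window)
            psi = exit_wave(O_n, P_n)
            psi_prime = revised_exit_wave(psi, dataset.intensities[n])
            costs[n] = np.sum(np.abs(psi_prime - psi) ** 2)
            if variant == "epie":
                O_n, P_n = epie_step(O_n, P_n, psi, psi_prime,
                                     params.alpha_o, params.alpha_p)
            else:
                O_n, P_n = rpie_step(O_n, P_n, psi, psi_prime,
                                     params.gamma_o, params.gamma_p)
            write_patch(O, s_int, O_n)
            P = shift_probe_subpixel(P_n, -s_sub)
        cost_trace[k] = costs.mean()
        rf_trace[k] = r_factor(dataset, O, P, scan)

    return ReconResult(
        object=ObjectField(O, obj0.pixel_pitch),
        probe=ProbeField(P, probe0.pixel_pitch),
        r_factor_trace=rf_trace,
        cost_trace=cost_trace,
        algorithm=variant,
        iterations=params.K,
        seed=params.seed,
    )
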