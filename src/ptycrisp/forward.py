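"""Ptychographic observation model.

The measured diffraction pattern at scan position n is

    I_n = |F[P_n . O_n]|^2 + noise,

where ``O_n`` is the object patch under the probe window, ``P_n`` the probe
shifted to the scan position, ``.`` element-wise multiplication and ``F`` the
2-D discrete Fourier transform (far-field propagation).  The transform is
unitary (``norm="ortho"``) so Parseval holds: real-space and reciprocal-space
squared errors coincide, which fixes the Lipschitz constants used by the
reconstruction engines.

Position shifts are decomposed into an integer part, applied by windowing the
object canvas, and a subpixel part, applied to the probe by a linear phase
ramp in the frequency domain (band-limited interpolation).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "split_shift",
    "shift_probe_subpixel",
    "object_patch",
    "write_patch",
    "exit_wave",
    "propagate",
    "back_propagate",
    "clean_intensity",
    "apply_poisson_noise",
    "revised_exit_wave",
]


def split_shift(r) -> tuple[np.ndarray, np.ndarray]:
    """Split a real 2-vector shift into integer and subpixel parts.

    Rounds to the nearest integer with the fraction constrained to
    ``[-0.5, 0.5)`` (ties round up: ``0.5 -> 1``, fraction ``-0.5``), so that
    ``s_int + s_sub == r`` to machine precision.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("shift vector must be finite")
    s_int = np.floor(r + 0.5).astype(np.int64)
    s_sub = r - s_int
    return s_int, s_sub


def shift_probe_subpixel(P: np.ndarray, s_sub) -> np.ndarray:
    """Translate a probe field by a subpixel amount via a Fourier phase ramp.

    The ramp has unit modulus, so total field energy is preserved exactly.
    Shifts larger than half a pixel must be routed through
    :func:`split_shift` first.
    """
    P = np.asarray(P, dtype=np.complex128)
    s = np.asarray(s_sub, dtype=float)
    if np.any(np.abs(s) > 0.5 + 1e-12):
        raise ValueError("subpixel shift components must satisfy |s| <= 0.5")
    if not np.any(s):
        return P.copy()
    fy = np.fft.fftfreq(P.shape[0])[:, None]
    fx = np.fft.fftfreq(P.shape[1])[None, :]
    ramp = np.exp(-2j * np.pi * (fy * s[0] + fx * s[1]))
    return np.fft.ifft2(np.fft.fft2(P) * ramp)


def object_patch(O: np.ndarray, s_int, window: tuple[int, int]) -> np.ndarray:
    """Extract the probe-window patch of the object at integer offset s_int."""
    s = np.asarray(s_int, dtype=np.int64)
    h, w = window
    y, x = int(s[0]), int(s[1])
    if y < 0 or x < 0 or y + h > O.shape[0] or x + w > O.shape[1]:
        raise IndexError(
            f"window {window} at {(y, x)} falls outside canvas {O.shape}"
        )
    return O[y:y + h, x:x + w].copy()


def write_patch(O: np.ndarray, s_int, patch: np.ndarray) -> None:
    """Adjoint of :func:`object_patch`: write the patch back in place."""
    s = np.asarray(s_int, dtype=np.int64)
    h, w = patch.shape
    y, x = int(s[0]), int(s[1])
    if y < 0 or x < 0 or y + h > O.shape[0] or x + w > O.shape[1]:
        raise IndexError(
            f"patch {patch.shape} at {(y, x)} falls outside canvas {O.shape}"
        )
    O[y:y + h, x:x + w] = patch


def exit_wave(O_n: np.ndarray, P_n: np.ndarray) -> np.ndarray:
    """Exit wavefield psi = P_n . O_n (element-wise product)."""
    if O_n.shape != P_n.shape:
        raise ValueError(f"shape mismatch: object patch {O_n.shape}, probe {P_n.shape}")
    return P_n * O_n


def propagate(psi: np.ndarray) -> np.ndarray:
    """Unitary 2-D DFT: far-field (Fraunhofer) propagation to the detector."""
    return np.fft.fft2(psi, norm="ortho")


def back_propagate(F: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`propagate`."""
    return np.fft.ifft2(F, norm="ortho")


def clean_intensity(psi: np.ndarray) -> np.ndarray:
    """Noise-free intensity |F[psi]|^2. Under unitary scaling sum(I) = ||psi||_F^2."""
    return np.abs(propagate(psi)) ** 2


def apply_poisson_noise(I_clean: np.ndarray, seed) -> np.ndarray:
    """Draw each pixel independently from Poisson(mean = clean intensity).

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Drawn once
    at simulation time; reconstructions never re-draw noise.
    """
    I_clean = np.asarray(I_clean, dtype=float)
    if np.any(I_clean < 0):
        raise ValueError("clean intensity must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.poisson(I_clean).astype(float)


def revised_exit_wave(psi: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Magnitude projection onto the measured diffraction pattern.

    Replaces the propagated modulus with sqrt(I) while keeping the phase:

        psi' = F^-1[ sqrt(I) . sign(F[psi]) ],   sign(z) = z/|z|.

    Where the propagated field vanishes the phase is undefined; the
    convention ``sign(0) := 1`` keeps the measured modulus with zero phase.
    By construction ``|F[psi']|^2 == I`` (to rounding).
    """
    if psi.shape != I.shape:
        raise ValueError(f"shape mismatch: psi {psi.shape}, I {I.shape}")
    if np.any(I < 0):
        raise ValueError("measured intensity must be nonnegative")
    F = propagate(psi)
    mod = np.abs(F)
    phase = np.where(mod > 0, F / np.where(mod > 0, mod, 1.0), 1.0 + 0.0j)
    return back_propagate(np.sqrt(I) * phase)
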