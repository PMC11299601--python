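"""Quantitative evaluation of ptychographic reconstructions.

* ``r_factor`` — pooled normalized discrepancy between measured and modeled
  diffraction moduli; the standard convergence monitor.
* ``frc`` — Fourier ring correlation against a reference object, a
  ring-resolved accuracy measure (1 = perfect agreement at that frequency).
* ``tau_score`` — normalized squared difference between two reconstructions
  after ambiguity removal; used to quantify run-to-run dispersion.
* ``probe_correlation`` — normalized reciprocal-space correlation of two
  probes inside an aperture mask.

A ptychographic solution is only defined up to a global phase and a joint
object/probe translation, so image comparisons go through ``align_global``
first; without it FRC and tau are meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .fields import DiffractionSet, ObjectField, ProbeField, ScanPlan
from .forward import exit_wave, object_patch, propagate, split_shift

__all__ = [
    "FrcCurve",
    "AlignmentTransform",
    "r_factor",
    "align_global",
    "frc",
    "tau_score",
    "probe_correlation",
    "scan_coverage_box",
]


@dataclass
class FrcCurve:
    """FRC values per integer-radius ring of the 2-D frequency plane."""

    rings: np.ndarray        # integer ring indices
    frequencies: np.ndarray  # ring center in cycles/pixel
    values: np.ndarray       # |FRC| per ring, bounded by 1
    counts: np.ndarray       # pixels per ring

    def min_below(self, frequency: float) -> float:
        """Smallest FRC value over rings strictly below the given frequency."""
        sel = self.frequencies < frequency
        if not np.any(sel):
            raise ValueError("no rings below the requested frequency")
        return float(self.values[sel].min())


@dataclass
class AlignmentTransform:
    """Global ambiguity removal: unit-modulus phase and a translation."""

    phase: complex
    shift: np.ndarray  # (dy, dx), applied circularly via a Fourier ramp

    def apply(self, a: np.ndarray) -> np.ndarray:
        return _fourier_shift(a, self.shift) * self.phase


def _values(x):
    return x.values if hasattr(x, "values") else np.asarray(x)


def _fourier_shift(a: np.ndarray, shift) -> np.ndarray:
    """Circular translation (possibly subpixel) via a frequency-domain ramp."""
    shift = np.asarray(shift, dtype=float)
    if not np.any(shift):
        return np.asarray(a, dtype=np.complex128).copy()
    fy = np.fft.fftfreq(a.shape[0])[:, None]
    fx = np.fft.fftfreq(a.shape[1])[None, :]
    ramp = np.exp(-2j * np.pi * (fy * shift[0] + fx * shift[1]))
    return np.fft.ifft2(np.fft.fft2(a) * ramp)


def r_factor(dataset: DiffractionSet, O, P, scan: ScanPlan) -> float:
    """Pooled R_F factor.

        R_F = sum_n sum_q | sqrt(I_n[q]) - |F[psi_n][q]| |
              ---------------------------------------------
                     sum_n sum_q sqrt(I_n[q])

    with psi_n formed from the supplied object, probe and scan.  Zero means
    the model reproduces every diffraction modulus exactly.
    """
    from .forward import shift_probe_subpixel

    O = _values(O)
    P = _values(P)
    window = dataset.pattern_shape
    num = 0.0
    den = 0.0
    for n in range(len(dataset)):
        s_int, s_sub = split_shift(scan.positions[n])
        P_n = shift_probe_subpixel(P, s_sub)
        O_n = object_patch(O, s_int, window)
        model = np.abs(propagate(exit_wave(O_n, P_n)))
        meas = np.sqrt(dataset.intensities[n])
        num += np.sum(np.abs(meas - model))
        den += np.sum(meas)
    if den == 0.0:
        raise ValueError("all-zero dataset: R_F undefined")
    return float(num / den)


def align_global(O_est, O_ref, upsample: int = 50):
    """Remove global phase and translation from O_est relative to O_ref.

    Translation from the cross-correlation peak (subpixel-refined by
    upsampled DFT), then the phase of the inner product <O_shifted, O_ref>.
    Returns the aligned image and the transform that produced it.
    """
    a = _values(O_est).astype(np.complex128)
    b = _values(O_ref).astype(np.complex128)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if not np.any(b):
        raise ValueError("zero reference image")
    shift, _, _ = phase_cross_correlation(
        b, a, upsample_factor=upsample, normalization=None)
    shifted = _fourier_shift(a, shift)
    inner = np.vdot(shifted, b)  # sum conj(shifted) * ref
    phase = inner / abs(inner) if abs(inner) > 0 else 1.0 + 0.0j
    transform = AlignmentTransform(phase=complex(phase), shift=np.asarray(shift, float))
    return shifted * phase, transform


def frc(O_est, O_ref, ring_width: int = 1) -> FrcCurve:
    """Fourier ring correlation between an aligned estimate and a reference.

        FRC(S) = | sum_{q in ring S} F_est[q] conj(F_ref[q]) |
                 / sqrt( sum |F_est|^2 * sum |F_ref|^2 )

    Rings are integer-radius annuli (``ring_width`` frequency pixels wide) up
    to the Nyquist radius; empty rings are skipped.  Alignment must already
    have been applied.
    """
    a = _values(O_est)
    b = _values(O_ref)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    Fa = np.fft.fft2(a)
    Fb = np.fft.fft2(b)
    H, W = a.shape
    iy = np.fft.fftfreq(H) * H
    ix = np.fft.fftfreq(W) * W
    radius = np.hypot(iy[:, None], ix[None, :])
    ring = np.round(radius / ring_width).astype(int)
    n_rings = min(H, W) // 2 // ring_width + 1

    rings, freqs, vals, counts = [], [], [], []
    for s in range(n_rings):
        mask = ring == s
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        num = np.abs(np.sum(Fa[mask] * np.conj(Fb[mask])))
        den = np.sqrt(np.sum(np.abs(Fa[mask]) ** 2) * np.sum(np.abs(Fb[mask]) ** 2))
        if den == 0.0:
            continue
        rings.append(s)
        freqs.append(s * ring_width / min(H, W))
        vals.append(num / den)
        counts.append(cnt)
    return FrcCurve(np.asarray(rings), np.asarray(freqs),
                    np.asarray(vals), np.asarray(counts))


def tau_score(O_i, O_j) -> float:
    """Pairwise dissimilarity of two reconstructions.

        tau_ij = || align(O_i -> O_j) - O_j ||_F^2 / ( ||O_i||_F ||O_j||_F )

    Zero for images equal up to the global ambiguities; lower means the two
    runs agree better.  Symmetric to alignment tolerance.
    """
    a = _values(O_i)
    b = _values(O_j)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm input image")
    aligned, _ = align_global(a, b)
    return float(np.sum(np.abs(aligned - b) ** 2) / (na * nb))


def probe_correlation(P_est, P_ref, aperture_mask=None) -> float:
    """Reciprocal-space correlation of two probes inside an aperture mask.

    Modulus of the normalized complex inner product of the propagated probes
    restricted to mask pixels; 1 for identical probes (up to scale/phase).
    If no mask is given, the support of the reference probe's spectrum
    (above 1e-3 of its peak modulus) is used.
    """
    Fe = propagate(_values(P_est))
    Fr = propagate(_values(P_ref))
    if aperture_mask is None:
        aperture_mask = np.abs(Fr) > 1e-3 * np.abs(Fr).max()
    aperture_mask = np.asarray(aperture_mask, dtype=bool)
    if aperture_mask.shape != Fe.shape:
        raise ValueError("mask shape must match the probe window")
    if not np.any(aperture_mask):
        raise ValueError("empty aperture mask")
    fe = Fe[aperture_mask]
    fr = Fr[aperture_mask]
    den = np.linalg.norm(fe) * np.linalg.norm(fr)
    if den == 0.0:
        raise ValueError("zero probe field on the mask")
    return float(np.abs(np.vdot(fe, fr)) / den)


def scan_coverage_box(scan: ScanPlan, probe, canvas_shape,
                      threshold: float = 0.1) -> tuple[slice, slice]:
    """Bounding box of the well-illuminated part of the object canvas.

    Accumulates sum_n |P_n|^2 over the scan and returns the bounding box of
    pixels whose accumulated illumination exceeds ``threshold`` times its
    maximum.  Pixels outside carry little or no constraint from the data and
    are excluded before FRC/tau comparisons.
    """
    from .forward import shift_probe_subpixel

    P = _values(probe)
    cover = np.zeros(canvas_shape, dtype=float)
    ints, subs = scan.split()
    h, w = P.shape
    for s_int, s_sub in zip(ints, subs):
        P_n = shift_probe_subpixel(P, s_sub)
        cover[s_int[0]:s_int[0] + h, s_int[1]:s_int[1] + w] += np.abs(P_n) ** 2
    mask = cover > threshold * cover.max()
    ys, xs = np.nonzero(mask)
    return slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1)
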