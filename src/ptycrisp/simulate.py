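"""Synthetic ptychography: phantoms, probes, scans and dose-scaled datasets.

The generator emulates a hard-X-ray ptychographic measurement at desk scale:
a complex transmission phantom (randomly placed absorbing/phase-shifting
particles in a uniform film, or a Siemens-star resolution chart), a
localized soft-edged probe of aperture origin with optional defocus
curvature, an overlapping jittered raster scan, far-field diffraction, and
Poisson noise whose level is set by the diffraction intensity at the origin
(I0): 1e10 for the high-dose condition, 1e8 for the low-dose condition.

All randomness is drawn from independent, separately seeded streams
(phantom, scan jitter, noise), so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DiffractionSet, ObjectField, ProbeField, ScanPlan
from .forward import (
    apply_poisson_noise,
    clean_intensity,
    exit_wave,
    object_patch,
    shift_probe_subpixel,
    split_shift,
)

__all__ = [
    "PhantomSpec",
    "SimSpec",
    "SimulatedDataset",
    "make_particle_phantom",
    "make_siemens_star",
    "make_probe",
    "make_scan",
    "simulate_dataset",
    "simulate",
    "default_initializers",
    "demagnified_beam_diameter",
    "fzp_focal_length",
    "BEAMLINE_OPTICS",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# Beam geometry of the emulated measurement station (metadata, not simulated
# wave-optically).  A beam-defining aperture (BDA) is imaged onto the
# specimen through a Fresnel zone plate (FZP) at a fixed demagnification.
BEAMLINE_OPTICS = {
    "photon_energy_keV": 8.0,
    "bda_diameter_um": 20.0,
    "fzp_outermost_zone_nm": 86.0,
    "fzp_diameter_um": 416.0,
    "demagnification": 5.0,
    "detector_distance_m": 4.5,
}


def demagnified_beam_diameter(aperture_diameter: float,
                              demagnification: float) -> float:
    """Diameter of the demagnified aperture image on the specimen.

    Thin-lens imaging scales the aperture by 1/M; with the default optics
    (20 um BDA, M = 5) the illumination spot is 4 um across.
    """
    if aperture_diameter <= 0 or demagnification <= 0:
        raise ValueError("aperture diameter and demagnification must be positive")
    return aperture_diameter / demagnification


def fzp_focal_length(diameter: float, outermost_zone_width: float,
                     wavelength: float) -> float:
    """First-order focal length of a Fresnel zone plate: f = D * dr / lambda."""
    if min(diameter, outermost_zone_width, wavelength) <= 0:
        raise ValueError("all FZP parameters must be positive")
    return diameter * outermost_zone_width / wavelength


# ---------------------------------------------------------------------------
# Phantoms


@dataclass
class PhantomSpec:
    """Statistical description of a particle-filled transmission film.

    Defaults emulate a weakly absorbing, weakly phase-shifting specimen, as
    appropriate for thin films in the hard-X-ray regime (transmission
    amplitudes 0.75-0.95, phase shifts 0.1-0.5 rad) on a clear substrate.
    ``margin`` keeps particle centers inside the central region of the
    canvas — the scanned field of view; the film outside the field of view
    is clear, as in a measurement aimed at the structures of interest.
    """

    shape: tuple[int, int] = (64, 64)
    n_particles: int = 12
    radius_range: tuple[float, float] = (1.5, 3.0)
    amplitude_range: tuple[float, float] = (0.75, 0.95)
    phase_range: tuple[float, float] = (0.1, 0.5)  # radians
    background: float = 1.0
    margin: float | None = None  # default: 0.4 * min(shape)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("particle amplitudes must lie in (0, 1]")
        if not 0 < self.background <= 1:
            raise ValueError("background transmission must lie in (0, 1]")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("invalid radius range")
        if self.n_particles < 0:
            raise ValueError("particle count must be nonnegative")
        if self.margin is None:
            self.margin = 0.4 * min(self.shape)
        if 2 * self.margin >= min(self.shape):
            raise ValueError("margin leaves no room for particle centers")


def make_particle_phantom(spec: PhantomSpec) -> ObjectField:
    """Particle-filled film phantom: seeded random disks on a uniform background.

    Disks may overlap (later disks overwrite); inside each disk the
    transmission amplitude and phase shift are drawn uniformly from the
    spec's ranges, so |O| <= 1 everywhere (passive object).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    O = np.full((H, W), spec.background, dtype=np.complex128)
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(spec.n_particles):
        cy = rng.uniform(spec.margin, H - spec.margin)
        cx = rng.uniform(spec.margin, W - spec.margin)
        r = rng.uniform(*spec.radius_range)
        amp = rng.uniform(*spec.amplitude_range)
        ph = rng.uniform(*spec.phase_range)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        O[disk] = amp * np.exp(1j * ph)
    return ObjectField(O)


def make_siemens_star(shape: tuple[int, int], spokes: int,
                      low_transmission: float = 0.3,
                      hub_radius: float = 2.0) -> ObjectField:
    """Siemens-star resolution chart phantom.

    ``spokes`` counts the total number of angular sectors (alternating dark
    and clear with even duty cycle), so the pattern repeats after rotation
    by two sector widths.  Spoke width shrinks linearly toward the center; a
    small clear hub avoids the singular apex.  Binary amplitude, zero phase.
    """
    if spokes < 2 or spokes % 2:
        raise ValueError("need an even spoke count >= 2")
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2, (W - 1) / 2
    theta = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
    sector = np.floor(theta / (2 * np.pi / spokes)).astype(int)
    amp = np.where(sector % 2 == 0, 1.0, low_transmission)
    r = np.hypot(yy - cy, xx - cx)
    amp[r < hub_radius] = 1.0
    return ObjectField(amp.astype(np.complex128))


# ---------------------------------------------------------------------------
# Probe and scan


def make_probe(window: tuple[int, int], diameter: float,
               softness: float = 1.5, defocus: float = 0.0) -> ProbeField:
    """Soft-edged disk probe with optional defocus phase.

    ``diameter`` is the nominal illumination diameter in pixels, ``softness``
    the 10-90% edge width in pixels (0 gives a hard disk), ``defocus`` the
    quadratic phase in radians at the nominal radius.  Normalized to unit
    total energy; dose scaling happens at simulation time.
    """
    if diameter <= 0:
        raise ValueError("probe diameter must be positive")
    H, W = window
    if diameter >= min(H, W):
        raise ValueError("probe diameter must fit inside the window")
    yy, xx = np.mgrid[0:H, 0:W]
    r = np.hypot(yy - (H - 1) / 2, xx - (W - 1) / 2)
    R = diameter / 2
    if softness <= 0:
        amp = (r <= R).astype(float)
    else:
        # logistic edge; scale so `softness` is roughly the 10-90% width
        amp = 1.0 / (1.0 + np.exp((r - R) / (softness / 4.4)))
    phase = defocus * (r / R) ** 2
    P = amp * np.exp(1j * phase)
    P /= np.sqrt(np.sum(np.abs(P) ** 2))
    return ProbeField(P)


@dataclass
class SimSpec:
    """Full description of one synthetic measurement.

    The scan step must be smaller than the probe diameter so neighbouring
    illuminations overlap — the redundancy that makes the inverse problem
    well posed.  ``dose_I0`` is the largest zero-frequency (DC bin of the
    unshifted transform) diffraction intensity over the scan after scaling.
    """

    canvas: tuple[int, int] = (64, 64)
    window: tuple[int, int] = (16, 16)
    probe_diameter: float = 10.0
    probe_softness: float = 1.5
    probe_defocus: float = 0.0
    grid: tuple[int, int] = (5, 5)
    step: float = 3.0
    jitter: float = 0.2
    dose_I0: float = 1e10
    noise: str = "poisson"  # "poisson" | "clean"
    phantom: PhantomSpec | None = None
    scan_seed: int = 1
    noise_seed: int = 2

    def __post_init__(self) -> None:
        if self.step >= self.probe_diameter:
            raise ValueError("scan step must be below the probe diameter (overlap)")
        if self.dose_I0 <= 0:
            raise ValueError("dose must be positive")
        if self.phantom is None:
            self.phantom = PhantomSpec(shape=self.canvas)


def make_scan(spec: SimSpec) -> ScanPlan:
    """Jittered raster scan covering the center of the canvas.

    rows x cols positions at the given step, plus independent uniform jitter
    in [-j, j]^2 per position (jitter breaks the raster-grid degeneracy of a
    perfectly periodic scan).  Raises if any probe window would leave the
    canvas.
    """
    rows, cols = spec.grid
    H, W = spec.canvas
    h, w = spec.window
    rng = np.random.default_rng(spec.scan_seed)
    extent_y = (rows - 1) * spec.step + h
    extent_x = (cols - 1) * spec.step + w
    y0 = (H - extent_y) / 2
    x0 = (W - extent_x) / 2
    if y0 < spec.jitter + 0.5 or x0 < spec.jitter + 0.5:
        raise ValueError("scan grid (plus jitter margin) does not fit the canvas")
    base = np.array([[y0 + i * spec.step, x0 + j * spec.step]
                     for i in range(rows) for j in range(cols)])
    jit = rng.uniform(-spec.jitter, spec.jitter, size=base.shape)
    plan = ScanPlan(base + jit)
    plan.validate_geometry(spec.canvas, spec.window)
    return plan


# ---------------------------------------------------------------------------
# Dataset simulation


@dataclass
class SimulatedDataset:
    """A diffraction dataset bundled with its generating ground truth."""

    dataset: DiffractionSet
    scan: ScanPlan
    truth_object: ObjectField
    truth_probe: ProbeField  # includes the dose scale (sqrt applied)
    dose_scale: float
    spec: SimSpec | None = None


def simulate_dataset(phantom: ObjectField, probe: ProbeField, scan: ScanPlan,
                     I0: float, noise_seed=0,
                     noise: str = "poisson") -> SimulatedDataset:
    """Forward-simulate diffraction patterns at a target dose.

    Clean intensities are computed per position, then one global scale is
    applied so that the maximum zero-frequency intensity over the scan
    equals ``I0`` (a single incident flux for the whole measurement); the
    stored truth probe absorbs the square root of that scale, so truth
    exactly reproduces the scaled clean data.  Poisson noise, if enabled, is
    drawn once per pixel from the scaled means.
    """
    window = probe.shape
    scan.validate_geometry(phantom.shape, window)
    N = len(scan)
    clean = np.empty((N, *window))
    for n in range(N):
        s_int, s_sub = split_shift(scan.positions[n])
        P_n = shift_probe_subpixel(probe.values, s_sub)
        O_n = object_patch(phantom.values, s_int, window)
        clean[n] = clean_intensity(exit_wave(O_n, P_n))
    dc_max = clean[:, 0, 0].max()
    if dc_max <= 0:
        raise ValueError("zero diffracted intensity at the origin")
    scale = I0 / dc_max
    clean *= scale
    if noise == "poisson":
        intensities = apply_poisson_noise(clean, noise_seed)
    elif noise == "clean":
        intensities = clean
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return SimulatedDataset(
        dataset=DiffractionSet(intensities, noise_model=noise,
                               seed=noise_seed if noise == "poisson" else None),
        scan=scan,
        truth_object=phantom,
        truth_probe=ProbeField(np.sqrt(scale) * probe.values, probe.pixel_pitch),
        dose_scale=scale,
    )


def simulate(spec: SimSpec) -> SimulatedDataset:
    """Generate a full synthetic measurement from a :class:`SimSpec`."""
    phantom = make_particle_phantom(spec.phantom)
    probe = make_probe(spec.window, spec.probe_diameter,
                       spec.probe_softness, spec.probe_defocus)
    scan = make_scan(spec)
    sim = simulate_dataset(phantom, probe, scan, spec.dose_I0,
                           noise_seed=spec.noise_seed, noise=spec.noise)
    sim.spec = spec
    return sim


def default_initializers(dataset: DiffractionSet, window=None,
                         probe_diameter: float | None = None,
                         canvas: tuple[int, int] = (64, 64)):
    """Blind starting fields: all-ones object, soft disk probe.

    The probe starts as a soft-edged disk at the nominal illumination
    diameter (0.6 x window by default) and is scaled so its energy matches
    the mean total counts per pattern — by Parseval the measured pattern
    energy, which puts the initial fields on the data's scale.
    """
    window = window or dataset.pattern_shape
    diameter = probe_diameter or 0.6 * min(window)
    O0 = ObjectField(np.ones(canvas, dtype=np.complex128))
    P = make_probe(window, diameter, softness=1.5, defocus=0.0)
    energy = float(np.mean(np.sum(dataset.intensities, axis=(1, 2))))
    P0 = ProbeField(P.values * np.sqrt(energy))
    return O0, P0


# Engine parameter presets for the two dose conditions of the simulation
# study (step sizes shared between ePIE and CRISP, rPIE balancing, CRISP
# clipping and xi-tuning constants, iteration counts).
PRESETS = {
    "high_dose": {
        "dose_I0": 1e10,
        "alpha_o": 1.0, "alpha_p": 0.4,
        "lambda_o": 1.0, "lambda_p": 0.4,
        "gamma_o": 0.1, "gamma_p": 1.0,
        "nu_o": 1.0, "nu_p": 1.0,
        "c": 0.5,
        "K": 300,
    },
    "low_dose": {
        "dose_I0": 1e8,
        "alpha_o": 0.4, "alpha_p": 0.2,
        "lambda_o": 0.4, "lambda_p": 0.2,
        "gamma_o": 0.1, "gamma_p": 5.0,
        "nu_o": 1.0, "nu_p": 1.0,
        "c": 0.01,
        "K": 400,
    },
}
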