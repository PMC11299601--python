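"""HDF5 dataset layout, trace logs and image previews.

Dataset layout (bespoke but documented):

    /data/intensities   (N, H, W) float   diffraction patterns
    /data/positions     (N, 2)    float   scan positions, (y, x) object pixels
    /truth/object       complex 2-D       optional ground truth
    /truth/probe        complex 2-D       optional ground truth (dose-scaled)
    attrs: pixel_pitch, dose_I0, seed, noise_model, dose_scale,
           origin_convention ("DC bin of the unshifted transform")

Complex arrays are stored as native complex datasets.  Traces go to CSV,
scalar reports to JSON, previews to float32 TIFF (amplitude plane and phase
plane in radians, wrapped to (-pi, pi]).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .fields import DiffractionSet, ObjectField, ProbeField, ScanPlan
from .simulate import SimulatedDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "write_trace_csv",
    "read_trace_csv",
    "write_frc_csv",
    "write_preview_tiff",
    "write_json_report",
    "save_reconstruction",
    "load_reconstruction",
]

ORIGIN_CONVENTION = "DC bin of the unshifted transform"


def save_dataset(path, sim: SimulatedDataset, dose_I0: float | None = None) -> None:
    """Write a simulated dataset (and its truth, if present) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("data")
        g.create_dataset("intensities", data=sim.dataset.intensities)
        g.create_dataset("positions", data=sim.scan.positions)
        if sim.truth_object is not None:
            t = f.create_group("truth")
            t.create_dataset("object", data=sim.truth_object.values)
            t.create_dataset("probe", data=sim.truth_probe.values)
        f.attrs["pixel_pitch"] = sim.truth_object.pixel_pitch if sim.truth_object else 1.0
        f.attrs["noise_model"] = sim.dataset.noise_model
        f.attrs["seed"] = -1 if sim.dataset.seed is None else sim.dataset.seed
        f.attrs["dose_scale"] = sim.dose_scale
        f.attrs["origin_convention"] = ORIGIN_CONVENTION
        if dose_I0 is not None:
            f.attrs["dose_I0"] = dose_I0
        elif sim.spec is not None:
            f.attrs["dose_I0"] = sim.spec.dose_I0


def load_dataset(path) -> SimulatedDataset:
    """Read a dataset written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        intensities = f["data/intensities"][...]
        positions = f["data/positions"][...]
        noise_model = str(f.attrs.get("noise_model", "clean"))
        seed = int(f.attrs.get("seed", -1))
        pitch = float(f.attrs.get("pixel_pitch", 1.0))
        scale = float(f.attrs.get("dose_scale", 1.0))
        truth_o = truth_p = None
        if "truth" in f:
            truth_o = ObjectField(f["truth/object"][...], pitch)
            truth_p = ProbeField(f["truth/probe"][...], pitch)
    return SimulatedDataset(
        dataset=DiffractionSet(intensities, noise_model=noise_model,
                               seed=None if seed < 0 else seed),
        scan=ScanPlan(positions),
        truth_object=truth_o,
        truth_probe=truth_p,
        dose_scale=scale,
    )


def write_trace_csv(path, result) -> None:
    """Per-iteration log: k, R_F, mean cost (and xi for CRISP runs)."""
    has_xi = result.xi_trace is not None
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["k", "r_factor", "mean_cost"] + (["xi"] if has_xi else []))
        for k in range(len(result.r_factor_trace)):
            row = [k + 1, repr(float(result.r_factor_trace[k])),
                   repr(float(result.cost_trace[k]))]
            if has_xi:
                row.append(repr(float(result.xi_trace[k])))
            w.writerow(row)


def read_trace_csv(path) -> dict[str, np.ndarray]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        cols = {h: [] for h in header}
        for row in reader:
            for h, v in zip(header, row):
                cols[h].append(float(v))
    return {h: np.asarray(v) for h, v in cols.items()}


def write_frc_csv(path, curve) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ring", "frequency", "frc", "count"])
        for s, f, v, c in zip(curve.rings, curve.frequencies,
                              curve.values, curve.counts):
            w.writerow([s, repr(float(f)), repr(float(v)), c])


def write_preview_tiff(path, complex_field) -> None:
    """Two-plane float32 TIFF preview: amplitude and wrapped phase (radians)."""
    a = np.asarray(getattr(complex_field, "values", complex_field))
    amp = np.abs(a).astype(np.float32)
    # wrap to (-pi, pi]
    phase = np.angle(a)
    phase = np.where(phase <= -np.pi, phase + 2 * np.pi, phase).astype(np.float32)
    tifffile.imwrite(path, np.stack([amp, phase]))


def write_json_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_reconstruction(path, result) -> None:
    """Store final fields and traces of a reconstruction run in HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("object", data=result.object.values)
        f.create_dataset("probe", data=result.probe.values)
        f.create_dataset("r_factor_trace", data=result.r_factor_trace)
        f.create_dataset("cost_trace", data=result.cost_trace)
        if result.xi_trace is not None:
            f.create_dataset("xi_trace", data=result.xi_trace)
        f.attrs["algorithm"] = result.algorithm
        f.attrs["iterations"] = result.iterations
        f.attrs["seed"] = result.seed
        f.attrs["skipped_samples"] = result.skipped_samples


def load_reconstruction(path):
    from .pie import ReconResult

    with h5py.File(path, "r") as f:
        return ReconResult(
            object=ObjectField(f["object"][...]),
            probe=ProbeField(f["probe"][...]),
            r_factor_trace=f["r_factor_trace"][...],
            cost_trace=f["cost_trace"][...],
            xi_trace=f["xi_trace"][...] if "xi_trace" in f else None,
            algorithm=str(f.attrs["algorithm"]),
            iterations=int(f.attrs["iterations"]),
            seed=int(f.attrs["seed"]),
            skipped_samples=int(f.attrs["skipped_samples"]),
        )
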