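"""Mid-plane radiograph formation and imaging-dose accounting.

Accepted events are projected to the imaging plane placed at the phantom
inhomogeneity depth: the front segment is extrapolated to the upstream
phantom face, the rear segment back-extrapolated to the downstream face,
and the straight connection line between those two surface points is
evaluated at the plane.  Per 220 um image bin the running mean and
standard deviation of deposited energy, the ion count, the mean
front-to-rear angular change and the mean cluster size are accumulated.

On the rising Bragg flank a *larger* water-equivalent thickness upstream
means a deeper sampling point and therefore a *higher* energy deposition:
the air-step side of the phantom images darker (lower mean energy) than
the bulk side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import physics
from .config import BeamSpec, ImagingPlaneSpec, PhantomSpec
from .events import MatchedEvent

__all__ = [
    "RadiographImage", "DoseReport", "event_midplane_position",
    "accumulate_image", "image_from_events", "event_channels", "compute_dose",
    "fluence_for_dose",
]

CHANNELS = ("count", "mean_energy", "energy_sd", "mean_angle", "mean_cluster_size")


def event_midplane_position(event: MatchedEvent, phantom: PhantomSpec,
                            plane: ImagingPlaneSpec) -> tuple[float, float]:
    """Connection-line crossing of the imaging plane for one event.

    Raises ValueError if either segment misses the phantom face (outside
    the sensor-covered aperture), in which case the event is excluded.
    """
    if event.front is None or event.rear is None:
        raise ValueError("event lacks tracker segments")
    xf, yf = event.front.extrapolate(phantom.upstream_face_z)
    xr, yr = event.rear.extrapolate(phantom.downstream_face_z)
    half = 7.04 + 2.0  # generous aperture around the sensor stack
    if max(abs(xf), abs(yf), abs(xr), abs(yr)) > half:
        raise ValueError("segment misses the phantom aperture")
    f = ((plane.z_position_mm - phantom.upstream_face_z)
         / (phantom.downstream_face_z - phantom.upstream_face_z))
    return xf + f * (xr - xf), yf + f * (yr - yf)


@dataclass
class RadiographImage:
    """Multi-channel image on the mid-plane grid.

    Channels are defined only where ``count > 0`` (NaN elsewhere); bin [i,j]
    covers x_edges[i]..x_edges[i+1], y_edges[j]..y_edges[j+1].
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    channels: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def count(self) -> np.ndarray:
        return self.channels["count"]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def roi_values(self, name: str, x0, x1, y0, y1) -> np.ndarray:
        """Populated-bin values of a channel within a rectangle (mm)."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        sel = np.ix_((xc >= x0) & (xc <= x1), (yc >= y0) & (yc <= y1))
        vals = self.channels[name][sel]
        return vals[np.isfinite(vals) & (self.count[sel] > 0)]

    def write(self, directory, stem: str = "radiograph") -> None:
        """32-bit float TIFF per channel + CSV export + JSON sidecar."""
        import tifffile
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, arr in self.channels.items():
            tifffile.imwrite(d / f"{stem}_{name}.tif",
                             arr.astype(np.float32).T)
            pd.DataFrame(arr).to_csv(d / f"{stem}_{name}.csv", index=False,
                                     header=False)
        sidecar = {"x_edges_mm": self.x_edges.tolist(),
                   "y_edges_mm": self.y_edges.tolist(), **self.meta}
        (d / f"{stem}_meta.json").write_text(json.dumps(sidecar, indent=1))


def accumulate_image(positions: np.ndarray, energies: np.ndarray,
                     angles: np.ndarray, sizes: np.ndarray,
                     plane: ImagingPlaneSpec) -> RadiographImage:
    """Bin events into the imaging grid (order-independent accumulators).

    Each event contributes wholly to the bin containing its position (no
    splatting, which would correlate neighbouring-bin noise).
    """
    pitch = plane.pixel_pitch_um / 1e3
    hx, hy = plane.extent_x_mm / 2.0, plane.extent_y_mm / 2.0
    x_edges = np.arange(-hx, hx + pitch / 2, pitch)
    y_edges = np.arange(-hy, hy + pitch / 2, pitch)
    pos = np.asarray(positions, float).reshape(-1, 2)
    e = np.asarray(energies, float)
    a = np.asarray(angles, float)
    s = np.asarray(sizes, float)

    def hist(w=None):
        h, _, _ = np.histogram2d(pos[:, 0], pos[:, 1],
                                 bins=(x_edges, y_edges), weights=w)
        return h

    n = hist()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_e = hist(e) / n
        mean_e2 = hist(e * e) / n
        sd = np.sqrt(np.maximum(mean_e2 - mean_e ** 2, 0.0) * n
                     / np.maximum(n - 1, 1))
        mean_a = hist(a) / n
        mean_s = hist(s) / n
    empty = n == 0
    for arr in (mean_e, sd, mean_a, mean_s):
        arr[empty] = np.nan
    sd[n == 1] = 0.0
    return RadiographImage(
        x_edges=x_edges, y_edges=y_edges,
        channels={"count": n, "mean_energy": mean_e, "energy_sd": sd,
                  "mean_angle": mean_a, "mean_cluster_size": mean_s},
        meta={"pixel_pitch_um": plane.pixel_pitch_um,
              "plane_z_mm": plane.z_position_mm,
              "n_events": int(len(pos))})


def event_channels(events: list[MatchedEvent], phantom: PhantomSpec,
                   plane: ImagingPlaneSpec, positions: str = "midplane",
                   accepted_only: bool = True):
    """Extract (positions, energies, angles, sizes) arrays from events.

    ``positions='midplane'`` uses the connection-line projection (requires
    both segments); ``'detector'`` uses the raw energy-cluster centroid,
    the no-tracking variant.
    """
    pos, e, a, s = [], [], [], []
    for ev in events:
        if accepted_only and not ev.accepted:
            continue
        cl = ev.energy_cluster
        if cl is None or cl.energy_mev is None:
            continue
        if positions == "midplane":
            try:
                p = event_midplane_position(ev, phantom, plane)
            except ValueError:
                continue
            ang = float(np.hypot(ev.front.tx - ev.rear.tx,
                                 ev.front.ty - ev.rear.ty))
        else:
            p = cl.centroid_mm
            ang = np.nan
        pos.append(p)
        e.append(cl.energy_mev)
        a.append(ang)
        s.append(cl.size)
    if not pos:
        return (np.zeros((0, 2)), np.zeros(0), np.zeros(0), np.zeros(0))
    return (np.asarray(pos), np.asarray(e), np.asarray(a), np.asarray(s))


def image_from_events(events: list[MatchedEvent], phantom: PhantomSpec,
                      plane: ImagingPlaneSpec, positions: str = "midplane",
                      accepted_only: bool = True) -> RadiographImage:
    pos, e, a, s = event_channels(events, phantom, plane, positions,
                                  accepted_only)
    return accumulate_image(pos, e, a, s, plane)


# ---------------------------------------------------------------------------
# dose accounting

@dataclass
class DoseReport:
    """Imaging dose summary; dose is linear in fluence by construction."""

    fluence_per_cm2: float
    mean_dose_ugy: float
    slab_depth_mm: np.ndarray
    slab_dose_ugy: np.ndarray


def _slab_doses(beam: BeamSpec, phantom: PhantomSpec, fluence: float,
                n_slabs: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-slab dose from Phi * S/rho at the local mean energy."""
    ion = beam.ion
    edges = np.linspace(0.0, phantom.length_mm, n_slabs + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    doses = np.empty(n_slabs)
    e = beam.energy_per_nucleon
    mat = phantom.bulk
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        e_mid = physics.energy_after(ion, e, mat, (hi - lo) / 2.0 / 10.0)
        e_mid = max(e_mid, physics.E_MIN)
        s = physics.mass_stopping_power(ion, e_mid, mat)
        doses[i] = fluence * s * physics.MEV_PER_G_TO_GY * 1e6  # uGy
        e = physics.energy_after(ion, e, mat, (hi - lo) / 10.0)
        e = max(e, physics.E_MIN)
    return mids, doses


def compute_dose(beam: BeamSpec, phantom: PhantomSpec,
                 fluence_per_cm2: float, n_slabs: int = 64) -> DoseReport:
    """Mean dose to the phantom for a given primary fluence.

    The phantom is sliced along the beam; each slab receives
    Phi * (S/rho)(E_slab), with the energy degraded slab by slab; the mean
    over slabs is the mass-averaged phantom dose (the step is a negligible
    mass fraction and is ignored).
    """
    mids, doses = _slab_doses(beam, phantom, fluence_per_cm2, n_slabs)
    return DoseReport(fluence_per_cm2=fluence_per_cm2,
                      mean_dose_ugy=float(doses.mean()),
                      slab_depth_mm=mids, slab_dose_ugy=doses)


def fluence_for_dose(beam: BeamSpec, phantom: PhantomSpec,
                     target_dose_ugy: float, n_slabs: int = 64) -> float:
    """Inverse mode: fluence (cm^-2) delivering a requested mean dose."""
    ref = compute_dose(beam, phantom, 1.0, n_slabs)
    return target_dose_ugy / ref.mean_dose_ugy
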