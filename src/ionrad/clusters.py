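"""Cluster finding, descriptors and energy calibration.

A *cluster* is a connected group of fired pixels left by one particle (or,
in pile-up, several).  Clusters are found by 8-connected component
labelling; their descriptors - volume (summed counts), size (pixel count),
value-weighted sub-pixel centroid, arrival-tick statistics in time mode and
the number of plateau-merged local maxima - feed every downstream cut.

Calibration is two-stage, mirroring the detector chain: a per-pixel
electronics response (counts as a function of deposited keV, the standard
linear-plus-hook surrogate ``counts = a*E + b - c/(E - t)``) inverted
pixel-by-pixel, and one global monotone recalibration curve that maps the
partial-depletion (10 V bias) cluster volume back to true deposited energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .config import pixel_to_mm
from .frames import Frame, read_frames

__all__ = [
    "Cluster", "find_clusters", "decode_frames",
    "CalibrationMap", "apply_pixel_calibration",
    "RecalibrationCurve", "recalibrate_partial_depletion",
    "build_recalibration_curve",
]

decode_frames = read_frames

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Cluster:
    """A connected pixel group with its descriptors.

    ``volume`` is the sum of raw values (counts); ``calibrated_energy_mev``
    is filled by :func:`apply_pixel_calibration`.  ``centroid_mm`` is the
    sub-pixel center of mass (value-weighted in energy mode, unweighted in
    time mode, where pixel values are arrival ticks, not signal).
    """

    layer: int
    frame: int
    mode: str
    cols: np.ndarray
    rows: np.ndarray
    values: np.ndarray
    n_local_maxima: int = 1
    flags: set = field(default_factory=set)
    calibrated_energy_mev: float | None = None
    pixel_energies_kev: np.ndarray | None = None
    recalibrated_energy_mev: float | None = None

    @property
    def size(self) -> int:
        return len(self.values)

    @property
    def volume(self) -> int:
        return int(self.values.sum())

    @property
    def centroid_mm(self) -> tuple[float, float]:
        w = self.values.astype(float) if self.mode == "energy" else None
        x = float(np.average(pixel_to_mm(self.cols), weights=w))
        y = float(np.average(pixel_to_mm(self.rows), weights=w))
        return x, y

    @property
    def arrival_tick(self) -> int:
        """Earliest tick in the cluster (time mode)."""
        return int(self.values.min())

    @property
    def tick_spread(self) -> int:
        return int(self.values.max() - self.values.min())

    @property
    def energy_mev(self) -> float | None:
        """Best available energy: recalibrated, else calibrated."""
        if self.recalibrated_energy_mev is not None:
            return self.recalibrated_energy_mev
        return self.calibrated_energy_mev


def _count_local_maxima(img: np.ndarray) -> int:
    """Plateau-merged count of pixels >= all 8 neighbours within a cluster.

    A plateau of equal-valued dominant pixels counts once, so flat-topped
    single-ion clusters are not mistaken for pile-up.
    """
    # treat off-cluster pixels as -1 so edge pixels can dominate
    work = np.where(img > 0, img.astype(float), -1.0)
    dominant = (ndimage.maximum_filter(work, size=3, mode="constant",
                                       cval=-1.0) == work) & (img > 0)
    _, n = ndimage.label(dominant, structure=_STRUCT8)
    return int(n)


def find_clusters(frame: Frame, connectivity: int = 2) -> list["Cluster"]:
    """Partition a frame's hit pixels into connected components.

    ``connectivity`` 2 means 8-connectivity (default; round ion clusters
    with diagonal corner pixels must not fragment), 1 means 4-connectivity.
    """
    if frame.n_hits == 0:
        return []
    cols, rows, values = frame.to_arrays()
    n = 256
    img = np.zeros((n, n), dtype=np.int64)
    img[rows, cols] = values
    structure = _STRUCT8 if connectivity == 2 else ndimage.generate_binary_structure(2, 1)
    labels, n_lab = ndimage.label(img > 0, structure=structure)
    out = []
    lab_of_hit = labels[rows, cols]
    order = np.argsort(lab_of_hit, kind="stable")
    sorted_lab = lab_of_hit[order]
    lab_ids = np.arange(1, n_lab + 1)
    starts = np.searchsorted(sorted_lab, lab_ids, side="left")
    ends = np.searchsorted(sorted_lab, lab_ids, side="right")
    for k in range(n_lab):
        sel = order[starts[k]:ends[k]]
        c, r, v = cols[sel], rows[sel], values[sel]
        r0, r1, c0, c1 = r.min(), r.max(), c.min(), c.max()
        sub = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=np.int64)
        sub[r - r0 + 1, c - c0 + 1] = v
        nmax = _count_local_maxima(sub) if len(v) > 1 else 1
        out.append(Cluster(layer=frame.layer, frame=frame.index,
                           mode=frame.mode, cols=c, rows=r, values=v,
                           n_local_maxima=nmax))
    return out


# ---------------------------------------------------------------------------
# per-pixel electronics calibration


class CalibrationMap:
    """Per-pixel response parameters (a, b, c, t) over the 256 x 256 matrix.

    The forward response (simulator side) is ``counts = a*E + b - c/(E-t)``
    for deposited energy E in keV above the hook threshold t; the analysis
    side inverts it per pixel.  The identity map (a=1, b=0, c=0, t=0) makes
    counts numerically equal to keV.
    """

    def __init__(self, a, b, c, t):
        self.a = np.broadcast_to(np.asarray(a, float), (256, 256)).copy()
        self.b = np.broadcast_to(np.asarray(b, float), (256, 256)).copy()
        self.c = np.broadcast_to(np.asarray(c, float), (256, 256)).copy()
        self.t = np.broadcast_to(np.asarray(t, float), (256, 256)).copy()
        if np.any(self.a <= 0):
            raise ValueError("gain a must be positive everywhere")
        self.is_identity = bool(
            np.all(self.a == 1.0) and not self.b.any()
            and not self.c.any() and not self.t.any())

    @classmethod
    def identity(cls) -> "CalibrationMap":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def random(cls, rng: np.random.Generator, gain_sd: float = 0.05,
               offset_sd: float = 2.0, hook: bool = True) -> "CalibrationMap":
        """A plausible inhomogeneous detector: ~5% gain spread, small
        offsets, and a low-energy hook below ~3 keV."""
        a = rng.normal(1.0, gain_sd, (256, 256)).clip(0.5)
        b = rng.normal(0.0, offset_sd, (256, 256))
        c = rng.uniform(20.0, 60.0, (256, 256)) if hook else np.zeros((256, 256))
        t = rng.uniform(0.5, 2.5, (256, 256)) if hook else np.zeros((256, 256))
        return cls(a, b, c, t)

    # forward model (used by the simulator)
    def counts_from_energy(self, cols, rows, energy_kev):
        a = self.a[rows, cols]; b = self.b[rows, cols]
        c = self.c[rows, cols]; t = self.t[rows, cols]
        e = np.asarray(energy_kev, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            hook = np.where(e > t, c / (e - t), np.inf)
        return a * e + b - hook

    def energy_from_counts(self, cols, rows, counts):
        """Invert the response; returns (energy_kev, valid_mask)."""
        a = self.a[rows, cols]; b = self.b[rows, cols]
        c = self.c[rows, cols]; t = self.t[rows, cols]
        n = np.asarray(counts, float)
        # a*E^2 + (b - a*t - n)*E + (n*t - b*t - c) = 0, branch E > t
        B = b - a * t - n
        C = n * t - b * t - c
        disc = B * B - 4.0 * a * C
        valid = disc >= 0
        e = np.where(valid, (-B + np.sqrt(np.abs(disc))) / (2.0 * a), np.nan)
        valid &= e > t + 1e-12
        return e, valid

    # CSV round trip: one row per pixel
    def to_csv(self, path) -> None:
        cols, rows = np.meshgrid(np.arange(256), np.arange(256))
        pd.DataFrame({
            "col": cols.ravel(), "row": rows.ravel(),
            "a": self.a[rows.ravel(), cols.ravel()],
            "b": self.b[rows.ravel(), cols.ravel()],
            "c": self.c[rows.ravel(), cols.ravel()],
            "t": self.t[rows.ravel(), cols.ravel()],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationMap":
        df = pd.read_csv(path)
        maps = {}
        for name in "abct":
            m = np.zeros((256, 256))
            m[df["row"], df["col"]] = df[name]
            maps[name] = m
        return cls(maps["a"], maps["b"], maps["c"], maps["t"])


def apply_pixel_calibration(cluster: Cluster, cal: CalibrationMap) -> Cluster:
    """Convert an energy-mode cluster's counts to per-pixel keV in place.

    Pixels whose counts fall outside the invertible branch of their response
    (at or below the hook threshold) are flagged and excluded from the
    calibrated volume; the cluster is flagged ``overshoot`` since a
    non-invertible reading indicates a distorted signal.
    """
    if cluster.mode != "energy":
        raise ValueError("per-pixel calibration applies to energy-mode clusters")
    e, valid = cal.energy_from_counts(cluster.cols, cluster.rows,
                                      cluster.values.astype(float))
    # counts numerically at/below the hook threshold are degenerate readings
    valid &= cluster.values.astype(float) > cal.t[cluster.rows, cluster.cols]
    if not valid.all():
        cluster.flags.add("overshoot")
    cluster.pixel_energies_kev = np.where(valid, e, 0.0)
    cluster.calibrated_energy_mev = float(cluster.pixel_energies_kev.sum() / 1e3)
    return cluster


# ---------------------------------------------------------------------------
# global partial-depletion recalibration


class RecalibrationCurve:
    """Monotone map from measured cluster energy (MeV) to true deposition.

    Built from a (measured, true) scan of the simulator's 10 V response;
    stored as knots, evaluated with a PCHIP monotone spline.
    """

    def __init__(self, measured_mev: np.ndarray, true_mev: np.ndarray):
        m = np.asarray(measured_mev, float)
        t = np.asarray(true_mev, float)
        order = np.argsort(m)
        m, t = m[order], t[order]
        if np.any(np.diff(m) <= 0) or np.any(np.diff(t) < 0):
            raise ValueError("recalibration curve must be strictly monotone")
        self.measured = m
        self.true = t
        self._interp = PchipInterpolator(m, t, extrapolate=False)

    @classmethod
    def identity(cls, lo: float = 0.0, hi: float = 20.0) -> "RecalibrationCurve":
        knots = np.linspace(lo, hi, 32)
        return cls(knots, knots)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.measured[0]), float(self.measured[-1])

    def __call__(self, measured_mev):
        lo, hi = self.domain
        x = np.asarray(measured_mev, float)
        clipped = np.clip(x, lo, hi)
        if np.any(x != clipped):
            warnings.warn("measured energy outside recalibration domain; clamped",
                          stacklevel=2)
        out = self._interp(clipped)
        return float(out) if out.ndim == 0 else out

    def to_csv(self, path) -> None:
        pd.DataFrame({"measured_mev": self.measured,
                      "true_mev": self.true}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RecalibrationCurve":
        df = pd.read_csv(path)
        return cls(df["measured_mev"].to_numpy(), df["true_mev"].to_numpy())


def build_recalibration_curve(measured_mev, true_mev,
                              n_knots: int = 24) -> RecalibrationCurve:
    """Fit a monotone curve to a noisy (measured, true) scan.

    Bins the scan in measured energy, takes per-bin medians, enforces
    monotonicity, and refines once by re-binning against the residual of the
    first pass (the 'iterate once' scheme).
    """
    m = np.asarray(measured_mev, float)
    t = np.asarray(true_mev, float)

    def fit(mm, tt):
        edges = np.quantile(mm, np.linspace(0, 1, n_knots + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, mm, side="right") - 1,
                      0, len(edges) - 2)
        km = [np.median(mm[idx == k]) for k in range(len(edges) - 1)]
        kt = [np.median(tt[idx == k]) for k in range(len(edges) - 1)]
        # anchor the domain ends so the working window needs no clamping
        order = np.argsort(mm)
        k_edge = max(3, mm.size // 500)
        km = [mm.min()] + km + [mm.max()]
        kt = [np.median(tt[order[:k_edge]])] + kt \
            + [np.median(tt[order[-k_edge:]])]
        km = np.asarray(km)
        kt = np.maximum.accumulate(np.asarray(kt))
        keep = np.concatenate([[True], np.diff(km) > 1e-9])
        return RecalibrationCurve(km[keep], kt[keep])

    first = fit(m, t)
    lo, hi = first.domain
    inside = (m >= lo) & (m <= hi)
    resid = t - first(np.clip(m, lo, hi))
    second = fit(m[inside], first(m[inside]) + resid[inside])
    return second


def recalibrate_partial_depletion(volume_mev, curve: RecalibrationCurve):
    """Map a measured (partial-depletion) cluster energy to true MeV.

    Inputs outside the curve's domain are clamped with a warning.
    """
    return curve(volume_mev)
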