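"""Event building: cleaning cuts, alignment, tracking, matching, species ID.

The chain turns per-layer clusters into accepted single-helium events:

1. *Cleaning* flags pile-up (multiple local maxima), readout overshoots
   (arrival-tick incoherence in time mode, >1 MeV calibrated pixels in
   energy mode), photon/electron background (tiny low-energy clusters) and
   temporally cropped signals (arrival too close to a frame boundary for
   full digitization; energy-mode clusters inherit their time from the
   matched tracker cluster).
2. *Alignment* recovers the per-layer mechanical offsets from a
   phantom-free narrow-beam run via the fluence-maximum beam centroid,
   referenced to the energy layer.
3. *Tracking* pairs clusters across the two layers of each tracker by
   arrival tick (nearest-position tie-break, purity over efficiency),
   and front/rear segments are matched the same way.
4. *Association* extrapolates the rear segment to the energy layer and
   claims the nearest clean energy cluster within 220 um (4 pixels).
5. *Species identification* separates helium from hydrogen fragments with
   a linear boundary in the (cluster volume, cluster size) plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import (CalibrationMap, Cluster, RecalibrationCurve,
                       apply_pixel_calibration, find_clusters,
                       recalibrate_partial_depletion)
from .config import AcquisitionSpec, CutConfig, LayerSpec, RunConfig
from .frames import Frame

__all__ = [
    "AlignmentSolution", "TrackSegment", "MatchedEvent", "SpeciesBoundary",
    "clean_clusters", "is_clean", "estimate_alignment", "build_segments",
    "match_front_rear", "associate_energy_cluster", "classify_species",
    "fit_species_boundary", "default_species_boundary", "build_events",
    "events_to_dataframe",
]


# ---------------------------------------------------------------------------
# cleaning

def clean_clusters(clusters: list[Cluster], cuts: CutConfig) -> tuple[list, list]:
    """Set artifact flags; returns (all clusters, rejected subset).

    Flags are independent and commute: ``overlap`` (>= 2 plateau-merged
    local maxima), ``overshoot`` (tick spread beyond the coherence cut in
    time mode; any calibrated pixel above ~1 MeV in energy mode),
    ``background`` (small, low-signal cluster).  Temporal cropping needs an
    arrival time and is flagged during association.
    """
    rejected = []
    for cl in clusters:
        if cl.n_local_maxima >= 2:
            cl.flags.add("overlap")
        if cl.mode == "time":
            if cl.tick_spread > cuts.max_tick_spread:
                cl.flags.add("overshoot")
            if cl.size <= cuts.background_size_max:
                cl.flags.add("background")
        else:
            if cl.pixel_energies_kev is not None and cl.pixel_energies_kev.size \
                    and cl.pixel_energies_kev.max() > cuts.overshoot_pixel_energy_mev * 1e3:
                cl.flags.add("overshoot")
            vol = cl.calibrated_energy_mev
            if cl.size <= cuts.background_size_max and vol is not None \
                    and vol < cuts.background_volume_max_mev:
                cl.flags.add("background")
        if cl.flags:
            rejected.append(cl)
    return clusters, rejected


def is_clean(cluster: Cluster) -> bool:
    return not cluster.flags


def _tick_time_us(tick: int, acq: AcquisitionSpec) -> float:
    return (tick - 0.5) * acq.time_tick_ns / 1e3


def is_cropped(tick: int, acq: AcquisitionSpec, cuts: CutConfig) -> bool:
    """Arrival within the crop guard of either frame boundary."""
    t = _tick_time_us(tick, acq)
    return t < cuts.crop_guard_us or t > acq.frame_duration_us - cuts.crop_guard_us


# ---------------------------------------------------------------------------
# alignment

@dataclass
class AlignmentSolution:
    """Per-layer (dx, dy) offsets in mm relative to the energy layer.

    Adding the offset to a measured sensor-frame position expresses it in
    the common (layer-3) frame; the layer-3 offset is identically zero.
    """

    offsets_mm: dict = field(default_factory=dict)

    def offset(self, layer_index: int) -> tuple[float, float]:
        return self.offsets_mm.get(layer_index, (0.0, 0.0))

    def apply(self, layer_index: int, x_mm: float, y_mm: float):
        dx, dy = self.offset(layer_index)
        return x_mm + dx, y_mm + dy

    @property
    def offsets_um(self) -> dict:
        return {k: (vx * 1e3, vy * 1e3) for k, (vx, vy) in self.offsets_mm.items()}

    @classmethod
    def identity(cls) -> "AlignmentSolution":
        return cls()

    def to_csv(self, path) -> None:
        rows = [{"layer": k, "dx_um": vx * 1e3, "dy_um": vy * 1e3}
                for k, (vx, vy) in sorted(self.offsets_mm.items())]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AlignmentSolution":
        df = pd.read_csv(path)
        return cls({int(r.layer): (r.dx_um / 1e3, r.dy_um / 1e3)
                    for r in df.itertuples()})


def _beam_centroid(frames: list[Frame], min_size: int = 3,
                   window_mm: float = 6.0) -> tuple[float, float, int]:
    """Beam position on one layer: robust mean of ion-cluster centroids.

    The window around the median only rejects stray background far from the
    beam spot; within it essentially every primary contributes on every
    layer, so beam-profile sampling noise is common mode and cancels in
    the between-layer differences that form the alignment solution.
    """
    xs, ys = [], []
    for fr in frames:
        for cl in find_clusters(fr):
            if cl.size >= min_size:
                x, y = cl.centroid_mm
                xs.append(x)
                ys.append(y)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    n = xs.size
    if n == 0:
        raise ValueError("no ion clusters found for alignment")
    sel = (np.abs(xs - np.median(xs)) < window_mm) \
        & (np.abs(ys - np.median(ys)) < window_mm)
    return float(xs[sel].mean()), float(ys[sel].mean()), n


def estimate_alignment(frames_by_layer: dict[int, list[Frame]],
                       reference_layer: int = 3) -> AlignmentSolution:
    """Recover per-layer offsets from a phantom-free narrow-beam run.

    On each layer the beam position is the point of maximum fluence; the
    offset is the reference-layer centroid minus the layer centroid, so
    that corrected positions of a straight-through beam agree across
    layers.  Warns when a layer has fewer than 1000 usable clusters.
    """
    cents = {}
    for idx, frames in frames_by_layer.items():
        cx, cy, n = _beam_centroid(frames)
        if n < 1000:
            warnings.warn(f"layer {idx}: only {n} clusters; alignment "
                          "precision degraded", stacklevel=2)
        cents[idx] = (cx, cy)
    rx, ry = cents[reference_layer]
    return AlignmentSolution({idx: (rx - cx, ry - cy)
                              for idx, (cx, cy) in cents.items()})


# ---------------------------------------------------------------------------
# tracking

@dataclass
class TrackSegment:
    """Straight two-point segment through one tracker."""

    tracker: str                # "front" | "rear"
    x0: float                   # position at reference z (mm, aligned frame)
    y0: float
    z0: float
    tx: float                   # dx/dz
    ty: float
    tick: int
    frame: int
    cluster_ids: tuple = ()

    def extrapolate(self, z_mm: float) -> tuple[float, float]:
        dz = z_mm - self.z0
        return self.x0 + self.tx * dz, self.y0 + self.ty * dz


def _greedy_pairs(cands: list[tuple], tie_eps: float = 1e-9) -> list[tuple]:
    """Greedy matching over (cost1, cost2, i, j) candidates.

    Accepts pairs in cost order; a cluster facing two candidates of equal
    cost is dropped entirely (purity over efficiency).
    """
    cands = sorted(cands, key=lambda c: (c[0], c[1]))
    used_i, used_j, banned_i, banned_j = set(), set(), set(), set()
    # detect exact ties: same i (or j) with indistinguishable costs
    by_i: dict = {}
    by_j: dict = {}
    for c in cands:
        by_i.setdefault(c[2], []).append(c)
        by_j.setdefault(c[3], []).append(c)
    for key, group, banned in (("i", by_i, banned_i), ("j", by_j, banned_j)):
        for idx, lst in group.items():
            if len(lst) >= 2:
                a, b = lst[0], lst[1]
                if abs(a[0] - b[0]) <= tie_eps and abs(a[1] - b[1]) <= tie_eps:
                    banned.add(idx)
    out = []
    for cost1, cost2, i, j in cands:
        if i in used_i or j in used_j or i in banned_i or j in banned_j:
            continue
        used_i.add(i)
        used_j.add(j)
        out.append((i, j))
    return out


def build_segments(clusters_a: list[Cluster], clusters_b: list[Cluster],
                   layer_a: LayerSpec, layer_b: LayerSpec, cuts: CutConfig,
                   alignment: AlignmentSolution | None = None,
                   tracker: str = "front") -> list[TrackSegment]:
    """Pair clean time-mode clusters of one tracker into segments.

    Clusters pair when their arrival ticks differ by at most the matching
    window; among candidates the nearest in position wins, and residual
    exact ties drop both candidates.  The segment is parameterized at the
    downstream layer's z.
    """
    alignment = alignment or AlignmentSolution.identity()
    ca = [c for c in clusters_a if is_clean(c)]
    cb = [c for c in clusters_b if is_clean(c)]
    cands = []
    for i, a in enumerate(ca):
        xa, ya = alignment.apply(layer_a.index, *a.centroid_mm)
        for j, b in enumerate(cb):
            dt = abs(a.arrival_tick - b.arrival_tick)
            if dt > cuts.time_match_window:
                continue
            xb, yb = alignment.apply(layer_b.index, *b.centroid_mm)
            dist = float(np.hypot(xb - xa, yb - ya))
            cands.append((dt, dist, i, j))
    segments = []
    dz = layer_b.z_position_mm - layer_a.z_position_mm
    for i, j in _greedy_pairs(cands):
        a, b = ca[i], cb[j]
        xa, ya = alignment.apply(layer_a.index, *a.centroid_mm)
        xb, yb = alignment.apply(layer_b.index, *b.centroid_mm)
        segments.append(TrackSegment(
            tracker=tracker, x0=xb, y0=yb, z0=layer_b.z_position_mm,
            tx=(xb - xa) / dz, ty=(yb - ya) / dz,
            tick=min(a.arrival_tick, b.arrival_tick), frame=a.frame,
            cluster_ids=(id(a), id(b))))
    return segments


def match_front_rear(front: list[TrackSegment], rear: list[TrackSegment],
                     cuts: CutConfig) -> list[tuple[TrackSegment, TrackSegment]]:
    """Time-match front and rear segments; unpaired segments are dropped.

    Matching is species-blind; position enters only as the tie-break
    (front segment extrapolated to the rear reference plane).
    """
    cands = []
    for i, f in enumerate(front):
        for j, r in enumerate(rear):
            dt = abs(f.tick - r.tick)
            if dt > cuts.time_match_window:
                continue
            xf, yf = f.extrapolate(r.z0)
            dist = float(np.hypot(xf - r.x0, yf - r.y0))
            cands.append((dt, dist, i, j))
    return [(front[i], rear[j]) for i, j in _greedy_pairs(cands)]


# ---------------------------------------------------------------------------
# species identification

@dataclass(frozen=True)
class SpeciesBoundary:
    """Linear decision boundary in the (cluster volume, cluster size) plane.

    ``helium`` iff w_volume * volume_MeV + w_size * size + bias > 0.
    """

    w_volume: float
    w_size: float
    bias: float

    def decide(self, volume_mev, size):
        s = self.w_volume * np.asarray(volume_mev, float) \
            + self.w_size * np.asarray(size, float) + self.bias
        return np.where(s > 0, "helium", "hydrogen")


def default_species_boundary() -> SpeciesBoundary:
    """Physics-motivated default: helium deposits ~5 MeV on the Bragg
    flank, hydrogen fragments ~1.3 MeV; split at the midpoint in volume."""
    return SpeciesBoundary(w_volume=1.0, w_size=0.0, bias=-2.7)


def fit_species_boundary(volumes_mev, sizes, labels) -> SpeciesBoundary:
    """Linear discriminant fitted to labelled (volume, size) samples."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    X = np.column_stack([np.asarray(volumes_mev, float),
                         np.asarray(sizes, float)])
    y = (np.asarray(labels) == "helium").astype(int)
    lda = LinearDiscriminantAnalysis().fit(X, y)
    (wv, ws), b = lda.coef_[0], float(lda.intercept_[0])
    return SpeciesBoundary(w_volume=float(wv), w_size=float(ws), bias=b)


def classify_species(volume_mev, size,
                     boundary: SpeciesBoundary | None = None) -> str:
    """Label one energy cluster as helium or hydrogen ('unknown' if the
    descriptors are missing)."""
    if volume_mev is None or size is None or not np.isfinite(volume_mev):
        return "unknown"
    boundary = boundary or default_species_boundary()
    return str(boundary.decide(volume_mev, size))


# ---------------------------------------------------------------------------
# association and full event building

@dataclass
class MatchedEvent:
    """One matched primary: tracker segments, energy cluster, species."""

    front: TrackSegment | None
    rear: TrackSegment | None
    energy_cluster: Cluster | None
    species: str = "unknown"
    status: str = "accepted"
    reason: str = ""
    frame: int = -1

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def associate_energy_cluster(pair: tuple[TrackSegment, TrackSegment],
                             energy_clusters: list[Cluster], cuts: CutConfig,
                             layer3: LayerSpec, acq: AcquisitionSpec,
                             alignment: AlignmentSolution | None = None,
                             claimed: set | None = None) -> MatchedEvent:
    """Attach the nearest clean energy cluster within the association radius.

    The rear segment is extrapolated back to the energy layer; a cluster
    farther than 220 um (4 pixels) leaves the event rejected.  The energy
    cluster inherits the tracker arrival time, which drives the temporal
    cropping cut.
    """
    front, rear = pair
    ev = MatchedEvent(front=front, rear=rear, energy_cluster=None,
                      frame=rear.frame)
    xe, ye = rear.extrapolate(layer3.z_position_mm)
    radius_mm = cuts.energy_association_radius_um / 1e3
    best, best_d = None, np.inf
    for cl in energy_clusters:
        if claimed is not None and id(cl) in claimed:
            continue
        x, y = cl.centroid_mm  # layer 3 is the alignment reference
        d = float(np.hypot(x - xe, y - ye))
        if d < best_d:
            best, best_d = cl, d
    if best is None or best_d > radius_mm:
        ev.status, ev.reason = "rejected", "no-energy"
        return ev
    ev.energy_cluster = best
    if claimed is not None:
        claimed.add(id(best))
    # the energy cluster inherits the tracker arrival time: crop cut
    if is_cropped(rear.tick, acq, cuts):
        ev.status, ev.reason = "rejected", "cropped"
        return ev
    if not is_clean(best):
        ev.status, ev.reason = "rejected", f"artifact:{sorted(best.flags)[0]}"
        return ev
    return ev


def build_events(frames_by_layer: dict[int, list[Frame]], config: RunConfig,
                 calibration: CalibrationMap | None = None,
                 recalibration: RecalibrationCurve | None = None,
                 alignment: AlignmentSolution | None = None,
                 boundary: SpeciesBoundary | None = None,
                 clean: bool = True, identify: bool = True
                 ) -> tuple[list[MatchedEvent], dict]:
    """Run the full chain over all frames; returns (events, run report).

    ``clean``/``identify`` switch off the artifact cuts and the hydrogen
    rejection to reproduce the stage-wise processing variants.  The report
    counts clusters, the fraction of energy clusters matched on all four
    tracking layers, and the rejection breakdown.
    """
    calibration = calibration or CalibrationMap.identity()
    alignment = alignment or AlignmentSolution.identity()
    boundary = boundary or default_species_boundary()
    cuts = config.cuts
    acq = config.acquisition
    layers = {l.index: l for l in config.layers}

    events: list[MatchedEvent] = []
    report = {"n_energy_clusters": 0, "n_matched_full": 0,
              "n_accepted": 0, "rejects": {}}
    n_frames = len(frames_by_layer[3])
    for k in range(n_frames):
        per_layer: dict[int, list[Cluster]] = {}
        for idx in layers:
            per_layer[idx] = find_clusters(frames_by_layer[idx][k])
        for cl in per_layer[3]:
            apply_pixel_calibration(cl, calibration)
            if recalibration is not None and cl.calibrated_energy_mev is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cl.recalibrated_energy_mev = float(
                        recalibrate_partial_depletion(
                            cl.calibrated_energy_mev, recalibration))
        if clean:
            for idx in layers:
                clean_clusters(per_layer[idx], cuts)
        report["n_energy_clusters"] += len(per_layer[3])
        # ion-like clusters: everything bigger than the 1-2 px background
        report["n_ion_clusters"] = report.get("n_ion_clusters", 0) + sum(
            1 for c in per_layer[3] if c.size > cuts.background_size_max)

        front = build_segments(per_layer[1], per_layer[2], layers[1],
                               layers[2], cuts, alignment, "front")
        rear = build_segments(per_layer[4], per_layer[5], layers[4],
                              layers[5], cuts, alignment, "rear")
        claimed: set = set()
        for pair in match_front_rear(front, rear, cuts):
            ev = associate_energy_cluster(pair, per_layer[3], cuts,
                                          layers[3], acq, alignment, claimed)
            if not clean and ev.status == "rejected" \
                    and ev.reason.startswith(("artifact", "cropped")):
                # stage variants without cleaning keep degraded events
                ev.status, ev.reason = "accepted", ""
            if ev.energy_cluster is not None:
                cl = ev.energy_cluster
                ev.species = classify_species(cl.energy_mev, cl.size, boundary)
                report["n_matched_full"] += 1
            if ev.accepted and identify and ev.species != "helium":
                ev.status, ev.reason = "rejected", "species"
            if ev.accepted:
                report["n_accepted"] += 1
            else:
                report["rejects"][ev.reason] = \
                    report["rejects"].get(ev.reason, 0) + 1
            events.append(ev)
    if report.get("n_ion_clusters"):
        # fraction of ion energy clusters matched on all four tracking layers
        report["matched_fraction"] = (report["n_matched_full"]
                                      / report["n_ion_clusters"])
    return events, report


def events_to_dataframe(events: list[MatchedEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {"frame": ev.frame, "status": ev.status, "reason": ev.reason,
               "species": ev.species}
        for name, seg in (("front", ev.front), ("rear", ev.rear)):
            if seg is not None:
                row.update({f"{name}_x": seg.x0, f"{name}_y": seg.y0,
                            f"{name}_tx": seg.tx, f"{name}_ty": seg.ty,
                            f"{name}_tick": seg.tick})
        cl = ev.energy_cluster
        if cl is not None:
            row["energy_mev"] = cl.energy_mev
            row["cluster_size"] = cl.size
            row["ex"], row["ey"] = cl.centroid_mm
        rows.append(row)
    return pd.DataFrame(rows)
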