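"""Cleaning cuts, alignment recovery, tracking, matching and species ID."""

import numpy as np
import pytest

from conftest import make_recal_curve
from ionrad.config import (AcquisitionSpec, ArtifactConfig, CutConfig,
                           RunConfig, default_layers, pixel_to_mm)
from ionrad.clusters import (CalibrationMap, apply_pixel_calibration,
                             find_clusters, recalibrate_partial_depletion)
from ionrad.events import (AlignmentSolution, MatchedEvent, TrackSegment,
                           associate_energy_cluster, build_events,
                           build_segments, classify_species, clean_clusters,
                           default_species_boundary, estimate_alignment,
                           fit_species_boundary, match_front_rear)
from ionrad.frames import Frame
from ionrad.simulate import (energy_response, make_cluster,
                             simulate_alignment_run, simulate_run)


def _cluster_at(x_mm, y_mm, dep_mev, layer, tick=5000, seed=0,
                calibrate=True):
    rng = np.random.default_rng(seed)
    cols, rows, values, _ = make_cluster(x_mm, y_mm, dep_mev, layer, rng,
                                         tick)
    fr = Frame(layer=layer.index, index=0, mode=layer.mode)
    for c, r, v in zip(cols, rows, values):
        fr.pixels[(int(c), int(r))] = int(v)
    (cl,) = find_clusters(fr)
    if calibrate and layer.mode == "energy":
        apply_pixel_calibration(cl, CalibrationMap.identity())
    return cl


class TestCleaning:
    def test_clean_frame_has_empty_rejected_set(self):
        layers = {l.index: l for l in default_layers()}
        cls = [_cluster_at(1.0, 1.0, 5.0, layers[3]),
               _cluster_at(-2.0, 0.5, 5.0, layers[3], seed=1)]
        _, rejected = clean_clusters(cls, CutConfig())
        assert rejected == []

    def test_injected_overlaps_all_flagged(self, medium_run):
        cfg, res = medium_run
        flagged = total = 0
        affected = res.truth.loc[res.truth.overlap_injected, "frame"].unique()
        for k in affected:
            cls = find_clusters(res.frames[3][int(k)])
            for cl in cls:
                apply_pixel_calibration(cl, CalibrationMap.identity())
            clean_clusters(cls, cfg.cuts)
            total += 1
            if any("overlap" in cl.flags for cl in cls):
                flagged += 1
        assert total > 0
        assert flagged == total

    def test_flags_invariant_under_cluster_order(self):
        layers = {l.index: l for l in default_layers()}
        mk = lambda: [_cluster_at(1.0, 1.0, 5.0, layers[3], seed=s)
                      for s in range(6)]
        a, b = mk(), mk()
        clean_clusters(a, CutConfig())
        clean_clusters(list(reversed(b)), CutConfig())
        assert [c.flags for c in a] == [c.flags for c in b]

    def test_time_incoherent_cluster_flagged_overshoot(self):
        layers = {l.index: l for l in default_layers()}
        cl = _cluster_at(0.0, 0.0, 1.3, layers[1], tick=100)
        cl.values[0] += 5  # a pixel with a wildly different arrival tick
        clean_clusters([cl], CutConfig())
        assert "overshoot" in cl.flags


@pytest.fixture(scope="module")
def offset_runs():
    offsets = {1: (80.0, -40.0), 5: (120.0, -80.0)}
    # same seed: r2 extends r1 with another 10k ions
    r1 = simulate_alignment_run(default_layers(offsets_um=offsets),
                                seed=21, n_ions=10_000)
    r2 = simulate_alignment_run(default_layers(offsets_um=offsets),
                                seed=21, n_ions=20_000)
    return offsets, r1, r2


class TestAlignment:
    def test_zero_offsets_recovered_as_zero(self):
        res = simulate_alignment_run(default_layers(), seed=20, n_ions=4000)
        sol = estimate_alignment(res.frames)
        for dx, dy in sol.offsets_um.values():
            assert abs(dx) < 27.5 and abs(dy) < 27.5

    def test_injected_offsets_recovered_within_half_pixel(self, offset_runs):
        offsets, r1, _ = offset_runs
        sol = estimate_alignment(r1.frames)
        for layer, (tx, ty) in offsets.items():
            dx, dy = sol.offsets_um[layer]
            assert abs(dx - tx) < 27.5
            assert abs(dy - ty) < 27.5
        assert sol.offsets_um[3] == (0.0, 0.0)

    def test_solution_stable_when_statistics_doubled(self, offset_runs):
        _, r1, r2 = offset_runs
        s1 = estimate_alignment(r1.frames)
        s2 = estimate_alignment(r2.frames)
        for layer in s1.offsets_um:
            d1, d2 = s1.offsets_um[layer], s2.offsets_um[layer]
            assert abs(d1[0] - d2[0]) < 10.0
            assert abs(d1[1] - d2[1]) < 10.0

    def test_low_statistics_triggers_precision_warning(self):
        res = simulate_alignment_run(default_layers(), seed=23, n_ions=300)
        with pytest.warns(UserWarning, match="precision"):
            estimate_alignment(res.frames)


class TestTracking:
    def test_single_ion_gives_one_segment_matching_truth_direction(self):
        cfg = RunConfig()
        cfg.beam.mean_ions_per_frame = 1.0
        cfg.artifacts = ArtifactConfig.disabled()
        res = simulate_run(cfg, seed=31, n_ions_total=70)
        layers = {l.index: l for l in cfg.layers}
        checked = 0
        per_frame = res.truth.groupby("frame").size()
        for _, ion in res.truth.iterrows():
            if ion.get("stopped") or np.isnan(ion.get("l2_x", np.nan)):
                continue
            k = int(ion.frame)
            if per_frame[k] != 1:
                continue
            segs = build_segments(find_clusters(res.frames[1][k]),
                                  find_clusters(res.frames[2][k]),
                                  layers[1], layers[2], cfg.cuts)
            if not segs:
                continue
            assert len(segs) == 1
            truth_tx = (ion.l2_x - ion.l1_x) / 10.0
            assert segs[0].tx == pytest.approx(truth_tx, abs=2.5e-3)
            checked += 1
        assert checked >= 20

    def test_empty_layer_yields_no_segments(self):
        layers = {l.index: l for l in default_layers()}
        cl = _cluster_at(0.0, 0.0, 1.3, layers[1])
        assert build_segments([cl], [], layers[1], layers[2],
                              CutConfig()) == []

    def test_two_separated_ions_pair_without_swaps(self):
        layers = {l.index: l for l in default_layers()}
        a1 = _cluster_at(-3.0, 0.0, 1.3, layers[4], tick=100, seed=0)
        a2 = _cluster_at(3.0, 0.0, 1.3, layers[4], tick=100, seed=1)
        b1 = _cluster_at(-3.05, 0.0, 1.3, layers[5], tick=100, seed=2)
        b2 = _cluster_at(2.95, 0.0, 1.3, layers[5], tick=100, seed=3)
        segs = build_segments([a1, a2], [b1, b2], layers[4], layers[5],
                              CutConfig(), tracker="rear")
        assert len(segs) == 2
        xs = sorted(s.extrapolate(layers[4].z_position_mm)[0] for s in segs)
        assert xs[0] == pytest.approx(-3.0, abs=0.1)
        assert xs[1] == pytest.approx(3.0, abs=0.1)

    def test_front_rear_matching_is_species_blind(self):
        f = TrackSegment("front", 0.0, 0.0, -90.0, 0.0, 0.0, 100, 0)
        r = TrackSegment("rear", 0.5, 0.0, 105.0, 0.0, 0.0, 100, 0)
        pairs = match_front_rear([f], [r], CutConfig())
        assert pairs == [(f, r)]

    def test_out_of_window_ticks_do_not_pair(self):
        f = TrackSegment("front", 0.0, 0.0, -90.0, 0.0, 0.0, 100, 0)
        r = TrackSegment("rear", 0.0, 0.0, 105.0, 0.0, 0.0, 103, 0)
        assert match_front_rear([f], [r], CutConfig()) == []


class TestEnergyAssociation:
    def _setup(self, offset_mm):
        layers = {l.index: l for l in default_layers()}
        ecl = Frame(layer=3, index=0, mode="energy")
        ecl.pixels[(128, 128)] = 5000
        (cl,) = find_clusters(ecl)
        apply_pixel_calibration(cl, CalibrationMap.identity())
        px = pixel_to_mm(128)
        rear = TrackSegment("rear", px - offset_mm, px, 105.0, 0.0, 0.0,
                            5000, 0)
        return rear, cl, layers[3]

    def test_cluster_at_extrapolated_point_attached(self):
        rear, cl, l3 = self._setup(0.0)
        ev = associate_energy_cluster((None, rear), [cl], CutConfig(), l3,
                                      AcquisitionSpec())
        assert ev.energy_cluster is cl
        assert ev.accepted

    def test_radius_boundary_exactly_four_pixels(self):
        rear, cl, l3 = self._setup(0.220)
        ev = associate_energy_cluster((None, rear), [cl], CutConfig(), l3,
                                      AcquisitionSpec())
        assert ev.energy_cluster is cl  # 220 um: inside by contract

        rear2, cl2, _ = self._setup(0.221)
        ev2 = associate_energy_cluster((None, rear2), [cl2], CutConfig(), l3,
                                       AcquisitionSpec())
        assert ev2.status == "rejected"
        assert ev2.reason == "no-energy"

    def test_default_radius_is_four_pixel_pitches(self):
        cuts = CutConfig()
        assert cuts.energy_association_radius_um == 4 * 55.0

    def test_arrival_near_frame_boundary_rejected_as_cropped(self):
        layers = {l.index: l for l in default_layers()}
        ecl = Frame(layer=3, index=0, mode="energy")
        ecl.pixels[(128, 128)] = 5000
        (cl,) = find_clusters(ecl)
        apply_pixel_calibration(cl, CalibrationMap.identity())
        px = pixel_to_mm(128)
        rear = TrackSegment("rear", px, px, 105.0, 0.0, 0.0, 5, 0)  # ~0.5 us
        ev = associate_energy_cluster((None, rear), [cl], CutConfig(),
                                      layers[3], AcquisitionSpec())
        assert ev.status == "rejected"
        assert ev.reason == "cropped"


class TestSpeciesID:
    def test_typical_helium_and_hydrogen_examples(self):
        assert classify_species(5.1, 20) == "helium"
        assert classify_species(1.0, 8) == "hydrogen"
        assert classify_species(None, 8) == "unknown"

    def _labelled_set(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        layers = {l.index: l for l in default_layers()}
        recal = make_recal_curve()
        vols, sizes, labels = [], [], []
        for _ in range(n):
            if rng.random() < 0.5:
                dep, lab = rng.normal(5.1, 0.6), "helium"
            else:
                dep, lab = rng.normal(1.35, 0.35), "hydrogen"
            dep = max(dep, 0.25)
            cols, rows, values, _ = make_cluster(
                rng.uniform(-5, 5), rng.uniform(-5, 5), dep, layers[3],
                rng, 1)
            if cols.size == 0:
                continue
            fr = Frame(layer=3, index=0, mode="energy")
            for c, r, v in zip(cols, rows, values):
                fr.pixels[(int(c), int(r))] = int(v)
            (cl,) = find_clusters(fr)
            apply_pixel_calibration(cl, CalibrationMap.identity())
            vols.append(recalibrate_partial_depletion(
                cl.calibrated_energy_mev, recal))
            sizes.append(cl.size)
            labels.append(lab)
        return np.array(vols), np.array(sizes), np.array(labels)

    def test_default_boundary_accuracy_at_least_95pct(self):
        vols, sizes, labels = self._labelled_set()
        pred = default_species_boundary().decide(vols, sizes)
        assert (pred == labels).mean() >= 0.95

    def test_fitted_discriminant_accuracy_on_holdout(self):
        vols, sizes, labels = self._labelled_set(n=900, seed=1)
        half = len(vols) // 2
        b = fit_species_boundary(vols[:half], sizes[:half], labels[:half])
        pred = b.decide(vols[half:], sizes[half:])
        assert (pred == labels[half:]).mean() >= 0.95


class TestFullChain:
    def test_purity_of_accepted_events(self, medium_run, recal_curve):
        cfg, res = medium_run
        events, report = build_events(res.frames, cfg,
                                      recalibration=recal_curve)
        accepted = [e for e in events if e.accepted]
        assert len(accepted) > 200
        for ev in accepted:
            assert ev.species == "helium"
            assert ev.front is not None and ev.rear is not None
            assert ev.energy_cluster is not None
            assert not ev.energy_cluster.flags
        assert 0.0 < report["matched_fraction"] <= 1.0

    def test_run_report_counts_are_consistent(self, medium_run, recal_curve):
        cfg, res = medium_run
        events, report = build_events(res.frames, cfg,
                                      recalibration=recal_curve)
        n_rejected = sum(report["rejects"].values())
        assert report["n_accepted"] + n_rejected == len(events)
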