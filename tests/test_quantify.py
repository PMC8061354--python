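"""Particle detection, region assignment and deposition statistics."""

import numpy as np
import pandas as pd
import pytest

from pulmovox import quantify
from pulmovox.types import (
    ParticleSet,
    RegionLabelMap,
    SegmentationMask,
    VolumeImage,
)

VS = (1.0, 1.0, 1.0)

#: Published per-region deposition fractions (%), labels 1..6.
PRINTED_FRACTIONS = {1: 27.00, 2: 2.50, 3: 47.05, 4: 3.21, 5: 4.70, 6: 15.52}


def _fluor(data):
    return VolumeImage(np.asarray(data, dtype=np.uint8), VS, "fluorescence")


def _particle_set(rows):
    df = pd.DataFrame(rows)
    for col, default in [("region", -1), ("deposition_class", ""), ("is_cluster", False)]:
        if col not in df:
            df[col] = default
    if "voxel_count" not in df:
        df["voxel_count"] = (df["volume_um3"]).astype(int)
    if "id" not in df:
        df["id"] = range(len(df))
    return ParticleSet(df, VS, 1.0)


class TestDetection:
    def test_empty_channel(self):
        ps = quantify.detect_particles(_fluor(np.zeros((10, 10, 10))))
        assert len(ps) == 0
        assert ps.total_volume() == 0.0

    def test_single_block_not_cluster(self):
        data = np.zeros((10, 10, 10))
        data[3:6, 3:6, 3:6] = 200
        ps = quantify.detect_particles(_fluor(data), threshold=50, min_voxels=1,
                                       single_particle_volume=27.0)
        assert len(ps) == 1
        row = ps.particles.iloc[0]
        assert row["voxel_count"] == 27
        assert not row["is_cluster"]
        assert row["z_um"] == pytest.approx(4.5)

    def test_cluster_flagged(self):
        data = np.zeros((10, 10, 12))
        data[3:6, 3:6, 3:9] = 200  # two cube volumes fused
        ps = quantify.detect_particles(_fluor(data), min_voxels=1,
                                       single_particle_volume=27.0)
        assert len(ps) == 1 and bool(ps.particles.iloc[0]["is_cluster"])

    def test_min_voxels_filters(self):
        data = np.zeros((10, 10, 10))
        data[1, 1, 1] = 200
        data[5:7, 5:7, 5:7] = 200
        ps = quantify.detect_particles(_fluor(data), min_voxels=4)
        assert len(ps) == 1

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError, match="threshold"):
            quantify.detect_particles(_fluor(np.zeros((4, 4, 4))), threshold=300)

    def test_threshold_monotonicity(self, small_phantom):
        _, _, fluor, _ = small_phantom
        counts = [
            len(quantify.detect_particles(fluor, threshold=t, min_voxels=1))
            for t in (30, 60, 120, 200, 240)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_noiseless_phantom_component_count_matches_ledger(
        self, small_phantom_noiseless
    ):
        cfg, _, fluor, truth = small_phantom_noiseless
        ps = quantify.detect_particles(fluor, threshold=50, min_voxels=1,
                                       single_particle_volume=cfg.particle_quantum)
        assert len(ps) == truth.particle_component_count
        assert ps.total_volume() == pytest.approx(truth.total_particle_volume())


class TestRegions:
    def _labels(self):
        lab = np.zeros((10, 10, 10), dtype=np.uint8)
        lab[1:5, 1:9, 1:9] = 1
        lab[5:9, 1:9, 1:9] = 3
        return RegionLabelMap(lab, VS)

    def test_centroid_inside_region(self):
        ps = _particle_set([{"z_um": 2.5, "y_um": 5.0, "x_um": 5.0, "volume_um3": 4.0}])
        out = quantify.assign_regions(ps, self._labels())
        assert out.particles.iloc[0]["region"] == 1

    def test_background_centroid_rescued_to_nearest_label(self):
        ps = _particle_set([{"z_um": 0.5, "y_um": 5.0, "x_um": 5.0, "volume_um3": 4.0}])
        out = quantify.assign_regions(ps, self._labels())
        assert out.particles.iloc[0]["region"] == 1

    def test_far_background_stays_unassigned(self):
        lab = np.zeros((30, 30, 30), dtype=np.uint8)
        lab[25:29, 25:29, 25:29] = 2
        ps = _particle_set([{"z_um": 1.0, "y_um": 1.0, "x_um": 1.0, "volume_um3": 4.0}])
        out = quantify.assign_regions(ps, RegionLabelMap(lab, VS))
        assert out.particles.iloc[0]["region"] == -1
        fr = quantify.deposition_fractions(out)
        assert all(v == 0.0 for v in fr.values())


class TestStatistics:
    def test_all_in_one_region(self):
        ps = _particle_set([
            {"z_um": 1, "y_um": 1, "x_um": 1, "volume_um3": 5.0, "region": 3},
            {"z_um": 2, "y_um": 2, "x_um": 2, "volume_um3": 7.0, "region": 3},
        ])
        fr = quantify.deposition_fractions(ps)
        assert fr[3] == pytest.approx(100.0)
        assert sum(fr.values()) == pytest.approx(100.0)

    def test_equal_volumes_split_evenly(self):
        ps = _particle_set([
            {"z_um": 1, "y_um": 1, "x_um": 1, "volume_um3": 3.0, "region": 1},
            {"z_um": 2, "y_um": 2, "x_um": 2, "volume_um3": 3.0, "region": 2},
        ])
        fr = quantify.deposition_fractions(ps)
        assert fr[1] == pytest.approx(50.0) and fr[2] == pytest.approx(50.0)

    def test_fractions_invariant_under_volume_rescale(self):
        rows = [
            {"z_um": 1, "y_um": 1, "x_um": 1, "volume_um3": v, "region": r}
            for v, r in [(2.0, 1), (6.0, 3), (4.0, 5)]
        ]
        fr1 = quantify.deposition_fractions(_particle_set(rows))
        for row in rows:
            row["volume_um3"] *= 17.3
        fr2 = quantify.deposition_fractions(_particle_set(rows))
        for lab in fr1:
            assert fr1[lab] == pytest.approx(fr2[lab])

    def test_right_left_ratio_from_printed_fractions(self):
        """(2.50 + 47.05 + 3.21 + 4.70) / 27.00 rounds to 2.13."""
        ratio = quantify.right_left_ratio(PRINTED_FRACTIONS)
        assert round(ratio, 2) == 2.13

    def test_right_left_ratio_equal_split(self):
        fr = {1: 25.0, 2: 25.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 50.0}
        assert quantify.right_left_ratio(fr) == pytest.approx(1.0)

    def test_right_left_ratio_zero_left_rejected(self):
        with pytest.raises(ValueError, match="left"):
            quantify.right_left_ratio({1: 0.0, 3: 50.0})

    def test_density_scaling_law(self):
        lab = np.zeros((10, 10, 10), dtype=np.uint8)
        lab[0:4] = 1
        lab[4:6] = 2
        lab[6:8] = 3
        labels = RegionLabelMap(lab, VS)
        ps = _particle_set([
            {"z_um": 1, "y_um": 1, "x_um": 1, "volume_um3": 10.0, "region": 1},
            {"z_um": 5, "y_um": 1, "x_um": 1, "volume_um3": 10.0, "region": 2},
        ])
        dens = quantify.particle_density(ps, labels, scale=1.0)
        # lobe 1 has twice the volume of lobe 2: half the density
        assert dens[1] == pytest.approx(dens[2] / 2.0)
        assert dens[3] == 0.0          # lobe present but empty of particles
        assert np.isnan(dens[4])       # lobe absent from the label map

    def test_density_excludes_trachea(self):
        lab = np.ones((4, 4, 4), dtype=np.uint8) * 6
        dens = quantify.particle_density(
            _particle_set([{"z_um": 1, "y_um": 1, "x_um": 1,
                            "volume_um3": 5.0, "region": 6}]),
            RegionLabelMap(lab, VS),
        )
        assert 6 not in dens

    def test_region_volume_conservation(self, small_phantom):
        """Assigned + unassigned volumes add up to the detected total."""
        _, _, fluor, truth = small_phantom
        ps = quantify.detect_particles(fluor, threshold=50, min_voxels=1)
        ps = quantify.assign_regions(ps, truth.region_labels)
        df = ps.particles
        per_region = df[df["region"] > 0]["volume_um3"].sum()
        unassigned = df[df["region"] == -1]["volume_um3"].sum()
        assert per_region + unassigned == pytest.approx(ps.total_volume())


class TestClassification:
    def _mask(self):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[:, 8:12, 8:12] = True
        return SegmentationMask(m, VS)

    def test_centroid_inside_airway(self):
        ps = _particle_set([{"z_um": 5, "y_um": 10, "x_um": 10, "volume_um3": 2.0}])
        out, frac = quantify.classify_deposition(ps, self._mask(), 10.0)
        assert out.particles.iloc[0]["deposition_class"] == "airway"
        assert frac == 0.0

    def test_far_particle_is_acinar(self):
        ps = _particle_set([{"z_um": 5, "y_um": 1.0, "x_um": 1.0, "volume_um3": 2.0}])
        out, frac = quantify.classify_deposition(ps, self._mask(), 3.0)
        assert out.particles.iloc[0]["deposition_class"] == "acinar"
        assert frac == pytest.approx(100.0)

    def test_zero_surface_distance_boundary(self):
        ps = _particle_set([{"z_um": 5, "y_um": 13.5, "x_um": 10, "volume_um3": 2.0}])
        out, _ = quantify.classify_deposition(ps, self._mask(), 0.0)
        assert out.particles.iloc[0]["deposition_class"] == "acinar"

    def test_phantom_acinar_fraction_recovery(self, small_phantom):
        cfg, _, fluor, truth = small_phantom
        ps = quantify.detect_particles(fluor, threshold=50, min_voxels=1)
        _, frac = quantify.classify_deposition(ps, truth.airway_mask,
                                               surface_distance=5.0)
        ledger = 100.0 * truth.acinar_particle_volume / truth.total_particle_volume()
        assert frac == pytest.approx(ledger, abs=1.5)


class TestClusterStats:
    def test_equivalent_diameter_of_small_cube(self):
        # a 1.2 µm cube has equivalent spherical diameter ~1.49 µm
        d = quantify.equivalent_diameter(np.array([1.2**3]))
        assert d[0] == pytest.approx(1.489, abs=0.01)
        ps = _particle_set([{"z_um": 1, "y_um": 1, "x_um": 1, "volume_um3": 1.2**3}])
        hist = quantify.cluster_size_stats(ps, bin_edges=(0, 5, 10, 20))
        assert hist["counts"] == [1, 0, 0]

    def test_empty_set(self):
        hist = quantify.cluster_size_stats(ParticleSet.empty(VS))
        assert sum(hist["counts"]) == 0
        assert hist["under_20um_pct"] == 0.0

    def test_all_small_clusters_under_20(self, small_phantom):
        _, _, fluor, _ = small_phantom
        ps = quantify.detect_particles(fluor, threshold=50, min_voxels=1)
        hist = quantify.cluster_size_stats(ps)
        assert hist["under_20um_pct"] == pytest.approx(100.0)


class TestRoundTrip:
    def test_noiseless_phantom_report_matches_ledger(self, small_phantom_noiseless):
        cfg, _, fluor, truth = small_phantom_noiseless
        ps = quantify.detect_particles(fluor, threshold=50, min_voxels=1,
                                       single_particle_volume=cfg.particle_quantum)
        report = quantify.deposition_report(
            ps,
            truth.region_labels,
            airway_mask=truth.airway_mask,
            surface_distance=5.0,
            density_scale=truth.density_scale,
        )
        truth_fr = truth.region_fractions_pct()
        quantum_pct = 100.0 * cfg.particle_quantum / truth.total_particle_volume()
        for lab in range(1, 7):
            assert report.fraction_pct[lab] == pytest.approx(
                truth_fr[lab], abs=quantum_pct + 1e-9
            )
        ledger_acinar = 100.0 * truth.acinar_particle_volume / truth.total_particle_volume()
        assert report.acinar_fraction_pct == pytest.approx(ledger_acinar, abs=quantum_pct)
        assert report.n_unassigned == 0
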