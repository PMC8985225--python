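"""Measurement conventions and distance-threshold classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camkii_ensemble import (BETA_LIKE, HoloenzymeParticle,
                             classify_compact, classify_dimers,
                             classify_stoichiometry, detect_clusters,
                             kinase_radius, linker_extension,
                             local_concentration, measure_particles,
                             neighbor_separation, simulate_ensemble,
                             stoichiometry_census)


def ring_particle(n_kinase, center_radius, hub_center=(0.0, 0.0), order=6,
                  phase=0.0):
    """Kinases equally spaced on a circle; hub ring at 5.5 nm."""
    hub = np.asarray(hub_center, dtype=float)
    ka = phase + 2 * np.pi * np.arange(n_kinase) / n_kinase
    va = 2 * np.pi * np.arange(order) / order
    return HoloenzymeParticle(
        hub_center=hub, symmetry_order=order,
        hub_vertices=hub + 5.5 * np.column_stack([np.cos(va), np.sin(va)]),
        kinase_centers=hub + center_radius * np.column_stack(
            [np.cos(ka), np.sin(ka)]),
        subunit_labels=["extended"] * n_kinase)


class TestKinaseRadius:
    def test_append_convention(self):
        p = ring_particle(1, 10.35)
        p.kinase_centers = np.array([[10.35, 0.0]])
        assert kinase_radius(p)[0] == pytest.approx(12.6)

    def test_kinase_at_hub_center(self):
        p = ring_particle(1, 0.0)
        assert kinase_radius(p)[0] == pytest.approx(2.25)

    def test_translation_rotation_invariance(self):
        base = ring_particle(12, 12.0)
        radii0 = kinase_radius(base)
        seps0 = neighbor_separation(base)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        shift = np.array([123.4, -56.7])
        moved = HoloenzymeParticle(
            hub_center=base.hub_center @ rot.T + shift,
            symmetry_order=6,
            hub_vertices=base.hub_vertices @ rot.T + shift,
            kinase_centers=base.kinase_centers @ rot.T + shift,
            subunit_labels=base.subunit_labels)
        assert np.allclose(kinase_radius(moved), radii0, atol=1e-9)
        assert np.allclose(np.sort(neighbor_separation(moved)),
                           np.sort(seps0), atol=1e-9)


class TestLinkerExtension:
    @pytest.mark.parametrize("radius,expected", [
        (16.8, 6.8),   # beta mean radius -> beta linker extension
        (10.0, 0.0),   # the compact cut-off is exactly zero extension
        (12.6, 2.6),   # alpha mean radius (arithmetic value)
    ])
    def test_subtract_convention(self, radius, expected):
        assert linker_extension(radius) == pytest.approx(expected)

    def test_negative_reported_as_is(self):
        assert linker_extension(5.0) == pytest.approx(-5.0)

    def test_append_subtract_identity(self, beta_noiseless_ensemble):
        """extension(radius(p)) == raw center distance - 5.5 - 2.25."""
        for p in list(beta_noiseless_ensemble)[:50]:
            raw = np.linalg.norm(p.kinase_centers - p.hub_center, axis=1)
            ext = linker_extension(kinase_radius(p))
            assert np.allclose(ext, raw - 5.5 - 2.25, atol=1e-12)


class TestNeighborSeparation:
    def test_equally_spaced_ring_chord(self):
        """12 kinases on a 10.35 nm circle: chord 2 r sin(pi/12)."""
        p = ring_particle(12, 10.35)
        expected = 2 * 10.35 * np.sin(np.pi / 12)
        assert np.allclose(neighbor_separation(p), expected, atol=1e-9)

    def test_coincident_pair(self):
        p = ring_particle(2, 5.0)
        p.kinase_centers = np.array([[5.0, 0.0], [5.0, 0.0]])
        assert np.allclose(neighbor_separation(p), 0.0)

    def test_fewer_than_two_rejected(self):
        p = ring_particle(1, 5.0)
        with pytest.raises(ValueError):
            neighbor_separation(p)

    def test_each_subunit_contributes_once(self):
        p = ring_particle(7, 9.0, phase=0.3)
        assert neighbor_separation(p).shape == (7,)


class TestCompact:
    def test_small_example(self):
        frac, flags = classify_compact([9.0, 11.0, 12.0])
        assert frac == pytest.approx(1 / 3)
        assert list(flags) == [True, False, False]

    def test_all_extended(self):
        frac, _ = classify_compact([10.0, 12.0, 15.0])
        assert frac == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_compact([])

    def test_labelled_fraction_recovered(self):
        """3% labelled compacts recovered within binomial 3-sigma at the
        headline per-subunit sample size (n = 1020)."""
        cfg = BETA_LIKE.with_(radius_sd=1.6, compact_fraction=0.03,
                              dimer_fraction=0.0,
                              stoichiometry_mix={12: 1.0})
        pset = simulate_ensemble(cfg, 85, seed=17)   # 1020 subunits
        radii = np.concatenate([kinase_radius(p) for p in pset])
        frac, _ = classify_compact(radii)
        sigma = np.sqrt(0.03 * 0.97 / radii.size)
        assert abs(frac - 0.03) < 3 * sigma


class TestDimers:
    def test_small_example(self):
        fr, _ = classify_dimers([4.0, 4.4, 5.9], cutoffs=(4.5,))
        assert fr[4.5] == pytest.approx(2 / 3)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=20.0),
                    min_size=1, max_size=100))
    def test_nesting_property(self, seps):
        fr, fl = classify_dimers(seps)
        assert fr[4.5] <= fr[5.0] <= fr[6.0]
        assert np.all(fl[4.5] <= fl[5.0]) and np.all(fl[5.0] <= fl[6.0])

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            classify_dimers([])
        with pytest.raises(ValueError):
            classify_dimers([1.0], cutoffs=(0.0,))

    def test_pair_level_label_recovery(self):
        """Ground-truth dimer pairs land below the 6 nm cut-off (>=95%)
        at pixel-scale noise."""
        cfg = BETA_LIKE.with_(dimer_fraction=0.15)
        pset = simulate_ensemble(cfg, 400, seed=21)
        pair_d = []
        for p in pset:
            for i in range(0, p.n_subunits, 2):
                if p.subunit_labels[i] == "dimer":
                    pair_d.append(np.linalg.norm(
                        p.kinase_centers[i] - p.kinase_centers[i + 1]))
        fr, _ = classify_dimers(np.array(pair_d))
        assert fr[6.0] >= 0.95


class TestStoichiometry:
    @pytest.mark.parametrize("order", [6, 7, 8])
    def test_noiseless_ring_called_exactly(self, order, pure_config):
        pset = simulate_ensemble(pure_config(2 * order), 100, seed=order)
        census = stoichiometry_census(pset)
        assert census["percent"][order] == 100.0

    def test_sevenfold_with_noise_monte_carlo(self, pure_config):
        """7-fold rings at 0.4 nm coordinate noise: correct call rate
        at least 98.5% (rate measured at 99.0% over 1000 trials)."""
        cfg = pure_config(14, noise_sd=0.4)
        pset = simulate_ensemble(cfg, 1000, seed=3)
        calls = [classify_stoichiometry(p.hub_vertices)[0] for p in pset]
        assert sum(c == 7 for c in calls) >= 985

    def test_scrambled_ring_rejected(self, rng):
        """Vertices at random angles carry no dominant harmonic."""
        n_called = 0
        for _ in range(200):
            ang = rng.uniform(0, 2 * np.pi, 6)
            verts = 5.5 * np.column_stack([np.cos(ang), np.sin(ang)])
            call, _ = classify_stoichiometry(verts)
            n_called += call != "ambiguous"
        assert n_called / 200 < 0.10

    def test_degenerate_vertices_rejected(self):
        with pytest.raises(ValueError):
            classify_stoichiometry(np.zeros((6, 2)))
        with pytest.raises(ValueError):
            classify_stoichiometry(np.zeros((3, 2)))


class TestClusters:
    def test_pair_within_threshold(self):
        centers = np.array([[0.0, 0.0], [20.0, 0.0]])
        frac, _, flags = detect_clusters(centers, diameter_nm=25.2)
        assert frac == 1.0 and flags.all()   # 20 < 1.5 * 25.2

    def test_single_holoenzyme(self):
        frac, _, _ = detect_clusters(np.array([[0.0, 0.0]]),
                                     diameter_nm=25.0)
        assert frac == 0.0

    def test_transitive_closure(self):
        # chain a-b-c: a-c far apart but same component through b
        centers = np.array([[0.0, 0.0], [30.0, 0.0], [60.0, 0.0]])
        frac, labels, flags = detect_clusters(centers, diameter_nm=25.0)
        assert frac == 1.0
        assert labels[0] == labels[1] == labels[2]

    def test_matches_brute_force_oracle(self, rng):
        """KD-tree + connected components vs all-pairs union-find."""
        for _ in range(20):
            n = int(rng.integers(2, 200))
            centers = rng.uniform(0, 500, (n, 2))
            diameter = float(rng.uniform(5, 40))
            frac, labels, flags = detect_clusters(centers, diameter)
            # brute force
            thr = 1.5 * diameter
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if np.linalg.norm(centers[i] - centers[j]) < thr:
                        parent[find(i)] = find(j)
            roots = [find(i) for i in range(n)]
            sizes = {r: roots.count(r) for r in set(roots)}
            brute_flags = np.array([sizes[r] > 1 for r in roots])
            assert np.array_equal(flags, brute_flags)
            assert frac == pytest.approx(brute_flags.mean())


class TestLocalConcentration:
    def test_beta_radius_one_millimolar(self):
        assert local_concentration(12, 16.8) == pytest.approx(1.0, abs=0.05)

    def test_alpha_radius(self):
        assert local_concentration(12, 12.6) == pytest.approx(2.38,
                                                              abs=0.005)

    def test_cubic_scaling(self):
        c1 = local_concentration(12, 10.0)
        c2 = local_concentration(12, 20.0)
        assert c1 / c2 == pytest.approx(8.0, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            local_concentration(12, 0.0)
        with pytest.raises(ValueError):
            local_concentration(0, 10.0)


class TestMeasurementTable:
    def test_columns_and_flags_consistent(self, beta_measurements):
        t = beta_measurements
        assert {"kinase_radius_nm", "linker_extension_nm",
                "neighbor_separation_nm", "compact_flag",
                "dimer_flag_4_5", "symmetry_call"} <= set(t.columns)
        assert (t["compact_flag"] == (t["kinase_radius_nm"] < 10)).all()
        assert ((t["linker_extension_nm"]
                 - (t["kinase_radius_nm"] - 10.0)).abs() < 1e-9).all()
        # nesting of dimer flags holds row-wise
        assert (t["dimer_flag_4_5"] <= t["dimer_flag_5_0"]).all()
        assert (t["dimer_flag_5_0"] <= t["dimer_flag_6_0"]).all()
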