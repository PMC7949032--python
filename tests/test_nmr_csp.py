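"""Combined-shift arithmetic, peak tracking, residue mapping, and Kd fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import khbind
from khbind.nmr_csp import (
    CSPProfile,
    PeakList,
    TitrationSeries,
    bound_fraction,
    classify_binding_residues,
    combined_shift,
    csp_profile,
    fit_kd,
    load_titration_series,
    track_peaks,
    write_peak_list,
)

finite = st.floats(min_value=-5, max_value=5, allow_nan=False)


class TestCombinedShift:
    @pytest.mark.parametrize(
        "dh,dn,expected",
        [(0.0, 0.0, 0.0), (0.1, 0.5, 0.1), (0.1, 0.0, 0.1 / np.sqrt(2))],
    )
    def test_closed_form_values(self, dh, dn, expected):
        assert combined_shift(dh, dn) == pytest.approx(expected, abs=1e-12)

    @given(finite, finite, st.floats(min_value=0.01, max_value=10))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_sign_invariant_homogeneous(self, dh, dn, c):
        v = combined_shift(dh, dn)
        assert v >= 0
        assert combined_shift(-dh, dn) == pytest.approx(v, rel=1e-12, abs=1e-15)
        assert combined_shift(dh, -dn) == pytest.approx(v, rel=1e-12, abs=1e-15)
        assert combined_shift(c * dh, c * dn) == pytest.approx(c * v, rel=1e-9, abs=1e-12)


class TestIsotherm:
    @given(
        st.floats(min_value=1e-4, max_value=10),  # P
        st.floats(min_value=0, max_value=50),  # L
        st.floats(min_value=1e-3, max_value=100),  # Kd
    )
    @settings(max_examples=200, deadline=None)
    def test_bound_fraction_in_unit_interval(self, P, L, kd):
        fb = bound_fraction(P, L, kd)
        assert 0.0 <= fb <= 1.0

    def test_quadratic_reduces_to_hyperbola_in_dilute_limit(self):
        kd = 1.5
        L = np.array([0.1, 0.5, 1.5, 5.0, 20.0])
        quad = bound_fraction(1e-6 * kd, L, kd)
        hyp = L / (L + kd)
        assert np.allclose(quad, hyp, rtol=1e-6)


def _series(kd=1.5, noise=0.0, seed=0, **kw):
    return khbind.gen_titration(
        khbind.TitrationSimConfig(true_kd=kd, noise_sd=noise, seed=seed, **kw)
    )


class TestTrackPeaks:
    def test_single_drifting_residue_tracked(self):
        points = [
            PeakList(entries={"10": (8.0 + 0.01 * i, 120.0)}, ligand_total=0.1 * i, protein_total=0.2)
            for i in range(6)
        ]
        traj = track_peaks(TitrationSeries(points=points, protein_total=0.2))
        assert traj.residues == ["10"]
        assert traj.delta_H.shape == (1, 6)
        assert np.allclose(traj.delta_H[0], 0.01 * np.arange(6))

    def test_unassigned_points_matched_by_nearest_neighbor(self):
        ref = PeakList(entries={"A": (8.0, 110.0), "B": (9.0, 125.0)}, ligand_total=0, protein_total=0.2)
        moved = PeakList(
            entries={}, unassigned=[(9.02, 125.1), (8.02, 110.1)], ligand_total=0.5, protein_total=0.2
        )
        traj = track_peaks(TitrationSeries(points=[ref, moved], protein_total=0.2))
        i_a = traj.residues.index("A")
        assert traj.delta_H[i_a, 1] == pytest.approx(0.02)
        assert not traj.ambiguous

    def test_crossing_trajectories_flagged_ambiguous(self):
        ref = PeakList(entries={"A": (8.00, 110.0), "B": (8.02, 110.1)}, ligand_total=0, protein_total=0.2)
        swapped = PeakList(
            entries={}, unassigned=[(8.02, 110.1), (8.00, 110.0)], ligand_total=0.5, protein_total=0.2
        )
        traj = track_peaks(TitrationSeries(points=[ref, swapped], protein_total=0.2))
        assert {"A", "B"} <= traj.ambiguous

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            PeakList(entries={1: (8, 110), "1": (8.1, 111)}, ligand_total=0, protein_total=0.2)


class TestCSPProfileAndClassification:
    def test_endpoint_equals_reference_gives_zeros(self):
        series = _series(noise=0.0)
        prof = csp_profile(series, endpoint_index=0)
        assert all(v == 0 for v in prof.values.values())

    def test_largest_planted_shift_dominates_profile(self):
        shifts = {"81": (0.30, 1.50), "40": (0.05, 0.25), "60": (0.02, 0.10)}
        series = _series(per_residue_max_shifts=shifts)
        prof = csp_profile(series)
        assert max(prof.values, key=prof.values.get) == "81"

    def test_residue_missing_at_endpoint_omitted_with_count(self):
        series = _series()
        del series.points[-1].entries["87"]
        with pytest.warns(UserWarning, match="missing at endpoint"):
            prof = csp_profile(series)
        assert "87" not in prof.values and prof.n_omitted == 1

    def test_outlier_in_tier2_uniform_profile_empty(self):
        baseline = {str(i): 0.01 + 0.001 * (i % 3) for i in range(1, 11)}
        prof = CSPProfile(values={**baseline, "4": 0.3})
        tiers = classify_binding_residues(prof)
        assert "4" in tiers["tier2"]
        uniform = CSPProfile(values={str(i): 0.05 for i in range(10)})
        tiers_u = classify_binding_residues(uniform)
        assert tiers_u["tier1"] == set() and tiers_u["tier2"] == set()

    def test_planted_loop_cluster_recovered(self):
        base = {str(i): (0.01, 0.05) for i in range(60, 100)}
        for r in ("84", "85", "86", "87"):
            base[r] = (0.20, 1.00)
        series = _series(per_residue_max_shifts=base)
        tiers = classify_binding_residues(csp_profile(series))
        assert {"84", "85", "86", "87"} <= tiers["tier2"]


class TestFitKd:
    def test_noiseless_exact_recovery(self):
        series = _series(kd=1.5, noise=0.0)
        fit = fit_kd(track_peaks(series).as_dict(), series.protein_total)
        assert fit.converged
        assert fit.kd == pytest.approx(1.5, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-15)

    def test_dilute_limit_half_saturation_at_kd(self):
        kd = 0.5
        P = 1e-6
        L = np.array([0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0])
        dd = 0.2 * bound_fraction(P, L, kd)
        fit = fit_kd({"84": (L, dd)}, P)
        assert fit.predict("84", kd, P) == pytest.approx(fit.ddmax["84"] / 2, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        series = _series(kd=0.078, noise=0.02 * 0.12, seed=42)
        fit = fit_kd(track_peaks(series).as_dict(), series.protein_total)
        assert abs(fit.kd - 0.078) / 0.078 < 0.10

    def test_shared_kd_not_worse_than_shared_ddmax(self):
        """Sharing Kd across residues with one true Kd beats forcing one ddmax."""
        series = _series(kd=0.2, noise=0.004, seed=3)
        traj = track_peaks(series).as_dict()
        shared = fit_kd(traj, series.protein_total)
        # force a single ddmax by pooling all residues into one trajectory
        L = np.concatenate([v[0] for v in traj.values()])
        dd = np.concatenate([v[1] for v in traj.values()])
        pooled = fit_kd({"pooled": (L, dd)}, series.protein_total)
        assert shared.rss <= pooled.rss + 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_kd({"84": (np.array([0.0, 0.1]), np.array([0.0, 0.05]))}, 0.2)

    def test_low_saturation_warns(self):
        L = np.array([0.0, 0.001, 0.002, 0.004, 0.008])
        dd = 0.5 * bound_fraction(0.2, L, 10.0)  # far below Kd everywhere
        with pytest.warns(UserWarning, match="poorly constrained"):
            fit_kd({"84": (L, dd)}, 0.2)

    def test_coverage_of_kd_confidence_intervals(self):
        """+-2 SE intervals cover the true Kd in >= 80% of noisy titrations."""
        hits = 0
        n = 40
        for s in range(n):
            series = _series(kd=0.2, noise=0.02 * 0.12, seed=100 + s)
            fit = fit_kd(track_peaks(series).as_dict(), series.protein_total)
            if abs(fit.kd - 0.2) <= 2 * fit.kd_se:
                hits += 1
        assert hits / n >= 0.80


class TestPeakListIO:
    def test_roundtrip(self, tmp_path):
        series = _series(noise=0.01, seed=6)
        paths = []
        for i, point in enumerate(series.points):
            p = tmp_path / f"point{i:02d}.tsv"
            write_peak_list(point, p)
            paths.append(p)
        loaded = load_titration_series(paths)
        assert loaded.protein_total == series.protein_total
        for a, b in zip(loaded.points, series.points):
            assert a.ligand_total == b.ligand_total
            for r in b.entries:
                assert a.entries[r] == pytest.approx(b.entries[r])
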