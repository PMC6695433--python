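"""Chromatogram I/O, TIC, peak picking, identification and normalization."""

from __future__ import annotations

import logging
import math

import numpy as np
import pytest

import terpscreen as ts
from terpscreen.chromatography import (ChromatogramParseError, EmptyRunError,
                                       InsufficientDataError, TICTrace,
                                       _valley_bounds)

from conftest import gaussian_tic_chromatogram

RNG = np.random.default_rng(42)


def small_chromatogram():
    scans = [
        (1.00, {93.0: 100.0, 136.0: 50.0}),
        (1.01, {93.0: 80.0}),
        (1.02, {68.0: 10.0, 93.0: 20.0}),
    ]
    return ts.Chromatogram("W1", scans)


class TestReadChromatogram:
    def test_mzxml_round_trip_preserves_scans(self, tmp_path):
        chrom = small_chromatogram()
        path = tmp_path / "w1.mzXML"
        ts.write_mzxml(chrom, path)
        parsed = ts.read_mzxml(path)
        assert len(parsed.scans) == 3
        times = [t for t, _ in parsed.scans]
        assert times == sorted(times)
        for (t0, s0), (t1, s1) in zip(chrom.scans, parsed.scans):
            assert t1 == pytest.approx(t0, abs=1e-6)
            assert s1 == pytest.approx(s0)

    def test_tsv_dialect_equals_mzxml_parse(self, tmp_path):
        # both dialects written from one in-memory fixture must parse equal
        chrom = small_chromatogram()
        ts.write_mzxml(chrom, tmp_path / "w1.mzXML")
        ts.write_tsv(chrom, tmp_path / "w1.tsv")
        a = ts.read_mzxml(tmp_path / "w1.mzXML")
        b = ts.read_mzxml(tmp_path / "w1.tsv")
        assert len(a.scans) == len(b.scans)
        for (ta, sa), (tb, sb) in zip(a.scans, b.scans):
            assert tb == pytest.approx(ta, abs=1e-6)
            assert sb == pytest.approx(sa)

    def test_empty_scan_survives_tsv_round_trip(self, tmp_path):
        chrom = ts.Chromatogram("W1", [(1.00, {93.0: 5.0}), (1.01, {})])
        ts.write_tsv(chrom, tmp_path / "w.tsv")
        parsed = ts.read_mzxml(tmp_path / "w.tsv")
        assert len(parsed.scans) == 2
        assert parsed.scans[1][1] == {}

    def test_out_of_order_scans_resorted_with_warning(self, tmp_path, caplog):
        path = tmp_path / "w.tsv"
        path.write_text("scan_time_min\tmz\tintensity\n"
                        "1.02\t93.0\t10\n1.00\t93.0\t20\n1.01\t93.0\t30\n")
        with caplog.at_level(logging.WARNING):
            parsed = ts.read_mzxml(path)
        times = [t for t, _ in parsed.scans]
        assert times == sorted(times)
        assert any("re-sorting" in r.message for r in caplog.records)

    def test_zero_scans_is_empty_run_error(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("scan_time_min\tmz\tintensity\n")
        with pytest.raises(EmptyRunError):
            ts.read_mzxml(path)

    def test_malformed_row_names_position(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("scan_time_min\tmz\tintensity\n1.0\t93.0\tnot_a_number\n")
        with pytest.raises(ChromatogramParseError, match="row 1"):
            ts.read_mzxml(path)


class TestTIC:
    def test_tic_sums_each_scan(self):
        tic = ts.total_ion_chromatogram(small_chromatogram())
        assert tic.intensities.tolist() == [150.0, 80.0, 30.0]

    def test_empty_spectra_yield_zero(self):
        chrom = ts.Chromatogram("W1", [(1.0, {}), (1.1, {})])
        tic = ts.total_ion_chromatogram(chrom)
        assert tic.intensities.tolist() == [0.0, 0.0]

    def test_matches_brute_force_sum_on_random_spectra(self):
        scans = []
        t = 0.0
        for _ in range(50):
            t += 0.01
            n = int(RNG.integers(0, 8))
            spec = {float(m): float(v) for m, v in
                    zip(RNG.uniform(35, 500, n), RNG.uniform(0, 1e4, n))}
            scans.append((t, spec))
        chrom = ts.Chromatogram("W1", scans)
        tic = ts.total_ion_chromatogram(chrom)
        for (t0, spec), (t1, v) in zip(scans, tic):
            expected = 0.0
            for intensity in spec.values():
                expected += intensity
            assert v == pytest.approx(expected)

    def test_invariant_under_mz_permutation(self):
        spec = {93.0: 10.0, 136.0: 5.0, 68.0: 2.0}
        permuted = dict(reversed(list(spec.items())))
        c1 = ts.Chromatogram("W1", [(1.0, spec), (1.1, {})])
        c2 = ts.Chromatogram("W1", [(1.0, permuted), (1.1, {})])
        assert (ts.total_ion_chromatogram(c1).intensities
                == ts.total_ion_chromatogram(c2).intensities).all()


class TestPickPeaks:
    def test_single_gaussian_apex_location(self):
        chrom = gaussian_tic_chromatogram([(2.10, 5000.0)])
        peaks = ts.pick_peaks(ts.total_ion_chromatogram(chrom))
        assert len(peaks) == 1
        assert abs(peaks[0].apex_rt - 2.10) <= 1.0 / 300.0
        assert peaks[0].left_rt < peaks[0].apex_rt < peaks[0].right_rt

    def test_flat_signal_gives_no_peaks(self):
        tic = TICTrace(np.linspace(0, 1, 100), np.zeros(100))
        assert ts.pick_peaks(tic) == []

    def test_two_gaussians_split_at_brute_force_valley(self):
        # separation > 4 sigma: the boundary between the peaks must sit at
        # the true minimum of the sampled signal between the two apexes
        sigma = 0.008
        chrom = gaussian_tic_chromatogram([(2.10, 5000.0), (2.10 + 6 * sigma, 4000.0)],
                                          sigma=sigma)
        tic = ts.total_ion_chromatogram(chrom)
        peaks = ts.pick_peaks(tic)
        assert len(peaks) == 2
        i0 = int(np.argmin(np.abs(tic.times - peaks[0].apex_rt)))
        i1 = int(np.argmin(np.abs(tic.times - peaks[1].apex_rt)))
        valley = i0 + int(np.argmin(tic.intensities[i0:i1 + 1]))
        assert peaks[0].right_rt == pytest.approx(tic.times[valley])
        assert peaks[1].left_rt == pytest.approx(tic.times[valley])

    def test_fewer_than_three_scans_rejected(self):
        tic = TICTrace(np.array([1.0, 1.1]), np.array([0.0, 1.0]))
        with pytest.raises(InsufficientDataError):
            ts.pick_peaks(tic)

    def test_valley_bounds_reach_local_minima(self):
        x = np.array([0.0, 1, 5, 2, 1, 3, 1, 0])
        assert _valley_bounds(x, 2) == (0, 4)
        assert _valley_bounds(x, 5) == (4, 7)


def _refs():
    return [
        ts.CompoundReference("a-pinene", 2.10, 93.0, qualifier_ions=(136.0,)),
        ts.CompoundReference("limonene", 2.85, 68.0, qualifier_ions=(93.0,)),
        ts.CompoundReference("geraniol", 1.40, 69.0, solvent_masked=True),
        ts.CompoundReference("IS", 3.30, 105.0, is_internal_standard=True),
    ]


def _chrom_with_peaks(rt_area_ion, sigma=0.008):
    """Gaussian peaks each carrying its own primary ion (plus weak 136)."""
    dt = 1.0 / 300.0
    n = 1380
    times = (np.arange(n) + 1) * dt
    specs = [dict() for _ in range(n)]
    for rt, area, ion in rt_area_ion:
        counts = area * np.exp(-0.5 * ((times - rt) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        for i, c in enumerate(counts):
            if c > 1e-6:
                specs[i][ion] = specs[i].get(ion, 0.0) + 0.7 * c
                specs[i][136.0] = specs[i].get(136.0, 0.0) + 0.3 * c
    return ts.Chromatogram("W1", list(zip(times.tolist(), specs)))


class TestIdentifyPeaks:
    def test_peak_at_expected_rt_with_dominant_primary_assigned(self):
        chrom = _chrom_with_peaks([(2.10, 5000, 93.0), (3.30, 10000, 105.0)])
        tic = ts.total_ion_chromatogram(chrom)
        peaks = ts.identify_peaks(ts.pick_peaks(tic), chrom, _refs())
        assigned = {p.assigned_compound for p in peaks}
        assert assigned == {"a-pinene", "IS"}

    def test_peak_outside_every_window_unassigned(self):
        chrom = _chrom_with_peaks([(2.30, 5000, 93.0)])  # 4x tolerance from a-pinene
        tic = ts.total_ion_chromatogram(chrom)
        peaks = ts.identify_peaks(ts.pick_peaks(tic), chrom, _refs())
        assert all(p.assigned_compound is None for p in peaks)

    def test_nearer_of_two_in_window_peaks_wins(self):
        refs = [ts.CompoundReference("x", 2.10, 93.0, rt_tolerance=0.08)]
        chrom = _chrom_with_peaks([(2.08, 5000, 93.0), (2.15, 5000, 93.0)])
        tic = ts.total_ion_chromatogram(chrom)
        picked = ts.pick_peaks(tic)
        assert len(picked) == 2
        out = ts.identify_peaks(picked, chrom, refs)
        # oracle: enumerate both placements, smallest |RT difference| wins
        dists = [abs(p.apex_rt - 2.10) for p in picked]
        winner = int(np.argmin(dists))
        assert out[winner].assigned_compound == "x"
        assert out[1 - winner].assigned_compound is None

    def test_solvent_masked_never_assigned(self):
        chrom = _chrom_with_peaks([(1.40, 5000, 69.0)])
        tic = ts.total_ion_chromatogram(chrom)
        out = ts.identify_peaks(ts.pick_peaks(tic), chrom, _refs())
        assert all(p.assigned_compound is None for p in out)

    def test_wrong_dominant_ion_blocks_assignment(self):
        # peak at a-pinene's RT but all signal on the qualifier ion
        chrom = _chrom_with_peaks([(2.10, 5000, 136.0)])
        tic = ts.total_ion_chromatogram(chrom)
        out = ts.identify_peaks(ts.pick_peaks(tic), chrom, _refs())
        assert all(p.assigned_compound is None for p in out)

    def test_assignment_is_partial_matching(self):
        chrom = _chrom_with_peaks([(2.10, 5000, 93.0), (2.12, 4000, 93.0),
                                   (2.85, 3000, 68.0), (3.30, 10000, 105.0)])
        tic = ts.total_ion_chromatogram(chrom)
        out = ts.identify_peaks(ts.pick_peaks(tic), chrom, _refs())
        assigned = [p.assigned_compound for p in out if p.assigned_compound]
        assert len(assigned) == len(set(assigned))  # injective both ways


class TestNormalizeWell:
    def test_ratio_against_internal_standard(self):
        peaks = [
            ts.Peak(2.10, 2.05, 2.15, 1.0, 500.0, 10, "a-pinene"),
            ts.Peak(3.30, 3.25, 3.35, 1.0, 1000.0, 20, "IS"),
        ]
        res = ts.normalize_well(peaks, _refs(), "W1")
        assert not res.failed
        assert res.normalized_area["a-pinene"] == pytest.approx(0.5)
        assert "is_missing" in res.flags["limonene"]
        assert "is_masked" in res.flags["geraniol"]

    def test_triangular_peak_area_matches_analytic(self):
        # height h over base width w integrates to h*w/2; trapezoid on a
        # piecewise-linear signal is exact up to discretization of the apex
        h, w = 6000.0, 0.05
        dt = 1.0 / 300.0
        times = (np.arange(200) + 1) * dt
        apex_t = times[100]
        tic_vals = np.maximum(0.0, h * (1 - np.abs(times - apex_t) / (w / 2)))
        chrom = ts.Chromatogram("W1", [(float(t), {93.0: float(v)} if v > 0 else {})
                                       for t, v in zip(times, tic_vals)])
        peaks = ts.pick_peaks(ts.total_ion_chromatogram(chrom), min_prominence=100)
        assert len(peaks) == 1
        assert peaks[0].area == pytest.approx(h * w / 2, rel=0.01)

    def test_missing_internal_standard_fails_well(self):
        peaks = [ts.Peak(2.10, 2.05, 2.15, 1.0, 500.0, 10, "a-pinene")]
        res = ts.normalize_well(peaks, _refs(), "W1")
        assert res.failed
        assert res.normalized_area == {}

    def test_invariant_under_uniform_intensity_scaling(self):
        chrom = _chrom_with_peaks([(2.10, 5000, 93.0), (3.30, 10000, 105.0)])
        scaled = ts.Chromatogram("W1", [
            (t, {m: 3.7 * v for m, v in spec.items()}) for t, spec in chrom.scans])
        r1 = ts.process_well(chrom, _refs())
        r2 = ts.process_well(scaled, _refs())
        for c in r1.normalized_area:
            assert r2.normalized_area[c] == pytest.approx(r1.normalized_area[c], rel=1e-9)


class TestThresholds:
    def _well(self, wid, areas):
        w = ts.WellResult(wid, "solvent_control")
        w.normalized_area.update(areas)
        return w

    def test_mean_of_solvent_wells(self):
        wells = [self._well("S1", {"a-pinene": 0.01}), self._well("S2", {"a-pinene": 0.03})]
        thr = ts.compute_thresholds(wells, ["a-pinene"])
        assert thr["a-pinene"] == pytest.approx(0.02)

    def test_all_zero_background_gives_zero_thresholds(self):
        wells = [self._well("S1", {"a-pinene": 0.0}), self._well("S2", {"a-pinene": 0.0})]
        assert ts.compute_thresholds(wells, ["a-pinene"])["a-pinene"] == 0.0

    def test_simulated_wells_match_independent_mean(self):
        draws = RNG.uniform(0, 0.05, size=(8, 2))
        wells = [self._well(f"S{i}", {"a": d[0], "b": d[1]}) for i, d in enumerate(draws)]
        thr = ts.compute_thresholds(wells, ["a", "b"])
        assert thr["a"] == pytest.approx(sum(draws[:, 0]) / 8)
        assert thr["b"] == pytest.approx(sum(draws[:, 1]) / 8)

    def test_no_solvent_wells_is_configuration_error(self):
        with pytest.raises(ValueError):
            ts.compute_thresholds([], ["a"])


class TestPlantedAreaRecovery:
    def test_non_overlapping_gaussians_recovered_within_2pct(self):
        # synthetic chromatogram from known Gaussian areas: recovered areas
        # within 2% and assignments exact
        from terpscreen.simulate import SimulationConfig, simulate_chromatogram
        cfg = SimulationConfig(seed=5, baseline_noise=0.0)
        planted = {"alpha-pinene": 4000.0, "beta-pinene": 2000.0,
                   "limonene": 800.0, "sabinene/myrcene": 1200.0}
        chrom, truth = simulate_chromatogram(planted, cfg, "W1")
        res = ts.process_well(chrom, list(cfg.compound_table))
        assert not res.failed
        for c, area in planted.items():
            assert res.raw_area[c] == pytest.approx(area, rel=0.02)
            assert not res.flags[c]
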