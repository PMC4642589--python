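"""Co-addition, SMFT cross-sections and 2D peak picking."""

import dataclasses

import numpy as np
import pytest

from nusproj.acquisition import (ModulatedDataset, detect_direct_dim,
                                 make_nus_schedule, simulate_datasets)
from nusproj.processing import (CrossSection, GridSpec, SmftProcessor, coadd,
                                pick_peaks, smft_cross_section)
from nusproj.spin_model import BasePeak, hnco_base_peaks

from conftest import make_table


def _freq_sections(table, geometry, schedule):
    ds = simulate_datasets(table, geometry, schedule, decay_t2=0.05)
    freq = detect_direct_dim(ds, geometry, zero_fill=2)
    return freq, coadd(freq)


class TestCoadd:
    def test_six_d_separates_sum_and_difference(self, toy_geometry_6d,
                                                full_schedule_6d,
                                                single_component_table):
        g = toy_geometry_6d
        freq, combos = _freq_sections(single_component_table, g, full_schedule_6d)
        anchor = hnco_base_peaks(single_component_table)[-1]
        proc = SmftProcessor(full_schedule_6d, g, GridSpec(128, 64))
        wn, wh = single_component_table.hz(2, "N"), single_component_table.hz(2, "HN")
        for lab, expected in (("+", wn + g.ratio_h * wh), ("-", wn - g.ratio_h * wh)):
            cs = proc.cross_section(combos[lab], anchor)
            peaks = pick_peaks(cs, 0.2)
            assert len(peaks) == 1
            assert peaks[0].position[0] == pytest.approx(expected, abs=2.0)

    def test_seven_d_four_single_frequency_outputs(self, toy_geometry_7d,
                                                   full_schedule_7d,
                                                   single_component_table):
        g = toy_geometry_7d
        freq, combos = _freq_sections(single_component_table, g, full_schedule_7d)
        anchor = hnco_base_peaks(single_component_table)[-1]
        proc = SmftProcessor(full_schedule_7d, g, GridSpec(128, 64))
        t = single_component_table
        wn, wh, wca = t.hz(2, "N"), t.hz(2, "HN"), t.hz(2, "CA")
        expect = {"++": wn + g.ratio_h * wh + g.ratio_ca * wca,
                  "+-": wn + g.ratio_h * wh - g.ratio_ca * wca,
                  "-+": wn - g.ratio_h * wh + g.ratio_ca * wca,
                  "--": wn - g.ratio_h * wh - g.ratio_ca * wca}
        for lab, f in expect.items():
            peaks = pick_peaks(proc.cross_section(combos[lab], anchor), 0.2)
            assert len(peaks) == 1
            assert peaks[0].position[0] == pytest.approx(f, abs=2.0)

    def test_zero_inputs_zero_outputs(self):
        z = {lab: ModulatedDataset(lab, np.zeros((5, 8), dtype=complex))
             for lab in ("c", "s")}
        out = coadd(z)
        assert set(out) == {"+", "-"}
        assert all(np.all(d.data == 0) for d in out.values())

    def test_incomplete_set_rejected(self):
        z = {"c": ModulatedDataset("c", np.zeros((5, 8), dtype=complex))}
        with pytest.raises(ValueError):
            coadd(z)


class TestSmft:
    def test_matches_dense_fft_on_full_grid(self, axes):
        # oracle equivalence: SMFT on a fully sampled 8^4 grid equals
        # the dense FFT slice at the fixed-frequency bins
        from nusproj.acquisition import ExperimentGeometry
        g = ExperimentGeometry(6, 7 / 700, 7 / 400, 7 / 400, 7 / 500,
                               t5max_h=(7 / 700) * (2 / 3),
                               sw_n=500.0, sw_co=400.0, sw_hn=300.0, sw_ca=600.0,
                               direct_points=8, direct_sw=300.0)
        assert g.grid_sizes == (8, 8, 8, 8)
        sch = make_nus_schedule(8 ** 4, g.grid_sizes, seed=0)
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8 ** 4, 8)) + 1j * rng.standard_normal((8 ** 4, 8))
        ds = ModulatedDataset("c", data.copy(), domain="freq",
                              direct_freqs=np.fft.fftshift(
                                  np.fft.fftfreq(8, 1 / 300.0)))
        m3, m4 = 5, 2          # fixed-dimension FFT bin indices
        anchor = BasePeak("X", 3,
                          freq_co_prev=np.fft.fftfreq(8, 1 / 400.0)[m3],
                          freq_n=np.fft.fftfreq(8, 1 / 500.0)[m4],
                          freq_hn=float(ds.direct_freqs[4]))
        cs = smft_cross_section(ds, sch, g, anchor,
                                GridSpec(8, 8, span1=(0.0, 700.0),
                                         span2=(0.0, 400.0)),
                                apodization=None, phase_correct=None)
        cube = data[:, 4].reshape(8, 8, 8, 8)
        dense = np.fft.fftn(cube)[:, :, m3, m4] / 8 ** 4
        assert np.allclose(cs.grid, dense.real, rtol=1e-9, atol=1e-9)

    def test_coadd_commutes_with_transform(self, toy_geometry_6d, full_schedule_6d,
                                           single_component_table):
        g = toy_geometry_6d
        ds = simulate_datasets(single_component_table, g, full_schedule_6d)
        freq = detect_direct_dim(ds, g)
        anchor = hnco_base_peaks(single_component_table)[-1]
        proc = SmftProcessor(full_schedule_6d, g, GridSpec(64, 32),
                             phase_correct=None)
        first = proc.cross_section(coadd(freq)["+"], anchor).grid
        second = (proc.cross_section(freq["c"], anchor).grid
                  + proc.cross_section(freq["s"], anchor).grid)
        assert np.allclose(first, second, atol=1e-12)

    def test_mismatched_anchor_suppressed_by_kernel(self, axes, toy_geometry_6d,
                                                    full_schedule_6d,
                                                    single_component_table):
        g = toy_geometry_6d
        freq, combos = _freq_sections(single_component_table, g, full_schedule_6d)
        true_anchor = hnco_base_peaks(single_component_table)[-1]
        off = 3.0 / g.t4max_n      # >= 3/tmax away in the fixed N dimension
        wrong = dataclasses.replace(true_anchor, freq_n=true_anchor.freq_n + off)
        proc = SmftProcessor(full_schedule_6d, g, GridSpec(128, 64),
                             apodization=None, phase_correct=None)
        matched = np.abs(proc.cross_section(combos["+"], true_anchor).grid).max()
        detuned = np.abs(proc.cross_section(combos["+"], wrong).grid).max()
        assert detuned < 0.25 * matched

    def test_empty_data_gives_zero_section(self, toy_geometry_6d, full_schedule_6d,
                                           single_component_table):
        nchan = toy_geometry_6d.direct_points * 4
        z = ModulatedDataset("+", np.zeros((len(full_schedule_6d), nchan),
                                           dtype=complex),
                             domain="freq",
                             direct_freqs=np.fft.fftshift(
                                 np.fft.fftfreq(nchan, 1 / 300.0)))
        anchor = hnco_base_peaks(single_component_table)[-1]
        cs = smft_cross_section(z, full_schedule_6d, toy_geometry_6d, anchor)
        assert np.all(cs.grid == 0)
        assert pick_peaks(cs, 0.5) == []

    def test_anchor_outside_window_rejected(self, toy_geometry_6d,
                                            full_schedule_6d,
                                            single_component_table):
        anchor = hnco_base_peaks(single_component_table)[-1]
        bad = dataclasses.replace(anchor, freq_n=9999.0)
        ds = ModulatedDataset("+", np.zeros((len(full_schedule_6d), 128),
                                            dtype=complex), domain="freq",
                              direct_freqs=np.linspace(-150, 150, 128))
        with pytest.raises(ValueError):
            smft_cross_section(ds, full_schedule_6d, toy_geometry_6d, bad)


class TestPeakPicking:
    def test_raw_modulated_sections_show_mirror_pairs(self, toy_geometry_6d,
                                                      full_schedule_6d,
                                                      single_component_table):
        g = toy_geometry_6d
        freq, _ = _freq_sections(single_component_table, g, full_schedule_6d)
        anchor = hnco_base_peaks(single_component_table)[-1]
        proc = SmftProcessor(full_schedule_6d, g, GridSpec(128, 64))
        for lab in ("c", "s"):
            peaks = pick_peaks(proc.cross_section(freq[lab], anchor), 0.10)
            assert len(peaks) == 2

    def test_off_grid_position_refined_within_tenth_of_step(
            self, axes, toy_geometry_6d, full_schedule_6d):
        g = toy_geometry_6d
        # frequencies chosen away from the output-grid points
        table = make_table(axes, [
            (1, -120.0, 95.0, -72.3, -130.0),
            (2, 63.7, -48.9, 30.0, 80.0),
            (3, 40.0, 20.0, 110.0, -40.0),
        ])
        freq, combos = _freq_sections(table, g, full_schedule_6d)
        anchor = hnco_base_peaks(table)[-1]
        proc = SmftProcessor(full_schedule_6d, g, GridSpec(128, 64))
        cs = proc.cross_section(combos["+"], anchor)
        step1 = cs.axis1[1] - cs.axis1[0]
        step2 = cs.axis2[1] - cs.axis2[0]
        pk = pick_peaks(cs, 0.2)[0]
        truth1 = table.hz(2, "N") + g.ratio_h * table.hz(2, "HN")
        assert abs(pk.position[0] - truth1) < 0.1 * step1
        assert abs(pk.position[1] - table.hz(1, "CO")) < 0.1 * step2

    def test_flat_zero_section_yields_no_peaks(self):
        cs = CrossSection("A1", "+", np.zeros((16, 8)),
                          np.arange(16.0), np.arange(8.0))
        assert pick_peaks(cs, 0.1) == []

    def test_bad_threshold_rejected(self):
        cs = CrossSection("A1", "+", np.ones((4, 4)),
                          np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValueError):
            pick_peaks(cs, 1.5)
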