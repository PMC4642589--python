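"""NUS schedules and sparse time-domain simulation."""

import dataclasses

import numpy as np
import pytest

from nusproj.acquisition import (ExperimentGeometry, detect_direct_dim,
                                 geometry_600_6d, geometry_800_6d,
                                 geometry_800_7d, make_nus_schedule,
                                 modulation_labels, simulate_datasets)
from nusproj.spin_model import SpinSystem, ShiftTable

from conftest import make_table


class TestGeometry:
    def test_published_ratios(self):
        assert geometry_800_7d().ratio_h == pytest.approx(20 / 30)
        assert geometry_800_7d().ratio_ca == pytest.approx(52 / 30)
        assert geometry_800_6d().ratio_h == pytest.approx(2 / 3)
        assert geometry_600_6d().ratio_h == pytest.approx(0.5)

    def test_projected_bandwidth_includes_coevolved_terms(self):
        g = geometry_800_7d()
        assert g.sw1_projected == pytest.approx(
            g.sw_n + g.ratio_h * g.sw_hn + g.ratio_ca * g.sw_ca)

    def test_seven_d_requires_ca_time(self):
        with pytest.raises(ValueError):
            ExperimentGeometry(7, 0.03, 0.025, 0.025, 0.03, t5max_h=0.02)


class TestSchedule:
    def test_exhaustive_grid(self):
        sch = make_nus_schedule(256, (4, 4, 4, 4), seed=0)
        assert len(sch) == 256
        assert len(np.unique(sch.indices, axis=0)) == 256

    def test_deterministic_and_seed_sensitive(self):
        a = make_nus_schedule(100, (32, 16, 16, 16), seed=3)
        b = make_nus_schedule(100, (32, 16, 16, 16), seed=3)
        c = make_nus_schedule(100, (32, 16, 16, 16), seed=4)
        assert np.array_equal(a.indices, b.indices)
        assert not np.array_equal(a.indices, c.indices)

    def test_contains_time_origin(self):
        sch = make_nus_schedule(50, (8, 8, 8, 8), seed=5)
        assert any((row == 0).all() for row in sch.indices)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            make_nus_schedule(17, (2, 2, 2, 2), seed=0)


class TestSimulate:
    def test_zero_coevolved_proton_gives_silent_sine(self, axes, toy_geometry_6d,
                                                     full_schedule_6d):
        # predecessor H on the carrier: theta_H = 0, so the sine dataset
        # vanishes and the cosine dataset is the plain 5D signal
        table = make_table(axes, [
            (1, -120.0, 95.0, -70.0, -130.0),
            (2, 60.0, 0.0, 30.0, 80.0),
            (3, 40.0, 20.0, 110.0, -40.0),
        ])
        ds = simulate_datasets(table, toy_geometry_6d, full_schedule_6d)
        assert np.allclose(ds["s"].data, 0.0)
        assert np.abs(ds["c"].data).max() > 0

    def test_cosine_plus_sine_is_single_frequency(self, axes, toy_geometry_6d,
                                                  full_schedule_6d,
                                                  single_component_table):
        # Euler identity: c + s = exp(i(2 pi Omega_N t1 + theta_H)) x rest,
        # for each helicity of the CO_{i-2} evolution
        table = single_component_table
        g = toy_geometry_6d
        ds = simulate_datasets(table, g, full_schedule_6d, decay_t2=0.05)
        t = full_schedule_6d.times(g)
        td = np.arange(g.direct_points) / g.direct_sw
        w = [table.hz(2, "N"), table.hz(1, "CO"), table.hz(2, "CO"), table.hz(3, "N")]
        wsum = w[0] + g.ratio_h * table.hz(2, "HN")
        from nusproj.transfer import seq_transfer
        amp = abs(seq_transfer(0.054))
        fid = np.exp((2j * np.pi * table.hz(3, "HN") - 20.0) * td)
        total = ds["c"].data + ds["s"].data
        for hel, sign in ((0, 1.0), (1, -1.0)):
            phase = np.exp(2j * np.pi * (wsum * t[:, 0] + sign * w[1] * t[:, 1]
                                         + w[2] * t[:, 2] + w[3] * t[:, 3]))
            expected = amp * np.outer(phase * np.exp(-t.sum(axis=1) / 0.05), fid)
            assert np.allclose(total[:, hel, :], expected, atol=1e-10)

    def test_four_modulations_sum_to_double_projection(self, axes, toy_geometry_7d,
                                                       full_schedule_7d,
                                                       single_component_table):
        table = single_component_table
        g = toy_geometry_7d
        ds = simulate_datasets(table, g, full_schedule_7d, decay_t2=0.05)
        t = full_schedule_7d.times(g)
        td = np.arange(g.direct_points) / g.direct_sw
        wsum = (table.hz(2, "N") + g.ratio_h * table.hz(2, "HN")
                + g.ratio_ca * table.hz(2, "CA"))
        from nusproj.transfer import seq_transfer
        amp = abs(seq_transfer(0.054))
        fid = np.exp((2j * np.pi * table.hz(3, "HN") - 20.0) * td)
        phase = np.exp(2j * np.pi * (wsum * t[:, 0] + table.hz(1, "CO") * t[:, 1]
                                     + table.hz(2, "CO") * t[:, 2]
                                     + table.hz(3, "N") * t[:, 3]))
        expected = amp * np.outer(phase * np.exp(-t.sum(axis=1) / 0.05), fid)
        total = sum(ds[lab].data for lab in ("cc", "sc", "cs", "ss"))
        assert np.allclose(total[:, 0, :], expected, atol=1e-10)

    def test_linearity_over_components(self, axes, toy_geometry_6d, full_schedule_6d):
        rows = [
            (1, -120.0, 95.0, -70.0, -130.0),
            (2, 60.0, -50.0, 30.0, 80.0),
            (3, 40.0, 20.0, 110.0, -40.0),
            (4, -90.0, -10.0, -150.0, 200.0),
            (5, 150.0, 60.0, 80.0, -220.0),
        ]
        full = simulate_datasets(make_table(axes, rows), toy_geometry_6d,
                                 full_schedule_6d)
        acc = {lab: 0.0 for lab in modulation_labels(6)}
        for i in (3, 4, 5):
            sub = [r[:5] + ((r[0] in (i, i - 1)),) for r in rows]
            part = simulate_datasets(make_table(axes, sub), toy_geometry_6d,
                                     full_schedule_6d)
            for lab in acc:
                acc[lab] = acc[lab] + part[lab].data
        for lab in acc:
            assert np.allclose(full[lab].data, acc[lab], atol=1e-12)

    def test_flipping_proton_sign_swaps_combinations(self, axes, toy_geometry_6d,
                                                     full_schedule_6d,
                                                     single_component_table):
        ds = simulate_datasets(single_component_table, toy_geometry_6d,
                               full_schedule_6d)
        flipped_table = make_table(axes, [
            (1, -120.0, 95.0, -70.0, -130.0),
            (2, 60.0, 80.0, 30.0, 120.0),    # H(2) sign flipped
            (3, 40.0, 20.0, 110.0, -40.0),
        ])
        fl = simulate_datasets(flipped_table, toy_geometry_6d, full_schedule_6d)
        # cos(-x) = cos(x), sin(-x) = -sin(x): c invariant, s negated,
        # so the later (+) and (-) co-additions trade places
        assert np.allclose(ds["c"].data, fl["c"].data, atol=1e-12)
        assert np.allclose(ds["s"].data, -fl["s"].data, atol=1e-12)

    def test_vanishing_ratios_reduce_to_plain_4d_signal(self, axes,
                                                        single_component_table):
        g6 = ExperimentGeometry(6, 0.032, 0.020, 0.020, 0.018, t5max_h=1e-13,
                                sw_n=500.0, sw_co=400.0, sw_hn=0.0, sw_ca=600.0,
                                direct_points=32, direct_sw=300.0)
        g5 = ExperimentGeometry(5, 0.032, 0.020, 0.020, 0.018,
                                sw_n=500.0, sw_co=400.0, sw_hn=0.0, sw_ca=600.0,
                                direct_points=32, direct_sw=300.0)
        assert g6.grid_sizes == g5.grid_sizes
        grid = g6.grid_sizes
        sch = make_nus_schedule(int(np.prod(grid)), grid, seed=0)
        d6 = simulate_datasets(single_component_table, g6, sch)
        d5 = simulate_datasets(single_component_table, g5, sch)
        assert np.allclose(d6["c"].data, d5[""].data, atol=1e-9)
        assert np.allclose(d6["s"].data, 0.0, atol=1e-9)

    def test_noise_reproducible_by_seed(self, toy_geometry_6d, full_schedule_6d,
                                        single_component_table):
        kw = dict(noise_sigma=0.1, noise_seed=42)
        a = simulate_datasets(single_component_table, toy_geometry_6d,
                              full_schedule_6d, **kw)
        b = simulate_datasets(single_component_table, toy_geometry_6d,
                              full_schedule_6d, **kw)
        assert np.array_equal(a["c"].data, b["c"].data)


class TestDirectDetection:
    def test_tone_lands_on_nearest_channel(self, toy_geometry_6d, full_schedule_6d,
                                           single_component_table):
        g = toy_geometry_6d
        ds = simulate_datasets(single_component_table, g, full_schedule_6d)
        spec = detect_direct_dim(ds, g)
        row = np.abs(spec["c"].data[0, 0])
        peak_freq = spec["c"].direct_freqs[int(np.argmax(row))]
        truth = single_component_table.hz(3, "HN")
        assert abs(peak_freq - truth) <= g.direct_sw / g.direct_points / 2

    def test_transform_is_linear(self, toy_geometry_6d, full_schedule_6d,
                                 single_component_table):
        ds = simulate_datasets(single_component_table, toy_geometry_6d,
                               full_schedule_6d)
        both = detect_direct_dim(ds, toy_geometry_6d)
        assert np.allclose(both["c"].data + both["s"].data,
                           detect_direct_dim(
                               {"x": dataclasses.replace(ds["c"], data=ds["c"].data
                                                         + ds["s"].data)},
                               toy_geometry_6d)["x"].data, atol=1e-9)

    def test_zero_in_zero_out(self, toy_geometry_6d, full_schedule_6d):
        from nusproj.acquisition import ModulatedDataset
        z = ModulatedDataset("c", np.zeros((10, 32), dtype=complex))
        out = detect_direct_dim({"c": z}, toy_geometry_6d)
        assert np.all(out["c"].data == 0)
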