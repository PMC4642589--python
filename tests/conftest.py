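"""Shared fixtures: desk-scale geometries and single-component tables.

The toy geometries use small spectral widths and short evolution times
so that the indirect grid can be fully sampled in-memory; frequencies
of the toy spin systems are specified as Hz offsets and converted to
ppm through the default axes.
"""

import numpy as np
import pytest

from nusproj.acquisition import ExperimentGeometry, make_nus_schedule
from nusproj.spin_model import ShiftTable, SpinSystem, default_axes, hz_to_ppm


@pytest.fixture(scope="session")
def axes():
    return default_axes()


def _ppm(axes, nucleus, hz):
    return float(hz_to_ppm(hz, axes[nucleus]))


def make_table(axes, rows):
    """Build a ShiftTable from (index, N, HN, CO, CA) Hz-offset rows."""
    residues = []
    for (idx, n, hn, co, ca, *rest) in rows:
        observable = rest[0] if rest else (hn is not None)
        residues.append(SpinSystem(
            residue_index=idx,
            shift_n=_ppm(axes, "N", n),
            shift_hn=None if hn is None else _ppm(axes, "HN", hn),
            shift_co=_ppm(axes, "CO", co),
            shift_ca=_ppm(axes, "CA", ca),
            amide_observable=observable))
    return ShiftTable(residues=tuple(residues), axes=axes)


@pytest.fixture(scope="session")
def toy_geometry_6d():
    return ExperimentGeometry(
        6, t1max_n=0.048, t2max_co=0.035, t3max_co=0.020, t4max_n=0.018,
        t5max_h=0.048 * 2 / 3, sw_n=500.0, sw_co=400.0, sw_hn=300.0,
        sw_ca=600.0, direct_points=16, direct_sw=300.0)


@pytest.fixture(scope="session")
def toy_geometry_7d():
    return ExperimentGeometry(
        7, t1max_n=0.048, t2max_co=0.035, t3max_co=0.020, t4max_n=0.018,
        t5max_h=0.048 * 2 / 3, t6max_ca=0.048 * 1.2, sw_n=500.0, sw_co=400.0,
        sw_hn=300.0, sw_ca=600.0, direct_points=16, direct_sw=300.0)


@pytest.fixture(scope="session")
def single_component_table(axes):
    """Three residues: exactly one sequential component (anchor A3).

    Predecessor frequencies (residue 2): N +60, H -80, CA +120 Hz;
    CO(1) -70 Hz; anchor coordinates (residue 3): N +40, H +20,
    CO(2) +30 Hz.
    """
    return make_table(axes, [
        (1, -120.0, 95.0, -70.0, -130.0),
        (2, 60.0, -80.0, 30.0, 120.0),
        (3, 40.0, 20.0, 110.0, -40.0),
    ])


@pytest.fixture(scope="session")
def full_schedule_6d(toy_geometry_6d):
    grid = toy_geometry_6d.grid_sizes
    return make_nus_schedule(int(np.prod(grid)), grid, seed=0)


@pytest.fixture(scope="session")
def full_schedule_7d(toy_geometry_7d):
    grid = toy_geometry_7d.grid_sizes
    return make_nus_schedule(int(np.prod(grid)), grid, seed=0)
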