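"""Sparse time-domain simulation of the 5D/6D/7D projection experiments.

Four indirect dimensions (N_{i-1}, CO_{i-2}, CO_{i-1}, N_i) are sampled
non-uniformly on a grid; the amide proton of the detected residue is
the direct dimension.  Extra dimensions are projected: the predecessor
amide-proton (6D/7D) and CA (7D) evolution times are incremented in a
fixed ratio with t1, so their frequencies add linear combinations
+-a*Omega_H (+- b*Omega_CA) to the N_{i-1} axis.  Each projected
dimension doubles the number of stored datasets (cosine and sine
modulated); the sine datasets carry the pi/2 phase compensation as a
factor i*sin(theta), so that downstream separation of the sign
combinations is a plain co-addition.

Because the t1 axis carries combination frequencies, its dwell time is
derived from a projected spectral width sw_N + a*sw_H (+ b*sw_CA); the
per-nucleus axis windows are unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .spin_model import ShiftTable
from .transfer import (CouplingConstants, DEFAULT_DELTA_NCA, auto_transfer,
                       seq_transfer)

__all__ = [
    "ExperimentGeometry",
    "SamplingSchedule",
    "ModulatedDataset",
    "geometry_800_7d",
    "geometry_800_6d",
    "geometry_600_6d",
    "modulation_labels",
    "make_nus_schedule",
    "simulate_datasets",
    "detect_direct_dim",
]


@dataclass(frozen=True)
class ExperimentGeometry:
    """Evolution-time and bandwidth layout of one experiment.

    ``t1max_n`` .. ``t4max_n`` are the maximum evolution times (s) of
    the four NUS dimensions (N_{i-1}, CO_{i-2}, CO_{i-1}, N_i).
    ``t5max_h`` and ``t6max_ca`` are the coevolved maxima; the
    projection coefficients are a = t5max/t1max and b = t6max/t1max
    (the ratio of maximum evolution times sets the projection angle).
    Spectral widths are in Hz; ``direct_points``/``direct_sw`` describe
    the directly detected amide-proton dimension.
    """

    dimensionality: int
    t1max_n: float
    t2max_co: float
    t3max_co: float
    t4max_n: float
    t5max_h: float = 0.0
    t6max_ca: float = 0.0
    sw_n: float = 2000.0
    sw_co: float = 1500.0
    sw_hn: float = 1600.0
    sw_ca: float = 4800.0
    direct_points: int = 128
    direct_sw: float = 1600.0

    def __post_init__(self) -> None:
        if self.dimensionality not in (5, 6, 7):
            raise ValueError("dimensionality must be 5, 6 or 7")
        if self.dimensionality >= 6 and self.t5max_h <= 0:
            raise ValueError("6D/7D geometry requires t5max_h > 0")
        if self.dimensionality == 7 and self.t6max_ca <= 0:
            raise ValueError("7D geometry requires t6max_ca > 0")
        if self.dimensionality < 7 and self.t6max_ca != 0.0:
            raise ValueError("t6max_ca must be 0 below 7D")
        if self.dimensionality < 6 and self.t5max_h != 0.0:
            raise ValueError("t5max_h must be 0 below 6D")

    @property
    def ratio_h(self) -> float:
        """Projection coefficient a = t5max / t1max."""
        return self.t5max_h / self.t1max_n

    @property
    def ratio_ca(self) -> float:
        """Projection coefficient b = t6max / t1max."""
        return self.t6max_ca / self.t1max_n

    @property
    def sw1_projected(self) -> float:
        """Bandwidth of the t1 axis including projected combinations."""
        return self.sw_n + self.ratio_h * self.sw_hn + self.ratio_ca * self.sw_ca

    @property
    def dwells(self) -> tuple[float, float, float, float]:
        """Dwell times (s) of the four indirect dimensions."""
        return (1.0 / self.sw1_projected, 1.0 / self.sw_co,
                1.0 / self.sw_co, 1.0 / self.sw_n)

    @property
    def grid_sizes(self) -> tuple[int, int, int, int]:
        """Number of grid points per indirect dimension."""
        tmax = (self.t1max_n, self.t2max_co, self.t3max_co, self.t4max_n)
        return tuple(int(np.floor(t / d + 1e-9)) + 1
                     for t, d in zip(tmax, self.dwells))


def geometry_800_7d() -> ExperimentGeometry:
    """7D at 800 MHz: tmax 20/30/25/52/25/30 ms (H, N, CO', CA, CO, N+1)."""
    return ExperimentGeometry(7, t1max_n=0.030, t2max_co=0.025, t3max_co=0.025,
                              t4max_n=0.030, t5max_h=0.020, t6max_ca=0.052)


def geometry_800_6d() -> ExperimentGeometry:
    """6D at 800 MHz: tmax 20/30/25/25/30 ms (H, N, CO', CO, N+1)."""
    return ExperimentGeometry(6, t1max_n=0.030, t2max_co=0.025, t3max_co=0.025,
                              t4max_n=0.030, t5max_h=0.020)


def geometry_600_6d() -> ExperimentGeometry:
    """6D at 600 MHz: tmax 20/40/40/40/40 ms (H, N, CO', CO, N+1)."""
    return ExperimentGeometry(6, t1max_n=0.040, t2max_co=0.040, t3max_co=0.040,
                              t4max_n=0.040, t5max_h=0.020)


def modulation_labels(dimensionality: int) -> tuple[str, ...]:
    """Stored dataset labels: none (5D), c/s (6D), cc/sc/cs/ss (7D)."""
    return {5: ("",), 6: ("c", "s"), 7: ("cc", "sc", "cs", "ss")}[dimensionality]


@dataclass(frozen=True)
class SamplingSchedule:
    """Set of unique (k1, k2, k3, k4) grid indices actually acquired."""

    indices: np.ndarray          # (K, 4) int
    grid_sizes: tuple[int, int, int, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.ndim != 2 or idx.shape[1] != 4:
            raise ValueError("indices must be (K, 4)")
        if len(np.unique(idx, axis=0)) != len(idx):
            raise ValueError("schedule tuples must be unique")
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.grid_sizes)):
            raise ValueError("schedule indices out of grid bounds")

    def __len__(self) -> int:
        return len(self.indices)

    def times(self, geometry: ExperimentGeometry) -> np.ndarray:
        """Evolution times (K, 4) in seconds for this geometry."""
        if tuple(self.grid_sizes) != geometry.grid_sizes:
            raise ValueError("schedule grid does not match geometry grid")
        return self.indices * np.asarray(geometry.dwells)


def make_nus_schedule(n_points: int,
                      grid: tuple[int, int, int, int],
                      seed: int) -> SamplingSchedule:
    """Uniform-random NUS schedule of unique grid tuples.

    Always contains the all-zeros tuple (the t=0 sample anchors the
    spectrum phase).  Reproducible for a given seed.
    """
    grid = tuple(int(g) for g in grid)
    total = int(np.prod([int(g) for g in grid], dtype=np.int64))
    if n_points > total:
        raise ValueError(f"requested {n_points} points from a {total}-point grid")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    if n_points == total:
        flat = np.arange(total, dtype=np.int64)
    else:
        chosen: dict[int, None] = {0: None}   # insertion-ordered unique set
        while len(chosen) < n_points:
            draw = rng.integers(0, total, size=2 * (n_points - len(chosen)) + 16)
            for f in draw:
                chosen[int(f)] = None
                if len(chosen) == n_points:
                    break
        flat = np.fromiter(chosen.keys(), dtype=np.int64)
    idx = np.stack(np.unravel_index(flat, grid), axis=1).astype(np.int64)
    return SamplingSchedule(indices=idx, grid_sizes=grid, seed=seed)


@dataclass(frozen=True)
class ModulatedDataset:
    """Sparse samples of one modulation label.

    ``data`` has shape (K, 2, direct_points): per schedule point, the
    echo/antiecho helicity pair of the CO_{i-2} evolution (P-type
    e^{+i phi2} and N-type e^{-i phi2}) times the direct-dimension
    channel.  Storing both helicities is what lets the processing stage
    build pure-absorption 2D cross-sections; a plain analytic dataset
    of shape (K, direct_points) is also accepted throughout and
    transforms in simple P-type (phase-twist) mode.  ``domain`` is
    "time" as simulated and "freq" after :func:`detect_direct_dim`, in
    which case ``direct_freqs`` labels the channels in Hz offsets.
    """

    label: str
    data: np.ndarray
    domain: str = "time"
    direct_freqs: np.ndarray | None = None


def _components(table: ShiftTable, include_auto: bool,
                delta_nca: float, couplings: CouplingConstants | None):
    """Yield (omega1..4, omega_H_coev, omega_CA_coev, f_direct, amp)."""
    present = {r.residue_index: r for r in table.residues}
    a_seq = abs(seq_transfer(delta_nca, couplings))
    a_auto = auto_transfer(delta_nca, couplings)
    for r in table.residues:
        i = r.residue_index
        prev = present.get(i - 1)
        if not r.amide_observable or prev is None:
            continue
        if include_auto:
            yield (table.hz(i, "N"), table.hz(i - 1, "CO"), table.hz(i - 1, "CO"),
                   table.hz(i, "N"), table.hz(i, "HN"), table.hz(i, "CA"),
                   table.hz(i, "HN"), a_auto)
        if (i - 2) in present and prev.amide_observable:
            yield (table.hz(i - 1, "N"), table.hz(i - 2, "CO"), table.hz(i - 1, "CO"),
                   table.hz(i, "N"), table.hz(i - 1, "HN"), table.hz(i - 1, "CA"),
                   table.hz(i, "HN"), a_seq)


def _modulation_factors(label: str, th_h: np.ndarray, th_ca: np.ndarray) -> np.ndarray:
    """Phase-compensated cos/sin modulation of one stored dataset.

    The pi/2 phase shift applied with each sine modulation is the
    factor i (and the double-sine 7D dataset carries i*i = -1).
    """
    if label == "":
        return np.ones_like(th_h)
    if label == "c":
        return np.cos(th_h)
    if label == "s":
        return 1j * np.sin(th_h)
    return {
        "cc": np.cos(th_h) * np.cos(th_ca),
        "sc": 1j * np.sin(th_h) * np.cos(th_ca),
        "cs": 1j * np.cos(th_h) * np.sin(th_ca),
        "ss": -np.sin(th_h) * np.sin(th_ca),
    }[label]


def simulate_datasets(
    table: ShiftTable,
    geometry: ExperimentGeometry,
    schedule: SamplingSchedule,
    noise_sigma: float = 0.0,
    decay_t2: float = 0.1,
    include_auto: bool = False,
    delta_nca: float = DEFAULT_DELTA_NCA,
    couplings: CouplingConstants | None = None,
    noise_seed: int | None = None,
) -> dict[str, ModulatedDataset]:
    """Simulate the sparse time-domain data of all modulation labels.

    Every sequential correlation (anchor residue i whose predecessor is
    amide-observable and whose i-2 carbonyl exists) contributes an
    analytic signal exp(2 pi i (w1 t1 + w2 t2 + w3 t3 + w4 t4)) times
    the modulation factor of the coevolved angles
    theta_H = 2 pi a Omega_H(i-1) t1, theta_CA = 2 pi b Omega_CA(i-1) t1,
    times a direct-dimension FID at Omega_H(i), all damped by
    exp(-t/T2) per time axis.  Both helicities of the CO_{i-2}
    evolution are stored (echo/antiecho pair, the quadrature needed
    for absorption-mode processing).  Amplitudes come from the transfer model
    at ``delta_nca``; auto-correlation components are added only when
    ``include_auto`` is set.  Complex white Gaussian noise of standard
    deviation ``noise_sigma`` is added per stored sample.
    """
    if len(table) == 0:
        raise ValueError("empty shift table")
    t = schedule.times(geometry)          # validates grid match
    labels = modulation_labels(geometry.dimensionality)
    nd = geometry.direct_points
    if nd < 8:
        raise ValueError("direct dimension needs at least 8 points")
    td = np.arange(nd) / geometry.direct_sw
    decay_ind = np.exp(-t.sum(axis=1) / decay_t2)
    out = {lab: np.zeros((len(schedule), 2, nd), dtype=complex) for lab in labels}
    for (w1, w2, w3, w4, wh, wca, fdir, amp) in _components(
            table, include_auto, delta_nca, couplings):
        if amp == 0.0:
            continue
        common = np.exp(2j * np.pi * (w1 * t[:, 0] + w3 * t[:, 2] + w4 * t[:, 3]))
        helicity = np.exp(2j * np.pi * np.outer(w2 * t[:, 1], [1.0, -1.0]))
        th_h = 2 * np.pi * wh * geometry.ratio_h * t[:, 0]
        th_ca = 2 * np.pi * wca * geometry.ratio_ca * t[:, 0]
        fid = np.exp((2j * np.pi * fdir - 1.0 / decay_t2) * td)
        base = amp * common * decay_ind
        for lab in labels:
            mod = base * _modulation_factors(lab, th_h, th_ca)
            out[lab] += (mod[:, None] * helicity)[:, :, None] * fid
    if noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        for lab in labels:
            out[lab] += noise_sigma * (rng.standard_normal(out[lab].shape)
                                       + 1j * rng.standard_normal(out[lab].shape))
    return {lab: ModulatedDataset(label=lab, data=out[lab]) for lab in labels}


def detect_direct_dim(datasets: Mapping[str, ModulatedDataset],
                      geometry: ExperimentGeometry,
                      zero_fill: int = 4) -> dict[str, ModulatedDataset]:
    """Fourier transform the direct dimension to frequency channels.

    The FID is zero-filled by ``zero_fill`` before the DFT (standard
    practice) so that nearest-channel slicing at the anchor frequencies
    loses little amplitude to channel quantisation.
    """
    if zero_fill < 1:
        raise ValueError("zero_fill must be >= 1")
    out = {}
    for lab, ds in datasets.items():
        if ds.domain != "time":
            raise ValueError("direct dimension already transformed")
        nd = ds.data.shape[-1] * zero_fill
        spec = np.fft.fftshift(np.fft.fft(ds.data, n=nd, axis=-1), axes=-1)
        freqs = np.fft.fftshift(np.fft.fftfreq(nd, d=1.0 / geometry.direct_sw))
        out[lab] = ModulatedDataset(label=lab, data=spec, domain="freq",
                                    direct_freqs=freqs)
    return out
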