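"""Ground-truth backbone spin systems for simulated assignment experiments.

The experiments this package models correlate, for each amide anchor
``i``, the backbone frequencies N_i, H_i^N, CO_{i-1} (the HNCO "base"
coordinates) with the predecessor frequencies N_{i-1}, H_{i-1}^N,
CA_{i-1} and CO_{i-2}.  This module holds the synthetic source of truth
for those frequencies: per-residue chemical shifts in ppm, the axis
definitions that convert them to Hz offsets relative to each carrier,
and the derived HNCO base peak list that anchors SMFT processing.

The shift generator emulates an intrinsically disordered protein:
narrow amide-proton and carbonyl dispersion, a bimodal CA distribution
(generic vs glycine-like), optional prolines without an amide proton,
and optional exchange-broadened N-terminal residues that are invisible
in amide-detected spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleusAxis",
    "SpinSystem",
    "ShiftTable",
    "BasePeak",
    "ShiftDistributions",
    "default_axes",
    "ppm_to_hz",
    "hz_to_ppm",
    "generate_idp_chain",
    "hnco_base_peaks",
    "write_shift_table",
    "read_shift_table",
]


@dataclass(frozen=True)
class NucleusAxis:
    """Frequency axis of one nucleus: carrier, base frequency, window.

    Parameters
    ----------
    nucleus : str
        One of ``"N"``, ``"HN"``, ``"CO"``, ``"CA"``.
    carrier_ppm : float
        Carrier offset in ppm; all Hz offsets are relative to it.
    base_freq_mhz : float
        Larmor frequency of the nucleus in MHz (so 1 ppm = base_freq Hz).
    spectral_width_hz : float
        Acquired window in Hz, centred on the carrier.
    """

    nucleus: str
    carrier_ppm: float
    base_freq_mhz: float
    spectral_width_hz: float

    def __post_init__(self) -> None:
        if self.nucleus not in ("N", "HN", "CO", "CA"):
            raise ValueError(f"unknown nucleus label {self.nucleus!r}")
        if self.base_freq_mhz <= 0:
            raise ValueError("base frequency must be positive")
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral width must be positive")


def default_axes(field_mhz: float = 800.13) -> dict[str, NucleusAxis]:
    """Axis set for a given proton base frequency (default 800 MHz).

    At 800.13 MHz the base frequencies are H 800.13, N 81.08,
    C 201.19 MHz; other fields scale by the gyromagnetic ratios.  The N
    and CO windows (2000 / 1500 Hz) match typical amide/carbonyl
    acquisition; HN and CA windows are wide enough to hold the IDP
    shift distributions including the glycine CA class.
    """
    scale = field_mhz / 800.13
    f_n, f_c = 81.08 * scale, 201.19 * scale
    return {
        "N": NucleusAxis("N", 118.0, f_n, 2000.0),
        "HN": NucleusAxis("HN", 8.3, field_mhz, 1600.0),
        "CO": NucleusAxis("CO", 175.5, f_c, 1500.0),
        "CA": NucleusAxis("CA", 54.0, f_c, 4800.0),
    }


def ppm_to_hz(value_ppm: float | np.ndarray, axis: NucleusAxis) -> float | np.ndarray:
    """Convert a ppm value to a Hz offset relative to the axis carrier."""
    return (np.asarray(value_ppm) - axis.carrier_ppm) * axis.base_freq_mhz


def hz_to_ppm(value_hz: float | np.ndarray, axis: NucleusAxis) -> float | np.ndarray:
    """Inverse of :func:`ppm_to_hz`."""
    return np.asarray(value_hz) / axis.base_freq_mhz + axis.carrier_ppm


@dataclass(frozen=True)
class SpinSystem:
    """One residue's backbone shifts in ppm.

    ``shift_hn`` is ``None`` for prolines.  ``amide_observable`` is
    False for prolines and for exchange-broadened residues whose amide
    signal is below the detection limit; it is never True without an
    amide proton.
    """

    residue_index: int
    shift_n: float
    shift_hn: float | None
    shift_co: float
    shift_ca: float
    amide_observable: bool = True
    aa_class: str = "generic"

    def __post_init__(self) -> None:
        if self.shift_hn is None and self.amide_observable:
            raise ValueError(
                f"residue {self.residue_index}: amide cannot be observable "
                "without an amide proton"
            )


@dataclass(frozen=True)
class ShiftTable:
    """Ordered, indexed list of spin systems plus the axis definitions."""

    residues: tuple[SpinSystem, ...]
    axes: Mapping[str, NucleusAxis]
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = [r.residue_index for r in self.residues]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise ValueError("residues must be ordered by index with no duplicates")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> SpinSystem | None:
        """Residue with the given 1-based index, or None."""
        for r in self.residues:
            if r.residue_index == index:
                return r
        return None

    def hz(self, index: int, nucleus: str) -> float | None:
        """Hz offset of one nucleus of one residue (None if absent)."""
        r = self.residue(index)
        if r is None:
            return None
        ppm = {"N": r.shift_n, "HN": r.shift_hn, "CO": r.shift_co, "CA": r.shift_ca}[nucleus]
        if ppm is None:
            return None
        return float(ppm_to_hz(ppm, self.axes[nucleus]))


@dataclass(frozen=True)
class BasePeak:
    """One HNCO base-list entry: (CO_{i-1}, N_i, H_i^N) as Hz offsets."""

    id: str
    anchor_residue: int
    freq_co_prev: float
    freq_n: float
    freq_hn: float


@dataclass(frozen=True)
class ShiftDistributions:
    """Gaussian shift models (ppm) used by :func:`generate_idp_chain`.

    Defaults mimic the crowding of a disordered chain: H^N spread of
    only ±0.45 ppm at 3 sigma and a ~3.6 ppm CO range, with CA split
    into a generic class and a distinct glycine-like class.
    """

    n_mean: float = 118.5
    n_sd: float = 3.5
    hn_mean: float = 8.25
    hn_sd: float = 0.15
    co_mean: float = 175.5
    co_sd: float = 1.2
    ca_mean: float = 55.0
    ca_sd: float = 3.0
    ca_gly_mean: float = 45.2
    ca_gly_sd: float = 0.8
    gly_fraction: float = 0.12


def _draw_in_window(rng: np.random.Generator, mean: float, sd: float,
                    axis: NucleusAxis) -> float:
    """Gaussian draw, resampled until inside the axis window (in ppm)."""
    half = axis.spectral_width_hz / (2.0 * axis.base_freq_mhz)
    lo, hi = axis.carrier_ppm - half, axis.carrier_ppm + half
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise RuntimeError("shift distribution incompatible with spectral window")


def generate_idp_chain(
    n_residues: int,
    seed: int,
    params: ShiftDistributions | None = None,
    axes: Mapping[str, NucleusAxis] | None = None,
    proline_at: Iterable[int] = (),
    exchange_broadened_prefix: int = 0,
) -> ShiftTable:
    """Generate a reproducible IDP-like backbone shift table.

    Parameters
    ----------
    n_residues : int
        Chain length (>= 3).
    seed : int
        Seed for the shift draws; equal seeds give identical tables.
    params : ShiftDistributions, optional
        Per-nucleus Gaussian parameters.
    proline_at : iterable of int
        1-based residue indices that are prolines (no amide proton).
    exchange_broadened_prefix : int
        Number of leading residues whose amide signal is exchange
        broadened beyond detection (``amide_observable=False``); their
        shifts still exist and still feed predecessor frequencies.
    """
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    params = params or ShiftDistributions()
    axes = dict(axes or default_axes())
    prolines = set(proline_at)
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(1, n_residues + 1):
        is_pro = i in prolines
        is_gly = (not is_pro) and rng.random() < params.gly_fraction
        if is_gly:
            ca = _draw_in_window(rng, params.ca_gly_mean, params.ca_gly_sd, axes["CA"])
        else:
            ca = _draw_in_window(rng, params.ca_mean, params.ca_sd, axes["CA"])
        hn = None if is_pro else _draw_in_window(rng, params.hn_mean, params.hn_sd, axes["HN"])
        residues.append(
            SpinSystem(
                residue_index=i,
                shift_n=_draw_in_window(rng, params.n_mean, params.n_sd, axes["N"]),
                shift_hn=hn,
                shift_co=_draw_in_window(rng, params.co_mean, params.co_sd, axes["CO"]),
                shift_ca=ca,
                amide_observable=(hn is not None) and i > exchange_broadened_prefix,
                aa_class="pro" if is_pro else ("gly" if is_gly else "generic"),
            )
        )
    return ShiftTable(residues=tuple(residues), axes=axes, seed=seed)


def hnco_base_peaks(table: ShiftTable) -> list[BasePeak]:
    """HNCO peak list: one entry per observable amide with a predecessor.

    A base peak for anchor residue ``i`` exists iff residue ``i`` is
    amide-observable and residue ``i-1`` exists (its CO supplies the
    third coordinate).  Frequencies are Hz offsets from the carriers.
    """
    peaks = []
    present = {r.residue_index for r in table.residues}
    for r in table.residues:
        i = r.residue_index
        if not r.amide_observable or (i - 1) not in present:
            continue
        peaks.append(
            BasePeak(
                id=f"A{i}",
                anchor_residue=i,
                freq_co_prev=table.hz(i - 1, "CO"),
                freq_n=table.hz(i, "N"),
                freq_hn=table.hz(i, "HN"),
            )
        )
    return peaks


_TSV_COLUMNS = ["residue_index", "aa_class", "N_ppm", "HN_ppm", "CO_ppm", "CA_ppm", "observable"]


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Serialize a shift table as tab-separated text ("-" = absent H^N)."""
    rows = []
    for r in table.residues:
        rows.append(
            {
                "residue_index": r.residue_index,
                "aa_class": r.aa_class,
                "N_ppm": f"{r.shift_n:.6f}",
                "HN_ppm": "-" if r.shift_hn is None else f"{r.shift_hn:.6f}",
                "CO_ppm": f"{r.shift_co:.6f}",
                "CA_ppm": f"{r.shift_ca:.6f}",
                "observable": int(r.amide_observable),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_shift_table(path: str | Path,
                     axes: Mapping[str, NucleusAxis] | None = None) -> ShiftTable:
    """Read a tab-separated shift table written by :func:`write_shift_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"HN_ppm": str})
    residues = []
    for _, row in df.iterrows():
        hn = None if str(row["HN_ppm"]).strip() == "-" else float(row["HN_ppm"])
        residues.append(
            SpinSystem(
                residue_index=int(row["residue_index"]),
                shift_n=float(row["N_ppm"]),
                shift_hn=hn,
                shift_co=float(row["CO_ppm"]),
                shift_ca=float(row["CA_ppm"]),
                amide_observable=bool(int(row["observable"])),
                aa_class=str(row["aa_class"]),
            )
        )
    return ShiftTable(residues=tuple(residues), axes=dict(axes or default_axes()))
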