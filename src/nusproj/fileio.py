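"""Text file formats: Sparky peak lists, NUS schedules, run artifacts.

Sparky lists are whitespace-separated with an ``Assignment`` column and
two or three frequency columns in ppm; comment lines start with ``#``.
NUS schedules are the common plain-text format: one space-separated
index tuple per line.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .acquisition import ExperimentGeometry, ModulatedDataset, SamplingSchedule
from .processing import Peak2D
from .spin_model import BasePeak, NucleusAxis, hz_to_ppm, ppm_to_hz

__all__ = [
    "SparkyParseError",
    "read_sparky_list",
    "write_sparky_list",
    "read_peak2d_list",
    "write_peak2d_list",
    "read_schedule",
    "write_schedule",
    "save_datasets",
    "load_datasets",
]


class SparkyParseError(ValueError):
    """Malformed Sparky list row; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _sparky_rows(path: str | Path, n_freqs: int):
    """Yield (line_no, label, freqs) from a Sparky-format list."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.split()[0].lower() == "assignment":
                continue
            parts = stripped.split()
            if len(parts) < 1 + n_freqs:
                raise SparkyParseError(path, line_no,
                                       f"expected label + {n_freqs} frequencies")
            try:
                freqs = [float(x) for x in parts[1:1 + n_freqs]]
            except ValueError:
                raise SparkyParseError(path, line_no,
                                       "non-numeric frequency value") from None
            rows.append((line_no, parts[0], freqs))
    if not rows:
        warnings.warn(f"empty peak list: {path}", stacklevel=2)
    return rows


def write_sparky_list(peaks: Sequence[BasePeak], path: str | Path,
                      axes: Mapping[str, NucleusAxis]) -> None:
    """Write an HNCO base list (CO_{i-1}, N_i, H_i^N columns, ppm)."""
    with open(path, "w") as fh:
        fh.write(f"{'Assignment':>16} {'w1':>11} {'w2':>11} {'w3':>11}\n")
        for p in peaks:
            co = hz_to_ppm(p.freq_co_prev, axes["CO"])
            n = hz_to_ppm(p.freq_n, axes["N"])
            hn = hz_to_ppm(p.freq_hn, axes["HN"])
            fh.write(f"{p.id:>16} {co:>11.6f} {n:>11.6f} {hn:>11.6f}\n")


def read_sparky_list(path: str | Path,
                     axes: Mapping[str, NucleusAxis]) -> list[BasePeak]:
    """Read an HNCO base list written by :func:`write_sparky_list`.

    The anchor residue is parsed from labels of the form ``A<i>``;
    other labels get a sequential anchor number.
    """
    peaks = []
    for k, (line_no, label, (co, n, hn)) in enumerate(_sparky_rows(path, 3)):
        try:
            anchor = int(label.lstrip("A"))
        except ValueError:
            anchor = k + 1
        peaks.append(BasePeak(
            id=label, anchor_residue=anchor,
            freq_co_prev=float(ppm_to_hz(co, axes["CO"])),
            freq_n=float(ppm_to_hz(n, axes["N"])),
            freq_hn=float(ppm_to_hz(hn, axes["HN"])),
        ))
    return peaks


def write_peak2d_list(peaks: Sequence[Peak2D], path: str | Path,
                      axes: Mapping[str, NucleusAxis]) -> None:
    """Write picked cross-section peaks as a 2D Sparky list.

    The label column is ``<anchor id>:<combination label>``; w1 is on
    the N ppm scale (the projection axis is conventionally labelled
    with the 15N scale even though it carries combination frequencies),
    w2 on the CO scale.  Intensity is kept as a trailing column.
    """
    with open(path, "w") as fh:
        fh.write(f"{'Assignment':>16} {'w1':>12} {'w2':>12} {'Height':>14}\n")
        for p in peaks:
            w1 = hz_to_ppm(p.position[0], axes["N"])
            w2 = hz_to_ppm(p.position[1], axes["CO"])
            fh.write(f"{p.anchor_id + ':' + p.label:>16} {w1:>12.6f} "
                     f"{w2:>12.6f} {p.intensity:>14.6e}\n")


def read_peak2d_list(path: str | Path,
                     axes: Mapping[str, NucleusAxis]) -> list[Peak2D]:
    """Read a 2D cross-section peak list written by :func:`write_peak2d_list`."""
    peaks = []
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.split()[0].lower() == "assignment":
                continue
            parts = stripped.split()
            if len(parts) < 4:
                raise SparkyParseError(path, line_no, "expected label w1 w2 height")
            label = parts[0]
            if ":" not in label:
                raise SparkyParseError(path, line_no, "label must be anchor:combo")
            anchor_id, combo = label.rsplit(":", 1)
            try:
                w1, w2, height = (float(x) for x in parts[1:4])
            except ValueError:
                raise SparkyParseError(path, line_no, "non-numeric value") from None
            peaks.append(Peak2D(
                position=(float(ppm_to_hz(w1, axes["N"])),
                          float(ppm_to_hz(w2, axes["CO"]))),
                intensity=height, anchor_id=anchor_id, label=combo))
    return peaks


def write_schedule(schedule: SamplingSchedule, path: str | Path) -> None:
    """One space-separated index tuple per line."""
    np.savetxt(path, schedule.indices, fmt="%d")


def read_schedule(path: str | Path, grid_sizes: tuple[int, int, int, int],
                  seed: int | None = None) -> SamplingSchedule:
    """Read a plain-text schedule; grid sizes come from the geometry."""
    idx = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return SamplingSchedule(indices=idx, grid_sizes=tuple(grid_sizes), seed=seed)


def save_datasets(datasets: Mapping[str, ModulatedDataset], outdir: str | Path,
                  meta: dict | None = None) -> None:
    """One binary array container per modulation label plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar = {"labels": sorted(datasets), "meta": meta or {}}
    for lab, ds in datasets.items():
        name = lab or "5d"
        np.save(outdir / f"data_{name}.npy", ds.data)
        sidecar[f"domain_{name}"] = ds.domain
    (outdir / "datasets.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_datasets(outdir: str | Path) -> dict[str, ModulatedDataset]:
    """Inverse of :func:`save_datasets` (time-domain datasets only)."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "datasets.json").read_text())
    out = {}
    for lab in sidecar["labels"]:
        name = lab or "5d"
        data = np.load(outdir / f"data_{name}.npy")
        out[lab] = ModulatedDataset(label=lab, data=data,
                                    domain=sidecar[f"domain_{name}"])
    return out
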