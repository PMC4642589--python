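"""Frequency decoding of sign-combination peaks and sequential linking.

Each co-added combination spectrum places its single peak at a signed
linear combination of the predecessor frequencies,

    f(s1)      = Omega_N + s1 * a * Omega_H                (one projection)
    f(s1, s2)  = Omega_N + s1 * a * Omega_H + s2 * b * Omega_CA,

with a = t5max/t1max and b = t6max/t1max.  With one projected dimension
the two observations determine (Omega_N, Omega_H) exactly; with two,
the four observations overdetermine three unknowns and are solved by
equal-weight least squares (closed form, since the sign columns are
orthogonal).  The decoded predecessor triple (Omega_N, Omega_H and the
CO_{i-2} position read directly off the second axis) is then matched
against the HNCO base list to chain anchors sequentially: each anchor's
decoded predecessor should coincide with exactly one other anchor's own
(N, H^N, CO_{i-1}) coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .acquisition import ExperimentGeometry
from .processing import CrossSection, Peak2D, combination_labels, pick_peaks
from .spin_model import BasePeak, NucleusAxis, ShiftTable, hz_to_ppm

__all__ = [
    "DecodedSpinFreqs",
    "AssignmentChain",
    "decode_6d",
    "decode_7d",
    "decode_anchor",
    "design_rank",
    "link_sequential",
    "ca_class_hint",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class DecodedSpinFreqs:
    """Decoded predecessor frequencies (Hz offsets) of one anchor."""

    anchor_id: str
    omega_n: float
    omega_h: float | None = None
    omega_ca: float | None = None
    omega_co_prev2: float | None = None
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual must be non-negative")


def decode_6d(f_plus: float, f_minus: float,
              geometry: ExperimentGeometry, anchor_id: str = "") -> DecodedSpinFreqs:
    """Invert the two-combination sign system (exactly determined)."""
    a = geometry.ratio_h
    if a <= 0:
        raise ValueError("ratio_h must be positive")
    return DecodedSpinFreqs(
        anchor_id=anchor_id,
        omega_n=(f_plus + f_minus) / 2.0,
        omega_h=(f_plus - f_minus) / (2.0 * a),
        residual_rms=0.0,
    )


def decode_7d(f: dict[str, float], geometry: ExperimentGeometry,
              anchor_id: str = "") -> DecodedSpinFreqs:
    """Equal-weight least-squares inversion of the four-combination system.

    ``f`` maps the labels ``++ + - - + --`` to the observed peak
    frequencies.  The design rows are (1, s1*a, s2*b); because the sign
    columns are mutually orthogonal the least-squares solution has the
    closed form below, and the residual is nonzero only for
    inconsistent observations.
    """
    a, b = geometry.ratio_h, geometry.ratio_ca
    if a <= 0 or b <= 0:
        raise ValueError("ratio_h and ratio_ca must be positive")
    try:
        fpp, fpm, fmp, fmm = f["++"], f["+-"], f["-+"], f["--"]
    except KeyError as e:
        raise ValueError(f"missing combination label {e.args[0]!r}") from None
    omega_n = (fpp + fpm + fmp + fmm) / 4.0
    omega_h = (fpp + fpm - fmp - fmm) / (4.0 * a)
    omega_ca = (fpp - fpm + fmp - fmm) / (4.0 * b)
    design = np.array([[1, a, b], [1, a, -b], [1, -a, b], [1, -a, -b]], dtype=float)
    resid = np.array([fpp, fpm, fmp, fmm]) - design @ (omega_n, omega_h, omega_ca)
    return DecodedSpinFreqs(
        anchor_id=anchor_id, omega_n=omega_n, omega_h=omega_h, omega_ca=omega_ca,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )


def design_matrix(dimensionality: int,
                  ratio_h: float = 2.0 / 3.0,
                  ratio_ca: float = 52.0 / 30.0) -> np.ndarray:
    """Full signed design matrix of the sign system.

    All sign choices of the row (1, a[, b]) are enumerated: 4 rows for
    one projected dimension, 8 for two.  Both branches of the overall
    sign are included, which is why the row count doubles the number of
    distinguishable combination spectra.
    """
    if dimensionality == 6:
        cols = (1.0, ratio_h)
    elif dimensionality == 7:
        cols = (1.0, ratio_h, ratio_ca)
    else:
        raise ValueError("dimensionality must be 6 or 7")
    return np.array([[s * c for s, c in zip(signs, cols)]
                     for signs in itertools.product((1, -1), repeat=len(cols))])


def design_rank(dimensionality: int) -> int:
    """Rank of the full signed design matrix (2 for 6D, 3 for 7D)."""
    return int(np.linalg.matrix_rank(design_matrix(dimensionality)))


def decode_anchor(sections: dict[str, CrossSection], geometry: ExperimentGeometry,
                  anchor: BasePeak,
                  threshold_fraction: float = 0.15) -> DecodedSpinFreqs | None:
    """Decode one anchor from its co-added combination cross-sections.

    Each combination contributes the position of its single strongest
    peak.  Returns None (decoding skipped) when any combination has no
    peak above threshold.  The CO_{i-2} coordinate is the mean of the
    second-axis positions across combinations.
    """
    labels = combination_labels(geometry.dimensionality)
    pos1, pos2 = {}, []
    for lab in labels:
        peaks = pick_peaks(sections[lab], threshold_fraction)
        if not peaks:
            return None
        best = peaks[0]
        pos1[lab] = best.position[0]
        pos2.append(best.position[1])
    co_prev2 = float(np.mean(pos2))
    if geometry.dimensionality == 6:
        d = decode_6d(pos1["+"], pos1["-"], geometry, anchor.id)
    else:
        d = decode_7d(pos1, geometry, anchor.id)
    return DecodedSpinFreqs(anchor_id=d.anchor_id, omega_n=d.omega_n,
                            omega_h=d.omega_h, omega_ca=d.omega_ca,
                            omega_co_prev2=co_prev2,
                            residual_rms=d.residual_rms)


def decode_from_peaks(peaks: list[Peak2D], geometry: ExperimentGeometry,
                      min_intensity_fraction: float | None = 0.3
                      ) -> list[DecodedSpinFreqs]:
    """Decode all anchors from a flat picked-peak list.

    Peaks are grouped by anchor; within each anchor and combination
    label the strongest peak is used.  Anchors missing any combination
    label are skipped.  Because peak picking thresholds within each
    cross-section, an anchor without a sequential component still
    yields "peaks" from leakage of neighbouring components; anchors
    whose strongest peak falls below ``min_intensity_fraction`` of the
    median strongest-peak intensity across anchors are therefore
    skipped as empty.  Output is sorted by anchor id.
    """
    labels = combination_labels(geometry.dimensionality)
    grouped: dict[str, dict[str, Peak2D]] = {}
    for pk in peaks:
        best = grouped.setdefault(pk.anchor_id, {}).get(pk.label)
        if best is None or abs(pk.intensity) > abs(best.intensity):
            grouped[pk.anchor_id][pk.label] = pk
    floor = 0.0
    if min_intensity_fraction and grouped:
        strongest = [max(abs(p.intensity) for p in by_label.values())
                     for by_label in grouped.values()]
        floor = min_intensity_fraction * float(np.median(strongest))
    out = []
    for anchor_id in sorted(grouped):
        by_label = grouped[anchor_id]
        if any(lab not in by_label for lab in labels):
            continue
        if max(abs(p.intensity) for p in by_label.values()) < floor:
            continue
        pos1 = {lab: by_label[lab].position[0] for lab in labels}
        co_prev2 = float(np.mean([by_label[lab].position[1] for lab in labels]))
        if geometry.dimensionality == 6:
            d = decode_6d(pos1["+"], pos1["-"], geometry, anchor_id)
        else:
            d = decode_7d(pos1, geometry, anchor_id)
        out.append(DecodedSpinFreqs(anchor_id=anchor_id, omega_n=d.omega_n,
                                    omega_h=d.omega_h, omega_ca=d.omega_ca,
                                    omega_co_prev2=co_prev2,
                                    residual_rms=d.residual_rms))
    return out


@dataclass(frozen=True)
class AssignmentChain:
    """Maximal sequential walk of base-peak ids (successor direction)."""

    peak_ids: tuple[str, ...]
    link_distances: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise ValueError("chain revisits a peak")


@dataclass(frozen=True)
class LinkReport:
    """Result of sequential matching over all decoded anchors."""

    chains: tuple[AssignmentChain, ...]
    links: dict[str, str]                     # anchor id -> predecessor id
    link_distances: dict[str, tuple[float, float, float]]
    candidate_counts: dict[str, int]
    ambiguities: tuple[str, ...]              # anchors withheld (multi-match)


def link_sequential(decoded: list[DecodedSpinFreqs], base: list[BasePeak],
                    tolerances: tuple[float, float, float] = (6.0, 8.0, 6.0),
                    greedy: bool = False) -> LinkReport:
    """Match decoded predecessor triples to base peaks and build chains.

    For each decoded anchor the (Omega_N, Omega_H, CO_{i-2}) triple is
    compared against every other base peak's (N, H^N, CO_{i-1}) with
    per-dimension tolerance gates (Hz).  A unique candidate creates a
    predecessor link; multiple candidates are recorded as an ambiguity
    and the link withheld, unless ``greedy`` resolves to the nearest
    candidate.  Chains are the maximal simple paths of the resulting
    predecessor graph, reported in successor direction, deterministic.
    """
    tol_n, tol_h, tol_co = tolerances
    if min(tolerances) <= 0:
        raise ValueError("tolerances must be positive")
    by_id = {p.id: p for p in base}
    links: dict[str, str] = {}
    dists: dict[str, tuple[float, float, float]] = {}
    counts: dict[str, int] = {}
    ambiguous: list[str] = []
    for d in decoded:
        if d.omega_h is None or d.omega_co_prev2 is None:
            continue
        cands = []
        for p in base:
            if p.id == d.anchor_id:
                continue
            dn = abs(d.omega_n - p.freq_n)
            dh = abs(d.omega_h - p.freq_hn)
            dc = abs(d.omega_co_prev2 - p.freq_co_prev)
            if dn <= tol_n and dh <= tol_h and dc <= tol_co:
                cands.append((p.id, (dn, dh, dc)))
        counts[d.anchor_id] = len(cands)
        if len(cands) == 1 or (greedy and len(cands) > 1):
            cands.sort(key=lambda c: (np.hypot(np.hypot(c[1][0], c[1][1]), c[1][2]), c[0]))
            links[d.anchor_id] = cands[0][0]
            dists[d.anchor_id] = cands[0][1]
            if len(cands) > 1:
                ambiguous.append(d.anchor_id)
        elif len(cands) > 1:
            ambiguous.append(d.anchor_id)
    # successor map; drop conflicting outgoing edges (two anchors
    # claiming the same predecessor) to keep paths simple
    succ: dict[str, str] = {}
    conflict: set[str] = set()
    for anchor, pred in sorted(links.items()):
        if pred in succ:
            conflict.add(pred)
        else:
            succ[pred] = anchor
    for pred in conflict:
        claimed = sorted(a for a, p in links.items() if p == pred)
        ambiguous.extend(claimed)
        for a in claimed:
            links.pop(a)
            dists.pop(a, None)
        succ.pop(pred, None)
    heads = sorted(set(succ) - set(links), key=lambda pid: by_id[pid].anchor_residue
                   if pid in by_id else 0)
    chains = []
    for head in heads:
        ids, dd = [head], []
        seen = {head}
        while ids[-1] in succ:
            nxt = succ[ids[-1]]
            if nxt in seen:
                break
            dd.append(dists[nxt])
            ids.append(nxt)
            seen.add(nxt)
        chains.append(AssignmentChain(peak_ids=tuple(ids), link_distances=tuple(dd)))
    return LinkReport(chains=tuple(chains), links=links, link_distances=dists,
                      candidate_counts=counts,
                      ambiguities=tuple(sorted(set(ambiguous))))


def ca_class_hint(omega_ca: float, axis: NucleusAxis,
                  glycine_max_ppm: float = 50.0) -> str:
    """Residue-type hint from the decoded CA frequency.

    Glycine CA shifts sit well upfield of all other residue types, so a
    CA below ``glycine_max_ppm`` (strict) is flagged glycine-like.
    """
    ppm = float(hz_to_ppm(omega_ca, axis))
    return "glycine-like" if ppm < glycine_max_ppm else "generic"


@dataclass(frozen=True)
class RecoveryMetrics:
    """Ground-truth scoring of sequential linking on synthetic data."""

    expected_links: int
    correct_links: int
    false_links: int
    ambiguity_count: int

    @property
    def fraction_correct(self) -> float:
        return 0.0 if self.expected_links == 0 else self.correct_links / self.expected_links


def evaluate_recovery(report: LinkReport, base: list[BasePeak],
                      table: ShiftTable) -> RecoveryMetrics:
    """Score links against the generating truth.

    A link i -> j is correct iff j's anchor residue is i's minus one.
    The expected-link denominator counts anchors whose predecessor
    residue is itself an anchor in the base list.
    """
    anchor_of = {p.id: p.anchor_residue for p in base}
    anchors = set(anchor_of.values())
    expected = sum(1 for p in base if (p.anchor_residue - 1) in anchors)
    correct = sum(1 for i, j in report.links.items()
                  if anchor_of[j] == anchor_of[i] - 1)
    false = len(report.links) - correct
    return RecoveryMetrics(expected_links=expected, correct_links=correct,
                           false_links=false,
                           ambiguity_count=len(report.ambiguities))
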