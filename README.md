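# nusproj

Simulation and processing toolkit for six- and seven-dimensional
projection-NUS NMR experiments used in backbone resonance assignment of
intrinsically disordered proteins (IDPs).

IDPs average their chemical shifts over fast conformational exchange,
so amide spectra crowd into a few tenths of a ppm and conventional
triple-resonance assignment stalls on overlap.  High-dimensionality
experiments fight this by correlating each amide anchor — the HNCO
coordinates (CO_{i-1}, N_i, H_i^N) — with the *predecessor's* N, CO,
H^N and CA frequencies in a single experiment.  Two tricks keep such
experiments practical:

- **Non-uniform sampling (NUS):** only a sparse random subset of the
  four-dimensional indirect time grid is acquired, and 2D
  cross-sections are computed by a sparse multidimensional Fourier
  transform (SMFT) with three dimensions fixed at each HNCO base-peak
  position.
- **Projection spectroscopy:** the predecessor H^N (6D) and CA (7D)
  evolutions are incremented in fixed ratios a = t5max/t1max,
  b = t6max/t1max with t1, so each cross-section peak appears at a
  signed combination

      f(s1, s2) = Ω_N + s1·a·Ω_H + s2·b·Ω_CA .

  Recording cosine/sine-modulated datasets and co-adding them isolates
  one sign combination per spectrum; the 2 (6D) or 4 (7D) single-peak
  positions are inverted for (Ω_N, Ω_H[, Ω_CA]) by equal-weight least
  squares.  Sequential chains then follow from matching each decoded
  predecessor triple to another anchor's own HNCO coordinates
  ("HNCO-HNCO" linking).

`nusproj` implements the whole loop on synthetic IDP chains: shift
table and HNCO base list generation, coherence-transfer amplitudes
versus the N–CA delay, sparse time-domain simulation with the
cos/sin modulation bookkeeping, SMFT processing with sign-combination
co-addition and peak picking, frequency decoding, sequential linking
and ground-truth scoring.  It is a library first (`import nusproj`,
see `examples/`), with a thin `nusproj` CLI over the same stages
(`simulate`, `process`, `decode`, `assign`, `evaluate`,
`transfer-scan`, `run`).

## Worked example

`examples/separation_patterns.py` simulates one sequential correlation
(predecessor offsets Ω_N = +60 Hz, Ω_H = −80 Hz, projection ratio
a = 2/3) in the 6D experiment on a fully sampled desk-scale grid and
prints:

```
section 'c': 2 peak(s) at omega1 =    +6.6,  +113.4 Hz
section 's': 2 peak(s) at omega1 =    +6.6,  +113.4 Hz
section '+': 1 peak(s) at omega1 =    +6.6 Hz
section '-': 1 peak(s) at omega1 =  +113.4 Hz

decoded predecessor: Omega_N = +60.0 Hz, Omega_H = -80.1 Hz
ground truth:        Omega_N =  +60.0 Hz, Omega_H =  -80.0 Hz
```

Both raw modulated sections show the peak at both combination
positions 60 ± (2/3)·80 ∈ {+6.7, +113.3} Hz; the co-added sections
contain one each, and the half-sum/half-difference of their refined
positions recovers the predecessor frequencies to a tenth of a hertz.

`examples/full_assignment_run.py` runs the full pipeline on a
20-residue chain with one proline and one exchange-broadened N-terminal
residue and prints the recovery block of the run summary:

```
"recovery": {
  "expected_links": 16,
  "correct_links": 16,
  "false_links": 0,
  "ambiguity_count": 0,
  "fraction_correct": 1.0
}
```

`examples/transfer_delay_scan.py` and `examples/decode_sign_systems.py`
cover the transfer-amplitude optimum (|I_seq| ≈ 0.876 near 57 ms,
≈8× auto-peak suppression at the 54 ms working point) and the algebra
of the sign systems (4 rows/rank 2 in 6D, 8 rows/rank 3 in 7D).

The published acquisition geometries ship as presets:

```python
from nusproj.config import RunConfig
cfg = RunConfig.preset("800MHz-7D")   # or 800MHz-6D, 600MHz-6D
```

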