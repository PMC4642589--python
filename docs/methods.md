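# Methods

## Problem and model

Backbone assignment of intrinsically disordered proteins (IDPs) by NMR
is limited by chemical-shift crowding: fast conformational averaging
compresses the amide-proton dispersion to a few tenths of a ppm, so
conventional triple-resonance spectra overlap severely.  One remedy is
to raise the dimensionality of the experiment: correlate each amide
anchor (CO_{i-1}, N_i, H_i^N, the HNCO coordinates) not only with the
predecessor's N and CO but also with the predecessor's amide proton
(6D) and CA (7D).  Every sequential cross-peak then carries a
six/seven-frequency fingerprint, and chaining anchors ("HNCO-HNCO"
matching) becomes nearly unambiguous.

`nusproj` implements a faithful software analogue of this experiment
family:

1. **Spin model** — a synthetic per-residue shift table (N, H^N, CO,
   CA) emulating an IDP, with prolines (no amide proton) and
   exchange-broadened N-terminal residues as options; the derived HNCO
   base peak list anchors all later processing.
2. **Transfer model** — the coherence-transfer amplitudes of the
   N→CA→CO step as trigonometric products of the ΔN–CA delay t:

       I_auto ∝  cos(πJ₁t) cos(πJ₂t) cos(πJ₃t)
       I_seq  ∝ −sin(πJ₁t) sin(πJ₂t) cos(πJ₃t)

   with J₁ = ¹J_NCA = 11 Hz, J₂ = ²J_NCA = 7 Hz, J₃ = ¹J_CACB = 35 Hz.
   At t = 54 ms the sequential amplitude is ≈0.835 while the
   auto-correlation amplitude is suppressed ≈8-fold, so the simulator
   defaults to sequential-only spectra at that delay.  The unconstrained
   maximum of |I_seq| on a 20–80 ms grid lies at ≈56.6 ms; 54 ms is the
   joint intensity/suppression compromise, and the package reports both
   rather than claiming a single optimum.
3. **Acquisition** — four indirect dimensions (N_{i-1}, CO_{i-2},
   CO_{i-1}, N_i) sampled on a sparse random (NUS) subset of the time
   grid; the predecessor H^N and CA evolutions are *coevolved*:
   incremented proportionally to t1 with ratios a = t5max/t1max and
   b = t6max/t1max, so their frequencies project onto the t1 axis as
   Ω_N ± aΩ_H (± bΩ_CA).  Each projected dimension doubles the number
   of stored datasets (cosine and sine amplitude-modulated); the π/2
   phase compensation applied with each sine modulation is represented
   by the factor i·sinθ, so downstream separation is a plain signed
   co-addition.
4. **Processing (SMFT)** — the sparse multidimensional Fourier
   transform evaluates each anchor's 2D cross-section (projection axis
   × CO_{i-2}) directly from the NUS samples, with CO_{i-1} and N_i
   fixed at the anchor's base-list frequencies and the direct dimension
   sliced at the channel nearest the anchor's H^N.
5. **Decoding** — the co-added combination spectra place one peak each
   at f(s₁[,s₂]) = Ω_N + s₁aΩ_H (+ s₂bΩ_CA).  Two observations solve
   the one-projection system exactly; the four observations of the
   two-projection system are solved by equal-weight least squares
   (closed form — the sign columns are orthogonal), with the residual
   RMS reported as a consistency diagnostic.  The full signed design
   matrix (both overall-sign branches) has 4 rows of rank 2, or 8 rows
   of rank 3.
6. **Assignment** — each anchor's decoded predecessor triple
   (Ω_N, Ω_H, CO_{i-2}) is matched against every other anchor's own
   HNCO coordinates under per-dimension tolerance gates; unique matches
   become links, multi-matches are withheld as ambiguities (a `greedy`
   flag switches to nearest-match resolution), and maximal simple paths
   of the link graph are reported as chains.  On synthetic data,
   `evaluate_recovery` scores links against the generating truth.

## Quadrature idealization and absorption-mode processing

Indirect evolutions are simulated as complex analytic signals
(idealized quadrature — no States-TPPI mechanics, no RF-level detail).
A purely analytic 2D dataset, however, produces *phase-twist*
lineshapes: the real part of a product of two complex Lorentzians
contains a dispersion×dispersion term whose star-shaped wings reach
well above 10% of the peak and defeat both peak counting and accurate
position measurement.  The real experiment avoids this with per-
dimension quadrature; this package does the equivalent by storing both
helicities of the CO_{i-2} evolution (an echo/antiecho pair,
`data[k, 0|1, channel]` with phases e^{±iφ₂}).  The SMFT combines them
as ½(w_P e^{-iω₂t₂} + w_N e^{+iω₂t₂}), which turns the second output
axis into a real cosine transform and yields pure-absorption 2D
lineshapes.  A plain single-helicity dataset is still accepted and
transforms in simple P-type mode; the FFT-equivalence tests use that
path.

Three further processing choices matter for fidelity:

- **Apodization.** A cosine (90°-shifted sine-bell) window is applied
  to all four processed time axes by default, with the standard half
  weight on the t = 0 samples of the two transformed axes.  This keeps
  truncation sidelobes below ~7% of the main peak (so single-component
  sections show exactly their sign images above a 10% threshold) and
  suppresses leakage of components mismatched in the fixed dimensions.
  `apodization=None` disables it (used by the FFT-oracle tests).
- **Autophase.** The direct-dimension channel nearest the anchor's
  H^N is generally off the true amide frequency by up to half a bin;
  its complex response multiplies the whole cross-section by one
  constant whose dispersive admixture would bias peak positions by
  several Hz.  A zero-order autophase removes it, with the phase
  estimated by the doubled-angle statistic φ = ½·arg Σ|F|²F² (exact at
  peaks regardless of their signs, insensitive to dispersive tails)
  and the residual ±π ambiguity resolved by making the strongest peak
  positive.  `phase_correct=None` disables it for linearity tests.
- **Zero-filling.** The direct FID is zero-filled ×4 before its DFT so
  that nearest-channel slicing loses little amplitude to channel
  quantization; without it a component sitting half a channel off can
  lose ~45% intensity, enough for a leaking neighbour to out-compete
  it in a crowded spectrum.

## Peak picking and decoding details

Peaks are strict 3×3 local maxima of |intensity| above a configurable
fraction of each section's global maximum (default 0.15 in the
pipeline; the separation-pattern counts use the 0.10 convention), with
per-axis three-point parabolic refinement; on noiseless single
components the refined positions are accurate to a few percent of a
grid step.  Each combination section contributes its single strongest
peak to decoding.  Because thresholds are per-section, an anchor with
no sequential component (first anchors, successors of prolines or of
exchange-broadened residues) still yields leakage "peaks"; anchors
whose strongest peak is below 0.3× the median strongest-peak intensity
across anchors are skipped as empty before decoding.

The output ω₁ grid is sized to ≈11 Hz per bin from the projected
bandwidth (256 points for the 6D defaults, 1024 for 7D, power of two),
with 128 points across the CO width; the t1 dwell itself is derived
from the projected bandwidth sw_N + a·sw_H (+ b·sw_CA) so that
combination frequencies never alias.

## Study conditions (defaults) and their provenance

- Evolution-time sets: 20/30/25/52/25/30 ms (7D, 800 MHz),
  20/30/25/25/30 ms (6D, 800 MHz), 20/40/40/40/40 ms (6D, 600 MHz) —
  the published acquisition geometries, shipped as presets
  `800MHz-7D`, `800MHz-6D`, `600MHz-6D`; projection ratios follow as
  a = 2/3 (b = 52/30), a = 2/3, and a = 1/2.
- J couplings 11/7/35 Hz; ΔN–CA = 54 ms.
- Shift distributions (ppm): N ~ N(118.5, 3.5²), H^N ~ N(8.25, 0.15²),
  CO ~ N(175.5, 1.2²), CA ~ N(55.0, 3.0²) with a glycine class
  N(45.2, 0.8²) at 12% frequency — IDP-like crowding with the narrow
  amide and carbonyl dispersion that motivates the method.  Draws are
  truncated-resampled into the spectral windows.
- Axes (800 MHz): base frequencies H 800.13 / N 81.08 / C 201.19 MHz;
  carriers H 8.3 / N 118.0 / CO 175.5 / CA 54.0 ppm; widths N 2000,
  CO 1500, H^N 1600, CA 4800 Hz.  The H^N and CA widths are package
  choices sized to contain the shift distributions (including
  glycines); everything is config-overridable.
- NUS density: 5000 points (6D) / 6000 (7D), estimated from the
  published 13 h / 31 h acquisition times at ~1.15 s repetition, a
  4-step phase cycle and 2 / 4 modulation datasets.  The sampling
  distribution is uniform random without replacement (the t = 0 tuple
  always included); the generating schedule is reproducible by seed.
- Relaxation: a single exp(−t/T2) with T2 = 100 ms on every time axis
  (IDP-favourable); no pulse imperfections, no solvent signal, no
  J-evolution during pulses.
- Match gates: 6 Hz (N), 8 Hz (H^N), 6 Hz (CO).

## What the synthetic generator does and does not emulate

It reproduces the *geometry* of the assignment problem — crowding,
absent amide anchors (prolines, exchange broadening), the sequential
dependency structure, realistic Hz-scale separations at two field
strengths — with Gaussian, sequence-independent shifts.  It does not
model residue-specific shift statistics beyond the glycine CA class,
correlated shifts along the chain, differential relaxation, amide
exchange line broadening as a continuum, spectrometer artifacts, or
solvent/baseline distortions.  Passing recovery tests therefore show
that the acquisition-processing-decoding-linking chain is correct and
self-consistent under the stated conditions, not that a real IDP
sample would be assigned at the same rate.

## Verification problem sizes

The separation-pattern checks run a single spin system on a fully
sampled desk-scale geometry (t-max 48/35/20/18 ms over 500/400 Hz
windows; ≈46 k grid points in 6D, ≈93 k in 7D).  The end-to-end
recovery runs use a 140-residue chain with the first two residues
exchange-broadened, the 800 MHz 6D preset and 5000 NUS points,
noiseless and at a per-sample time-domain SNR of 20 (noise σ =
|I_seq(54 ms)|/20): all 137 expected sequential links are recovered
with no false links in both conditions, in well under a minute each.
A 7D run at the same chain size behaves identically with the 1024-
point ω₁ grid.  At 600 MHz the Hz-scale dispersion shrinks by a
quarter while the match gates stay fixed, and isolated link losses
(≈2/137) appear — the expected crowding penalty of the lower field.

## Known limitations

- The mirror branch (−Ω_N) of the sign systems is not enumerated: the
  complex-signal simulator fixes the overall sign by construction.
  Real-data mirror handling is out of scope.
- Ambiguous links are withheld, not resolved; the `greedy` flag is a
  blunt alternative.  No global (graph-consistent) matching is done.
- `decode_anchor`/`decode_from_peaks` use the strongest peak per
  combination; partially overlapping components can still pull peak
  positions by a few Hz, which is what the tolerance gates absorb.
- The 5D variant is simulated and processed but has no projected
  dimensions to decode; it exists as the degenerate base case.
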