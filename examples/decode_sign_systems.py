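"""The sign-combination systems and their least-squares inversion.

With one projected dimension the two combination frequencies determine
(Omega_N, Omega_H) exactly; with two, the four observed combinations
overdetermine three unknowns and are solved by equal-weight least
squares.  The full signed design matrix has rank 2 (one projection) or
rank 3 (two projections).
"""

from nusproj import (ExperimentGeometry, decode_6d, decode_7d, design_matrix,
                     design_rank)

g7 = ExperimentGeometry(7, 0.030, 0.025, 0.025, 0.030,
                        t5max_h=0.020, t6max_ca=0.052)
a, b = g7.ratio_h, g7.ratio_ca
print(f"projection coefficients: a = t5/t1 = {a:.4f}, b = t6/t1 = {b:.4f}")
print(f"design matrix rows/rank: one projection {design_matrix(6).shape[0]}/"
      f"{design_rank(6)}, two projections {design_matrix(7).shape[0]}/"
      f"{design_rank(7)}")

wn, wh, wca = 240.0, 150.0, 90.0
f = {"++": wn + a * wh + b * wca, "+-": wn + a * wh - b * wca,
     "-+": wn - a * wh + b * wca, "--": wn - a * wh - b * wca}
print(f"\nencoded combinations for (N, H, CA) = (240, 150, 90) Hz: "
      f"{ {k: round(v, 1) for k, v in f.items()} }")
d = decode_7d(f, g7)
print(f"decoded: N = {d.omega_n:.1f}, H = {d.omega_h:.1f}, CA = {d.omega_ca:.1f}"
      f" Hz (residual {d.residual_rms:.2e} Hz)")

f_noisy = dict(f, **{"++": f["++"] + 4.0})
d2 = decode_7d(f_noisy, g7)
print(f"\nafter perturbing f(++) by +4 Hz: N shifts {d2.omega_n - d.omega_n:+.2f},"
      f" H {d2.omega_h - d.omega_h:+.2f}, CA {d2.omega_ca - d.omega_ca:+.3f} Hz,"
      f" residual {d2.residual_rms:.2f} Hz")
print("(sensitivities 1/4, 1/(4a), 1/(4b); the residual flags inconsistency)")

d6 = decode_6d(340.0, 140.0, ExperimentGeometry(6, 0.030, 0.025, 0.025, 0.030,
                                                t5max_h=0.020))
print(f"\none-projection example: (f+, f-) = (340, 140) Hz -> "
      f"N = {d6.omega_n:.0f}, H = {d6.omega_h:.0f} Hz")
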