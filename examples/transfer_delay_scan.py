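"""Scan the N-CA transfer delay and locate the sequential-peak optimum.

The auto-correlation and sequential transfer amplitudes are products of
cosines/sines of the three relevant scalar couplings (11, 7, 35 Hz).
Around 54-57 ms the sequential amplitude is near its maximum while the
auto-correlation pathway is suppressed almost tenfold, which is why the
simulated experiments default to a 54 ms delay and sequential-only
peaks.
"""

from nusproj import auto_transfer, delay_scan, seq_transfer, suppression_ratio

scan = delay_scan(0.020, 0.080, 0.0001)
best = scan.attrs["argmax_abs_seq_s"]

print("delay   I_auto    I_seq")
for delay_ms in (28.6, 45.45, 54.0):
    t = delay_ms / 1e3
    print(f"{delay_ms:5.2f} ms  {auto_transfer(t):+7.4f}  {seq_transfer(t):+7.4f}")
print(f"\nmax |I_seq| on the grid: {scan.attrs['max_abs_seq']:.4f} "
      f"at {best * 1e3:.1f} ms")
print(f"suppression |I_seq/I_auto| at 54 ms: {suppression_ratio(0.054):.2f}")
print("\nAt 28.6 ms both pathways are comparable (the doubled-peak variant);")
print("at 45.45 ms the one-bond N-CA cosine nulls the auto pathway exactly;")
print("54 ms keeps ~95% of the best sequential amplitude with ~8x suppression.")
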