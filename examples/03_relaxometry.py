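"""Two-point dual-echo relaxometry: synthesize, invert, recover.

Synthesizes dual-echo signals (TE 12/73 ms) from known proton spin density
and T2, then inverts them with the two-point formulas:
T2app = (TE2-TE1)/ln(SI1/SI2),  rho = SI1*exp(TE1/T2app).
"""

import numpy as np

from nervequant import proton_density, synthesize_dual_echo, t2_apparent

group_rho = {"control": 288.0, "no_dpn": 323.0, "mild_moderate": 365.0,
             "severe": 360.0}
t2 = 60.0  # ms, common nerve T2

print(f"{'group':>14} {'rho in':>8} {'SI(12ms)':>9} {'SI(73ms)':>9} "
      f"{'T2 out':>7} {'rho out':>8}")
for group, rho in group_rho.items():
    si1, si2 = synthesize_dual_echo(rho, t2)
    t2_hat = t2_apparent(si1, si2)
    rho_hat = proton_density(si1, t2_hat)
    print(f"{group:>14} {rho:8.1f} {si1:9.2f} {si2:9.2f} "
          f"{t2_hat:7.2f} {rho_hat:8.1f}")

# With noiseless signals the two-point inversion is exact: the recovered
# spin densities equal the group means that generated the signals, and T2
# returns 60 ms for every group — density separates the groups, T2 does not.
rng = np.random.default_rng(0)
si1, si2 = synthesize_dual_echo(np.full(2000, 360.0), t2, noise_sd=3.0, rng=rng)
ok = (si1 > 0) & (si2 > 0)
t2v = t2_apparent(si1[ok], si2[ok])
valid = ~np.isnan(t2v)
rho_mean = proton_density(si1[ok][valid], t2v[valid]).mean()
print(f"\nwith Gaussian noise (sd 3): voxel-mean rho = {rho_mean:.1f} "
      f"(truth 360, {int(valid.sum())} valid voxels)")
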