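"""Force-velocity relation and unloaded shortening velocity.

Scans steady shortening for the linear and nonlinear elasticity variants
and finds the velocity where the mean cross-bridge force crosses zero.
"""

from crossbridge import find_vmax, force_velocity_scan, make_active_params

for variant in ("linear", "nonlinear"):
    p = make_active_params(variant)
    df = force_velocity_scan(p, [0, 1000, 3000, 6000, 9000])
    vmax = find_vmax(p)
    print(f"--- {variant} cross-bridge elasticity ---")
    print(df[["v", "F", "tension_kPa", "Na", "ATPase", "efficiency"]]
          .round(3).to_string(index=False))
    print(f"unloaded shortening velocity: {vmax:.0f} nm/s\n")
print("F is per myosin head (pN); Na is the attached fraction; ATPase the")
print("turnover per head. Force falls monotonically with velocity and the")
print("nonlinear variant keeps more heads attached while shortening fast.")
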