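# Default kinetic and energetic parameters of the active-contraction model
# (fast mammalian skeletal muscle actomyosin near 30 C, ionic strength
# > 100 mM).  version: 1
#
# Provenance per entry:
#   [printed]        value printed in the source model description
#   [reconstructed]  value not printed anywhere available; fixed here by
#                    physical constraints (free-energy bookkeeping, standard
#                    actomyosin biochemistry) and calibrated so the model
#                    reproduces the printed steady-state outputs (maximal
#                    shortening velocities, K_M^v values, isometric tension
#                    and strain).  See docs/methods.md.

# --- geometry of the attached-state free-energy minima (nm)
x1 = 7.7            # [printed] AMD_L minimum
x2 = 1.0            # [reconstructed] AMD_H minimum; main power stroke x1-x2,
                    # second (nucleotide-pocket) step x2-x3 ~ 1 nm
x3 = 0.0            # [reconstructed] AM/AMD minimum; k2(0) is the zero-strain
                    # detachment rate at this point

# --- weak-binding (MDP <-> AMDP) rapid equilibrium
dG_w = 2.5          # [printed] kBT, AMDP minimum below MDP
ksw = 0.2           # [reconstructed] pN/nm, very low AMDP stiffness (the
                    # weak-state free energy is nearly flat across the window)
x_w = 7.7           # [reconstructed] nm, aligned with the AMD_L minimum

# --- free-energy drops of the strong-binding steps (kBT); together with
#     dG_w they place the AM/AMD minimum 20 kBT below the detached state
#     [printed total; split reconstructed]
dG_AMDP_AMDL = 2.5
dG_AMDL_AMDH = 13.5
dG_AMDH_AM = 1.5

# --- attachment / phosphate step
kb0 = 15.0          # [reconstructed] 1/s, rate scale of the AMDP->AMDL step
K_C = 4.0           # [reconstructed] mM, phosphate dissociation constant
Pi = 0.5            # [reconstructed] mM, nominal contaminating phosphate

# --- power stroke
kLH_minus = 2000.0  # [printed] 1/s, strain-independent reversal rate

# --- second step (nucleotide-pocket opening, AMD_H -> AM/AMD)
k5_x2 = 500.0       # [reconstructed] 1/s, rate scale at the AMD_H minimum

# --- ATP-induced detachment (AM/AMD -> MT) and ADP/ATP handling
k2_0_linear = 1800.0     # [printed] 1/s, zero-force value, linear variant
k2_0_nonlinear = 1600.0  # [printed] 1/s, nonlinear variant
x_crit_linear = 0.6      # [printed] nm, Bell strain sensitivity (linear)
x_crit_nonlinear = 0.0   # [printed] nm, no strain dependence (nonlinear)
k6 = 5500.0         # [reconstructed] 1/s, ADP release
K1 = 1.7            # [reconstructed] 1/mM, MgATP binding equilibrium
MgATP = 5.0         # [reconstructed] mM, standard assay concentration

# --- detached-side hydrolysis (MT <-> MDP)
k_h = 300.0         # [reconstructed] 1/s, forward hydrolysis
K_H = 4.0           # [reconstructed] hydrolysis equilibrium constant

# --- nonlinearity of the AM/AMD drag-stroke segment
c_standard = 0.0255 # [printed] S_low = 0.1 pN/nm standard nonlinear case
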