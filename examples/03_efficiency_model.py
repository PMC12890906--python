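"""How the spore-to-cell cost ratio limits sporulation efficiency.

Runs the batch-culture model (vegetative cells grow on a depleting
resource and switch to sporulation as it runs out), sweeps the
spore-to-cell cost ratio C_s/C_v, and contrasts the batch outcome with
the chemostat variant, whose steady-state efficiency is cost-independent.
"""

import numpy as np

from sporenergy.efficiency import (
    EfficiencyModelParams,
    simulate_batch,
    simulate_chemostat,
    sweep_cost_ratio,
)

params = EfficiencyModelParams()
traj = simulate_batch(params)
print(f"batch run: resource exhausted at t = {traj.t[-1]:.1f} h")
print(f"  final cells  {traj.N_v[-1]:.3e} /mL")
print(f"  final spores {traj.N_s[-1]:.3e} /mL")
print(f"  sporulation efficiency phi = {traj.phi:.4f}")

balance = params.epsilon * (traj.R[0] - traj.R[-1])
built = params.C_v * ((traj.N_v[-1] - traj.N_v[0]) + traj.N_s[-1]) \
    + params.C_s * traj.N_s[-1]
print(f"  energy closure: consumed {balance:.4e} ATP vs built {built:.4e} ATP")

print("\nbatch efficiency vs spore-to-cell cost ratio:")
table = sweep_cost_ratio(params, ratios=np.linspace(0.5, 10.0, 9))
for _, row in table.iterrows():
    print(f"  C_s/C_v = {row['ratio']:5.2f}   phi = {row['phi']:.5f}")
print("phi declines monotonically: costlier spores drain the remaining")
print("resource faster, so fewer cells complete the transition.")

print("\nchemostat steady state (dilution 0.2 /h):")
for ratio in (1.2, 12.0):
    result = simulate_chemostat(params.with_cost_ratio(ratio))
    print(f"  C_s/C_v = {ratio:5.2f}   phi = {result.phi:.6f}")
print("steady-state phi is set by the rate balance alone, so a tenfold")
print("cost change leaves it unchanged -- costs only matter when the")
print("resource pool is finite.")
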