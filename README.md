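# sporenergy

Evolutionary bioenergetics of bacterial sporulation: a tested Python
library for estimating the ATP cost of making, maintaining, and reviving
a *Bacillus subtilis* endospore, and for asking what those costs imply
for populations and for the long-term evolutionary fate of the trait.

It is written for microbial ecologists and evolutionary biologists who
want cellular energy budgets in a common currency — ATP-equivalents —
rather than oxygen consumption or heat, and who want the downstream
population-dynamic and population-genetic consequences computed from the
same numbers.

## What it computes

**Cost accounting.** Every expenditure is split into a direct cost P_D
(ATP hydrolysis powering activation, charging, polymerization) and an
opportunity cost P_O (the energetic value of precursor molecules diverted
from growth), with P_T = P_D + P_O. Closed forms cover:

- genome replication: `C_RD = 2·L_g·(c̄_s + c_p) + L_g·(c_hel + c_prim)`,
  `C_RO = 2·L_g·c̄_o`, with 11 + 2 P_D and 34 P_O per nucleotide, 1 and
  0.32 P_D per bp for helicase and primers;
- transcription: one-time nucleotide synthesis (10 P_D, 31.5 P_O per nt,
  charged once per transcript under efficient recycling) plus
  time-resolved polymerization (2 + 0.1 P_D per nt) distributed over
  expression-weighted hour bins; transcript demand follows from protein
  abundance via `N_mRNA = (ppm/10⁶ · P_total)/Y` with Y = 100;
- translation: 4 P_D per incorporated amino acid, 2 P_D per completed
  chain, per-residue opportunity costs (bacterial mean 25 P_O);
- membranes: lipid counts from spherocylinder or flat-disc bilayer areas
  at 0.65 nm² per headgroup, 18 P_D + 212 P_O per lipid; spore revival
  remakes 30% of the membrane with 1/6 of the lipid cost recycled.

**Temporal ledgers.** Costs are booked per (interval, category) for the
sporulation program (hour bins t0–t8) and revival (15 min germination +
outgrowth intervals), with mother/forespore attribution, cumulative-cost
queries (how much is sunk by the ~2 h commitment point), per-generation
head-to-head comparison of traits against the cellular budget
C_total = C_G + t_gen·C_M ≈ 9.4×10¹⁰ ATP, and the break-even time
t* = P_T(spore cycle)/C_M.

**Sporulation efficiency.** A batch-culture ODE model where vegetative
cells (N_v) grow on a depleting resource (R) and initiate sporulation
(N_s) through a sigmoidal switch f(R) = 1/(1 + e^{σ(R−R_min)}), with
ATP-parameterized yields Y_v = ε/C_v, Y_s = ε/C_s. Terminal efficiency
φ = N_s/(N_v + N_s) declines monotonically in the spore-to-cell cost
ratio; the chemostat variant's steady-state φ is cost-independent.

**Evolutionary maintenance.** Unexpressed sporulation DNA still costs
ATP to replicate, so a deletion of Δ bp carries advantage
s(Δ) = (c_n/C_cell)·Δ with c_n ≈ 50 ATP. The fixation rate of such
deletions relative to neutral substitutions,

    d_del/d_sub = [2N_e s / (1 − e^{−2N_e s})] · (U_del/U_sub),

equals U_del/U_sub ≈ 0.179 at neutrality and crosses 1 at Δ ≈ 86 bp for
N_e = 6.119×10⁷ — a gene-sized (~1 kb) deletion is strongly favored.
A seeded Wright–Fisher simulation independently checks the closed-form
fixation probability.

**Synthetic data.** Seeded generators emulate every input shape the
pipeline consumes (annotation tables, ppm abundances, stage-peaked
expression waves, cumulative revival scores, efficiency compilations,
deletion-size spectra), so the full analysis runs and is tested without
any download.

## Worked example

```python
from sporenergy import (replication_cost, membrane_cost, septum_cost,
                        revival_membrane_cost, break_even, fixation_ratio,
                        threshold_deletion_size, GENOME_LENGTH_BP)

rep = replication_cost(GENOME_LENGTH_BP)
print(f"{rep.total:.3e}")          # 4.018e+08  ATP to replicate the genome
print(f"{septum_cost(1.0)[1].total:.3e}")   # 2.779e+08  ATP for the septum
mem = membrane_cost()[1]
print(f"{mem.total:.3e}")          # 2.764e+09  ATP for the full membrane
print(f"{revival_membrane_cost(mem).total:.3e}")  # 6.909e+08  net revival membrane
print(f"{break_even(9.2e9, 1.2e9):.1f}")    # 7.7  hours to amortize the spore cycle
print(f"{fixation_ratio(1000):.2f}")        # 11.66  a 1 kb deletion fixes ~12x
                                            # faster than a neutral substitution
print(threshold_deletion_size())            # 86  bp: smallest selectively
                                            # favored deletion
```

Replicating the genome costs ~4×10⁸ ATP and the septum ~2.8×10⁸ — small
next to the ~10¹⁰-ATP spore cycle, which a dormant cell amortizes against
vegetative maintenance (1.2×10⁹ ATP/h) in under 8 hours. When sporulation
is unused, the same bookkeeping makes gene-sized deletions visible to
selection.

The scripts in `examples/` each exercise one capability end to end
(cost primitives, temporal ledgers on synthetic data, the efficiency
model, the deletion-fixation model) and print annotated output. A thin
CLI mirrors the pipeline: `sporenergy synth`, `ingest`, `cost`, `ledger`,
`breakeven`, `simulate`, `evolve`.

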