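# Methods

## Accounting conventions

All energy is expressed in ATP-equivalents ("P"): one high-energy
phosphate hydrolysis event, with GTP counted 1:1. Costs are partitioned
into **direct** (P_D: hydrolysis powering activation, charging, and
polymerization) and **opportunity** (P_O: the energetic value of
precursor synthesis diverted from growth), with P_T = P_D + P_O as an
exact floating-point identity on every `CostPair` the library returns.
P_T is the headline number under balanced growth; P_D alone matters for
instantaneous power, and P_O alone when monomers can be recycled.

Counts (transcripts, protein copies, base pairs) are continuous expected
values end to end; nothing is rounded mid-pipeline. Reported headline
totals are rounded to two significant figures, the precision at which
such estimates are meaningful. Budget constants are 20 °C values for
*B. subtilis* (generation time 1.16 h, maintenance 1.2×10⁹ ATP h⁻¹,
per-generation budget 9.4×10¹⁰ ATP) held in a single registry
(`sporenergy.constants`) so alternates can be swapped in one place; the
stored growth cost C_G is defined as C_total − t_gen·C_M so the budget
identity holds exactly at defaults. Temperature is not a model input.

Processes cheaper than ~10⁵ ATP (posttranslational modification, folding,
proofreading, ligation) are excluded throughout.

## Cost primitives

**Replication.** For a genome of L_g bp, both daughter strands are newly
synthesized: C_RD = 2L_g(c̄_s + c_p) + L_g(c_hel + c_prim) with
c̄_s = 11 P_D and c_p = 2 P_D per nucleotide, c_hel = 1 and
c_prim = 0.32 P_D per bp; C_RO = 2L_g·c̄_o with c̄_o = 34 P_O per
nucleotide (the 34 is a composite of ~33 P_O precursor synthesis plus
conversion; it is used as a single constant because the conversion
component is not itemized separately). At defaults this is 27.32 P_D +
68 P_O per genomic bp. Costs of genome subsets scale linearly.

**Transcription.** Nucleotide synthesis is charged once per transcript
(efficient recycling): 10 P_D and 31.5 P_O per nt on length × count.
Polymerization (2 P_D/nt elongation + 0.1 P_D/nt supercoil relief) is
paid every time a transcript is made and is distributed over time by
per-gene weight vectors proportional to measured expression. The
supercoil overhead is applied to all transcripts costed here; whether it
should exempt stable RNAs is unresolved, but stable RNAs do not enter the
ledgers in any case (gene counts are CDS-based). Transcript demand comes
from protein abundance: N_mRNA = (ppm/10⁶ · P_total)/Y with
P_total = 1,774,445 proteins per cell and a representative yield Y = 100
proteins per mRNA lifetime. Because the yield fixes transcript numbers
and timing, no separate mRNA degradation term is included (it would
double-count).

**Translation.** 4 P_D per incorporated amino acid (charging +
elongation) plus 2 P_D per completed protein (initiation and
termination/recycling GTPs). Opportunity costs sum per-residue values
from a packaged bacterial table keyed by one-letter code; nonstandard
residues (X, B, Z, U) and sequence-free fallbacks use the bacterial mean
of 25 P_O per residue. Protein turnover during the developmental windows
is neglected (slow relative to synthesis).

**Membranes.** The vegetative cell is a spherocylinder (L = 2.5 µm,
D = 1 µm); leaflet areas are A_outer = 4πab and
A_inner = 4π(a−h)(b−h) with a = L/2, b = D/2, h = 4 nm. The lipid count
is the summed leaflet area divided by the 0.65 nm² headgroup area, times
(1 − φ_prot) with protein occupancy 0.5; unit lipid costs are 18 P_D +
212 P_O. The sporulation septum is a flat circular bilayer,
A_sept = 2πb² (thickness negligible). Revival remakes a fraction
f_rev = 0.30 of the full membrane with f_recycle = 1/6 of lipid cost
offset by recycling — a net scale factor of 0.25. The µm²→nm² conversion
(10⁶) is applied inside the geometry operations, never by callers.

## Data handling

Identifier tokens are case-folded and stripped of non-alphanumerics;
exact locus-tag matches take precedence over synonym-map hits (the
collation rule is this package's choice — upstream sources specify only
that mapping be deterministic). Missing gene/protein lengths are replaced
by the dataset median (idempotent; counted and logged). Abundance rows
matching k locus tags contribute ppm/k to each (mass-conserving, asserted
pre-floor); unmatched proteome members receive a 0.1 ppm floor *after*
splitting, and all ppm are then renormalized so copies sum to P_total
exactly. Genes present in expression data but absent from the annotation
are retained with median-imputed lengths rather than dropped, mirroring
the median-substitution policy.

Expression heatmaps (hours t0–t8) become per-gene probability weight
vectors; all-zero genes are dropped with a log entry. Revival cumulative
scores at H0.25–H3.5 become interval weights by successive differencing
(first interval = first column); the H5.5 column is parsed but excluded
from costing because it overlaps resumed vegetative growth; negative
differences (measurement dips) are clamped to zero before renormalization
and counted.

## Ledger assembly

Ledgers book (interval, category) cells for categories {replication,
transcription_synthesis, transcription_polymerization, translation,
membrane, septum}. Genome replication is charged entirely within the
first hour bin (it completes early, well before the ~2 h commitment
point); the septum is charged in the second bin (septation follows
initiation — the sources do not fix either bin more precisely, so both
are configuration choices). One-time transcript synthesis (and its
opportunity cost) is booked at each gene's first nonzero expression
interval; polymerization and translation follow the weight vectors.
Revival membrane cost is spread uniformly over the outgrowth intervals
(H0.5 onward), not germination. Program durations — 8 h of costed
sporulation bins within an 11.5 h cycle, 0.25 h germination + 3.5 h
outgrowth, 1.16 h vegetative generation — are configuration constants.

Compartment attribution: per-gene expression costs follow gene →
{mother, forespore} labels; replication, septum, and membrane are
attributed to the mother cell; unlabeled genes default to the mother
(configurable), consistent with the mother bearing most biosynthesis.
The published ~87/13 mother/forespore split depends on a specific
gene-to-compartment map that is not reproducible here, so the split is
implemented as a labeled-input computation and validated by ground-truth
recovery on constructed labelings.

Head-to-head comparison: trait build cost = transcription + translation
at steady-state abundance (Y = 100); developmental programs are divided
by duration in generations, other traits charged as full per-generation
resynthesis (a conservative upper bound). Note the per-generation
maintenance implied by t_gen·C_M (1.392×10⁹ ATP) differs slightly from
the ~1.3×10⁹ sometimes quoted; the product is used as-is.

## Efficiency model

Batch dynamics (populations in mL⁻¹, resource in µg mL⁻¹):

    dN_v/dt = N_v[g_v(R) − f(R)g_s(R)]
    dN_s/dt = N_v f(R) g_s(R)
    dR/dt  = −N_v[g_v(R)/Y_v + f(R)g_s(R)/Y_s]

with Monod forms g_v = r_max,v R/(R+K_v), g_s = r_max,s R/(R+K_s) and the
initiation switch f(R) = 1/(1+e^{σ(R−R_min)}) (exponent clipped at ±500;
σ ≫ 1 approximates a step; R_min ≤ 0 disables initiation). Yields are
ATP-parameterized: Y = ε/C. No germination term is needed in batch mode
because the resource only decreases.

Defaults are repository choices scaled to R(0) = 1 µg mL⁻¹, not measured
values: r_max,v = ln2/1.16 h⁻¹, r_max,s = 1/8 h⁻¹ (an ~8 h program),
K_v = K_s = 0.1, σ = 50, R_min = 0.05, and (ε, C_v) = (10¹⁷ ATP/µg,
2×10⁸ ATP) giving Y_v = 5×10⁸ cells per µg (ε corresponds to ~30 ATP per
glucose-molecule-equivalent); default C_s = 1.2·C_v, with the cost ratio
swept over [0.5, 10].

Integration uses LSODA with a terminal event at R < 10⁻⁶·R(0); φ is
measured at the terminal state; state undershoots are clipped to zero
inside the right-hand side. Energy closure ε·ΔR = C_v·(ΔN_v + ΔN_s) +
C_s·ΔN_s holds to well under 1% at default tolerances (the ΔN_v + ΔN_s
term counts gross cell production, since each spore converts an existing
cell). The chemostat variant adds −D·N to both populations and
+D(R₀ − R) to the resource; because the approach to equilibrium is a
slowly damped oscillation, the integrated endpoint is polished with a
Newton solve of the stationarity conditions (in rescaled O(1)
coordinates) and accepted when relative derivatives are < 10⁻⁸. Washout
is reported when the vegetative population collapses. Steady-state φ
reduces to (f·g_s/D)/(1 + f·g_s/D), which contains no cost parameter —
the numerical check of cost-invariance confirms this structure.

## Evolution model

A deletion of Δ bp of unexpressed DNA has advantage s(Δ) = (c_n/C_cell)·Δ
with c_n = 50 ATP per nucleotide and C_cell = 9.4×10¹⁰ ATP; s is treated
as constant per deletion (no epistasis or expression-dependent cost,
matching the unexpressed-gene scenario). The diffusion fixation
probability P_fix(s, f) = (1−e^{−2Nsf})/(1−e^{−2Ns}) uses a series branch
for |2Ns| < 10⁻⁸ (agreeing with the direct form to 10⁻¹⁰ at the
boundary) and log-space/asymptotic evaluation beyond |2Ns| = 700. The
fixation-rate ratio d_del/d_sub = [2Ns/(1−e^{−2Ns})]·(U_del/U_sub) uses
U_del = 6.0×10⁻¹¹ (from an indel rate of 1.2×10⁻¹⁰ and the observed
deletion fraction) and U_sub = 3.35×10⁻¹⁰ per site per generation. Two
N_e presets are shipped (6.119×10⁷ default — the conservative,
mutation-accumulation-derived value — and 3.224×10⁸). The threshold size
where the ratio reaches 1 is found by integer bisection (86 bp at
defaults). Both the unweighted ratio curve and the deletion-size-spectrum
weighted version (ratio(Δ)·p(Δ)) are exposed, since either view of the
size dependence is informative; the packaged spectrum is a synthetic
geometric-plus-spikes mixture standing in for empirical deletion-size
tables, which are not redistributable here.

The Wright–Fisher oracle simulates binomial resampling with fitness
weighting p' = p(1+s)/(1+ps) from a single copy, vectorized over
replicates and capped at 100·N generations; it is reproducible under a
fixed seed and returns a normal-approximation CI. It exists purely as an
independent check on the closed form and is never used as the
implementation.

## Synthetic data: what it does and does not show

Generators draw from per-generator streams derived from one master seed
(adding a generator never perturbs existing fixtures) and are
byte-reproducible. They match the gross shape of the real resources —
lognormal gene lengths (median ~900 bp) with protein length =
gene_length/3 − 1, lognormal ppm summing to 10⁶, sequential stage-peaked
expression waves, nondecreasing cumulative revival scores with optional
dips, efficiencies in [0, 1] with a configured median of 0.30, and a
right-skewed deletion-size mixture — but none of the real biology:
no operon structure, no regulon identity, no sequence realism beyond a
valid alphabet, no correlation between abundance and function.

Consequently, tests on synthetic data demonstrate *bookkeeping
correctness* (conservation, additivity, oracle equivalence, ground-truth
recovery of constructed splits and stage shares, permutation invariance)
and *property-level* model behavior (monotonicity, invariances, energy
closure). They do not reproduce the study-specific totals that depend on
the real annotation/abundance/time-series tables (e.g. the absolute
2.4×10⁹ / 6.8×10⁹ ATP program totals or the 68/17/3% category shares);
with those tables supplied, the same pipeline computes them directly.

## Numerical choices and limitations

- Tolerances: expression/revival weight vectors must sum to 1 within
  10⁻⁹; ledger oracle equivalence is asserted at 10⁻⁶ relative; ODE
  integration at rtol 10⁻⁸ (halving changes φ by < 10⁻⁴).
- Degenerate inputs are defined, not errors: zero-length genomes, empty
  sequences (flat 2 P_D), zero-copy proteomes (infrastructure-only
  ledgers), f_rev = 0 (membrane category absent), φ_prot = 1 (free
  membranes).
- Ties and ordering: ledger rows are accumulated in sorted locus-tag
  order, making all outputs permutation-invariant.
- No thermodynamic (ΔG) modeling, no temperature scaling, no stochastic
  (agent-based/SDE) efficiency variant, no linkage or interference in the
  evolution model, and no live queries to annotation services.
- Problem sizes in the shipped tests and examples (tens to hundreds of
  genes, 10⁵ Wright–Fisher replicates, 25-point sweeps) were chosen as
  the smallest sizes at which every asserted property is
  well-resolved; all scale linearly if increased.
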