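# Methods

## The models

All three variants share the transposon life cycle and the two
silencing arms; they differ only in the dsRNA-formation reactions.
Copy numbers are absolute molecule/element counts (`#mol`), time is in
hours, and every reaction follows mass-action kinetics unless noted.
Species: genomic copies `T_act` (active) and `T_sil`
(heterochromatin-silenced); nuclear pools `M_n` (mRNA), `A_n`
(antisense/short heterochromatic transcript), `D_n` (dsRNA), `S_n`
(siRNA); cytoplasmic pools `M_c`, `A_c` (antisense model only), `D_c`,
`S_c`; and `VLP`, the virus-like particle.

Life cycle (all variants):

| reaction | flux |
|---|---|
| transcription of active copies | `v_ta*T_act` → `M_n` |
| transcription of silenced copies | `v_ts*T_sil` → `A_n` |
| mRNA export | `t_m*M_n`, `M_n → M_c` |
| VLP packaging | `q*M_c^2`, consumes one `M_c` |
| VLP decay | `d_v*VLP` |
| integration, successful | `f*j*VLP`, `VLP → T_act` |
| integration, failed | `(1-f)*j*VLP`, `VLP → ∅` |
| mRNA decay | `d_m*M_n`, `d_m*M_c` |

Transcriptional silencing (all variants): spontaneous
heterochromatinization `h_b*T_act` and RITS-guided (trans-acting)
`h_s*S_n*T_act`, both `T_act → T_sil`; re-activation `u*T_sil`;
antisense-RNA decay `d_r*A_n`; Dicer cleavage `g_s*D_n` releasing `n`
siRNAs per duplex; nuclear siRNA decay `d_r*S_n` (see below).

dsRNA formation, the variant-defining reactions:

| | nucleus | cytoplasm |
|---|---|---|
| rdrp | `p_n*A_n` | `p_c*M_c` + primed `g*S_c*M_c` (consumes both) |
| antisense | `p_nx*M_n*A_n` (consumes both) | `p_cx*M_c*A_c`; `A_n → A_c` at `t_an`, `A_c` decays at `d_m` |
| hairpin | `p_nx*M_n*A_n` | `p_cxx*M_c` |

Post-transcriptional silencing (all variants): RISC slicing
`b*S_c*M_c` consuming the mRNA with the siRNA acting catalytically;
Dicer `g_s*D_c` → `n` siRNAs; siRNA decay `d_s*S_c`. A second,
saturating mRNA sink `v_s*S_c*M_c/(k_s+M_c)` (an RNase acting on
RISC-marked transcripts) is implemented and selectable via
`risc_law={"mass_action","saturating","both"}` but **off by default**:
with `v_s = 800` it exceeds the RISC term by five orders of magnitude
and extinguishes every invasion at the single-copy stage, which is
incompatible with the observed cluster structure, so the shipped
default is the pure mass-action RISC law. The `v_s`, `k_s` constants
remain in the parameter set.

Genomic copies never decay; `T_act + T_sil` is non-decreasing and the
system is studied as a transient over a fixed two-year horizon
(17 520 h), never at steady state. Because VLP packaging is second
order in `M_c`, an unsilenced element grows *faster* than
exponentially and reaches any bound in finite time; the engines treat
crossing 1e12 copies of any species as a "diverged" outcome, not an
error.

### Reconstruction choices

Where the rate laws were genuinely open, the package fixes them as
follows (each is a deliberate modelling decision, revisitable through
the network-builder flags):

- **Silenced-copy transcription** feeds the silencing pathway only:
  `v_ts*T_sil` produces `A_n` (the short/antisense transcript), never
  export-competent mRNA.
- **VLP packaging** consumes one transcript per particle
  (`vlp_consumes_mrna=False` switches to a non-consuming source term;
  the effect is negligible at the default `q`).
- **Nuclear siRNA decays at `d_r`** (0.28 h⁻¹, the nuclear-RNA decay
  rate) rather than at the cytoplasmic siRNA rate `d_s` (2.8 h⁻¹).
  The slower nuclear turnover is what gives the heterochromatic
  feedback loop — silenced copies → antisense transcripts → nuclear
  siRNA → more silencing — enough gain to cap the active-copy count:
  with it, the antisense/hairpin models settle near the observed ~1:50
  active:silenced ratio and the hairpin controlled-cluster median VLP
  (~0.05); with `d_s` everywhere the nuclear arm is an order of
  magnitude too weak.
- **Primed amplification** `g*S_c*M_c` consumes both the priming
  siRNA and the mRNA (the siRNA is extended into the duplex); the net
  gain per cycle is still `n − 1` siRNAs.
- The success fraction `f` is realised as two integration channels
  (success/failure); in the stochastic engine the direct method over
  the pair is identical in law to one attempt event with a
  Bernoulli(`f`) outcome.

## Parameters

The 25 reference values (frozen in `default_parameters()`) are the
published defaults: `j=0.1`, `f=0.1`, `v_ta=16`, `v_ts=1.6`,
`t_m=t_an=0.45`, `q=1e-5`, `d_v=2.0`, `u=0.02`, `h_b=0.01`,
`h_s=0.001`, `p_n=p_c=p_cxx=0.002`, `p_nx=2e-4`, `p_cx=2.5e-4`,
`d_r=0.28`, `g=0.002`, `b=0.008`, `d_m=0.14`, `g_s=2.0`, `n=10`,
`d_s=2.8`, `v_s=800`, `k_s=5.0` (h⁻¹, #mol⁻¹h⁻¹ or #mol as
dimensionally required).

## The ensemble experiment

Each run starts from a single active element (`T_act = 1`, everything
else 0) with every rate constant drawn independently and **uniformly**
from `[ref/10, 10·ref]` (a 100-fold range; `sampler="log"` selects the
log-uniform alternative). The uniform draw is the shipped default
because it reproduces the observed no-invasion share (~0.14–0.20 per
model) and cluster ordering, while log-uniform sampling parks the
median run at the invasion threshold and yields no-invasion shares of
0.46–0.59. The success fraction `f` is clamped to [0, 1]. The siRNA
burst size `n` is a structural count, not a rate, and is **held at 10**
by default (`sample_n` exposes it to the sampler); sampling it
uniformly up to 100 lets the primed-amplification loop extinguish
~16% of canonical-model invasions at the single-copy stage, which the
observed statistics rule out.

Per-run RNG streams derive from `(master_seed, run_id)` via
`numpy.random.SeedSequence`, so ensembles are reproducible and
independent of execution order. Runs are simulated with the ODE
engine; solver failures are recorded on the outcome, never dropped.

### Cluster classification

- **red ("no invasion")**: terminal `T_act + T_sil ≤ 2.0`, inclusive,
  all variants.
- **rdrp blue ("out of control")**: among non-red runs,
  `T_sil/T_act ≥ 200`. The threshold keeps the published blue-cluster
  medians (ratio ≈ 279) inside the cluster and reproduces its ~0.10
  share; no VLP condition is imposed, since a third of this cluster
  sits below the control line.
- **antisense blue ("low VLP")**: `VLP ≤ 0.5` *and* `T_sil ≥ 1000` —
  heavy silencing with a suppressed cytoplasm.
- **hairpin**: no third cluster; non-red runs are green.
- Diverged or failed runs are `unclassified`; fractions are always
  reported against the full ensemble size.

A k-means alternative (`classify_kmeans`, on log-transformed terminal
states, red still rule-based) is provided for sensitivity checks.

## Numerical choices

- ODE engine: LSODA via `scipy.integrate.solve_ivp`, `rtol=1e-6`,
  `atol=1e-9`; halving the tolerances moves default-run terminal
  states by <0.1% (tested). Negative undershoot is clamped to zero at
  output; fluxes evaluate `max(x, 0)` so the vector field never pushes
  a pool below zero, and an undershoot beyond ~10·atol raises.
- Overflow guard at 1e12 copies (terminal event → `diverged`).
- SSA: exact direct method, numba-compiled; same-species bimolecular
  propensity `q*M*(M-1)`; event budget 1e8 with a "budget exceeded"
  error carrying the partial trajectory.
- ODE–SSA agreement is measured as
  `|mean_SSA − ODE| / max(|ODE|, 0.01·init_scale)`: the floor keeps
  pools that both descriptions have emptied from registering spurious
  relative error, because the fluid limit is only a statement about
  large copy numbers.

## Problem sizes

The test suite and the reproduction script run 1000-run ensembles per
variant (the original experiment used 10 000), 7×7 recruitment sweeps,
and 20–60 SSA replicates per agreement check. At these sizes the
binomial standard error on a reported fraction of 0.14 is ≈0.011.

## What the ensembles do and do not show

The generator *is* the study design: randomized kinetics around a
single reference host, one invading autonomous element, no TE loss, no
defective/non-autonomous copies, no Piwi/ping-pong pathway, no
nucleus–cytoplasm siRNA transport. Passing tests therefore support
claims about this model family — e.g. that RdRP-free feedbacks can
control an invasion — not about any particular organism's genome.

## Known quantitative deviations

With the exact supplementary equations unavailable, the rate laws
above are a reconstruction, and three published statistics are not
reproduced within their tolerances under the shipped defaults
(1000-run ensembles):

- the canonical-model no-invasion share is ≈0.20 vs the published
  0.14 — residual early extinction by the primed loop in strict-host
  draws;
- the hairpin controlled-cluster share with `VLP < 1` is ≈0.75 vs
  0.91 — the reconstruction's hairpin cytoplasmic response is too weak
  in hosts drawn with low `p_cxx·b/d_s`; sampling `n` would close this
  gap but opens the larger no-invasion one above;
- the rdrp blue-cluster controlled share is ≈0.44–0.57 vs 0.33.

Also, the published cluster fractions sum to 0.88 (rdrp) and 0.92
(hairpin) with no stated rule for the remainder; this reconstruction
produces no diverged or unlabeled runs under default sampling, so its
green shares run correspondingly high. All other reported fractions
(controlled shares of the rdrp/antisense green clusters, antisense
cluster sizes, red-cluster control, gradient directions of the
recruitment sweeps, ODE–SSA agreement) land within tolerance; the
corresponding checks live in `tests/test_acceptance.py`.
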