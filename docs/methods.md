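# Methods

## Model overview

`kinrun` simulates a dimeric kinesin walking along one microtubule
protofilament as a continuous-time Markov chain over a small set of
composite chemical/mechanical states, advanced by exact
competing-exponential races (kinetic Monte Carlo). Mechanical substeps —
the detachment of a just-hydrolyzed ADP head into the one-head-bound
intermediate (INT) position and the diffusion of the tethered head to the
forward binding site once the bound head's neck linker (NL) docks — are
treated as instantaneous events. This is justified by the separation of
timescales: a head-sized particle diffuses over the 8-nm site spacing in
microseconds, while every chemical dwell in the cycle is a fraction of a
millisecond or longer. The Brownian-dynamics layer (below) checks this
separation explicitly rather than assuming it.

Reachable states, with the trailing/bound head always holding ATP
(nucleotide-free, ATP and ADP·Pi heads bind the microtubule strongly and
never dissociate below stall; hydrolysis and Pi release are lumped into a
single transition):

| state | competing channels |
|---|---|
| two heads bound, leading head ADP (post-step) | leading ADP release k_D · trailing hydrolysis k_c (→ Period II) |
| two heads bound, leading head φ | leading ATP binding k_b·[ATP] · trailing hydrolysis k_c (→ INT, bound head φ) |
| two heads bound, both ATP | trailing hydrolysis k_c (→ INT, bound head ATP) · leading hydrolysis k_c/ρ (futile branch) |
| INT, bound head φ | ATP binding k_b·[ATP] |
| INT, bound head ATP | NL docking k_NL (→ 8-nm step) · bound-head hydrolysis k_c/ρ (→ Period I; rate 0 while the kinesin-3 clock runs) |

The kinesin-3 dimerization clock contributes one extra channel (rate
k_0 = n·k_cc) to every race, including the dissociation-exposure windows:
coiled-coil zipping is independent of head chemistry, so freezing it
during those windows would bias the activation time upward.

**Futile branch.** ATP binding to the leading φ-head opens a slow
leading-head hydrolysis channel (k_c/ρ). When it fires, the leading ADP
head detaches to the INT position; NL docking of the (now bound, trailing)
ATP head then returns the tethered head to the site it came from, so the
cycle is futile — no net displacement — but its INT passage carries the
same Period-I exposure as a productive one, and the re-bound state carries
the usual post-step ADP-release race. At saturating ATP this branch fires
in ~2% (kinesin-1) to ~5% (kinesin-3) of cycles and raises the per-step
dissociation hazard by the same factor. Under no load no backward stepping
occurs; velocities are therefore narrow and approximately Gaussian.

## Dissociation

Runs end during two weak-binding exposures of a sole microtubule-bound
ADP head:

- **Period I** (depth E_w1, fixed window t_r): entered from the INT state
  when bound-head hydrolysis beats NL docking, probability per passage
  p_I = (k_c/ρ)/(k_c/ρ + k_NL). For E_w1 ≤ 18 k_BT escape within t_r is
  near certain (the implementation uses the computed probability, not
  literally 1, so the insensitivity to E_w1 is testable). A Period-I
  survivor sits at a relaxed site of depth E_w2 and continues as a
  Period-II race.
- **Period II** (depth E_w2, racing ADP release k_D): entered per
  completed step with probability p_II,occ = k_c/(k_c + k_D), escape
  probability P_II = k_off/(k_off + k_D).

Escape kinetics follow one Arrhenius form k_off(E) = A·e^(−E/k_BT). The
single attempt rate A is phenomenological — it absorbs all well-shape
detail and is reported, not interpreted. It is **calibrated once**, by
requiring that raising kinesin-1's E_w2 from 39 to ≥ 45 k_BT multiplies
the mean run length by 2.3 (equivalently, that the per-step hazard ratio
(p_I·P_I + p_II,occ·P_II)/(p_I·P_I) equals 2.3), and then frozen for every
construct and every E_w2. The calibration must also satisfy two hard
regime constraints — P_I ≥ 0.99 at E_w1 = 18 k_BT and P_II ≤ 10⁻³ at
E_w2 = 45 k_BT — and the side condition that Period II out-contributes
Period I for kinesin-1; violation is a refusal to simulate, not a warning.
The calibrated values are A ≈ 6.1×10¹⁷ s⁻¹, P_II(39 k_BT) ≈ 0.0198,
P_II(45 k_BT) ≈ 5×10⁻⁵. Since the underlying escape computation that a
detailed Brownian treatment would provide is not reproduced here,
P_II(39) is an inference from the calibrated fold-change and should be
quoted as such.

The analytic decomposition ε = k_I·P_I + k_II·P_II (occurrence rates times
per-exposure escape probabilities) is exposed for cross-checks and is
verified against 1/mean detachment time of simulated traces.

## Parameters

Energies are carried in k_B·T throughout; no absolute temperature is
exposed. Family presets:

| parameter | kinesin-1 | kinesin-3 | meaning |
|---|---|---|---|
| t_r | 10 μs | 10 μs | local-site relaxation time |
| E_w1 | ≤ 18 k_BT (default 18) | same | perturbed-site ADP affinity |
| E_w2 | 39 k_BT | ≥ 45 k_BT (default 45) | unperturbed-site ADP affinity |
| k_NL | 800 s⁻¹ | 3400 s⁻¹ | NL docking rate (INT, ATP/ADP·Pi) |
| k_c | 140 s⁻¹ | 270 s⁻¹ | hydrolysis + Pi release, forward NL |
| ρ | 40 | 20 | suppression without forward NL |
| k_D | 350 s⁻¹ | 350 s⁻¹ | microtubule-stimulated ADP release |
| k_b | 2 μM⁻¹s⁻¹ | 2 μM⁻¹s⁻¹ | ATP binding |
| k_cc | — | 0.17 s⁻¹ | overall coiled-coil zipping rate |
| n | — | 10 | rate-limiting zipper stages |

Choices made where the model leaves a range: E_w2 for kinesin-3 is set at
the lower bound 45 k_BT of its insensitive regime; E_NL defaults to
5 k_BT (within the ≥ 4 k_BT requirement, the value used for the load
calculations); E_I1/E_I2 sit at their threshold values 40/20 k_BT and
enter only the Brownian layer; the lattice spacing is the 8-nm tubulin
repeat. E_w1 > 18 k_BT is rejected outright rather than silently
simulated, because the near-certain-Period-I-escape regime is a model
assumption, not an emergent result. Parameter sets round-trip through
JSON with unknown keys rejected (typo guard).

Construct variants change exactly one documented parameter on the family
preset: `l8_mutant` (E_w2 → 39 k_BT), `kloop_swap` (E_w2 → 40.5 k_BT),
`kif1a_393` (INT-state ATPase active from t = 0), `ew2_enhanced_k1`
(kinesin-1 with E_w2 → 45 k_BT).

## Dimerization clock

Coiled-coil zipping is an n-stage chain of identical exponential steps at
k_0 = n·k_cc, so the completion time τ ~ Gamma(n, k_0): mean 1/k_cc
independent of n, CV = 1/√n. The clock is carried as the explicit stage
chain (one channel in the global race) rather than a pre-sampled τ so
that load-induced disruption can be applied at any time; equality in
distribution with direct Gamma sampling is a tested property
(Kolmogorov–Smirnov). Before completion the INT-state ATPase of the bound
head is 0; the two-heads-bound rates are k_c and k_c/ρ both before and
after. This single gate produces both superprocessivity (no Period I
before τ) and the Gaussian-like run-length distribution
(run ≈ v·τ + exponential tail).

## Load

A backward load F > 0 on the cargo has exactly two effects, both in the
INT state: the clock is treated as disrupted (INT-state ATPase active from
t = 0) and k_NL is divided by a user-supplied λ ≥ 1 (typical values 2
and 5). The NL-stretch condition for the λ-fold slowdown (stretch
> 2.8 nm) is taken as always satisfied in the INT state under backward
load, since no geometry-to-force map is part of the model. ATPase rate
constants are F-independent. No mechanical stepping model under load is
implemented, so velocities under load come from the unchanged chemical
cycle and quantitative force–velocity comparison is out of scope; the
model's prediction is the ≈ μλ-fold rise of the dissociation rate, with μ
measured (not assumed) as the fold-increase of k_d from disabling the
clock alone at F = 0.

## Statistics

Mean run length, velocity (total displacement / total time per trace),
SEM, CV and k_d = 1/mean detachment time are computed from raw per-trace
values; histograms are display-only. k_d is cross-checked against mean
velocity / mean run length. Run-length distributions are fit by maximum
likelihood under exponential and Gaussian models and classified by lower
AIC, ties toward the exponential null. Sub-step displacements
(dissociation before the first completed step, including the −4 nm
half-step of a futile-passage death) are retained in the summary
statistics but excluded from the shape comparison, since they lie outside
the exponential support and both likelihoods must see the same sample.
Traces hitting the safety cap (default 300 s) are excluded from all
statistics and counted.

## Brownian validation layer

A 2-D overdamped Langevin integrator (stochastic Heun/Runge–Kutta,
dt ≤ 1 ns) moves a single head in a piecewise potential built from
Gaussian wells and barriers, with drag from Stokes' law for a 4-nm sphere
in water (D ≈ 5.4×10⁷ nm²/s) — the drag choice only sets validation
timescales. The potential shapes are a documented stand-in, not derived
well profiles, and the layer never produces headline numbers. It verifies:
free-diffusion MSD and harmonic-well equipartition against closed forms;
monotone decrease of within-window escape with well depth at shallow
depths (2–8 k_BT; deep wells are astronomically slow at BD timescales and
are covered by the calibrated escape model alone); first passage of the
tethered head to the forward site far faster than 1/k_NL; and suppression
of backward arrival by an E_NL-high ridge (the NL-docking barrier is a
ridge in x, uniform in y, so it cannot be circumvented off-axis).
Dissociation in this layer means |y| > 10 nm.

## Simulation sizes and numerical choices

Experiment-level statistics use the canonical ~500-trace protocol; the
reproduction script uses 2000 traces per construct to hold the
Monte-Carlo error of fold-ratios to a few percent, and the test suite
uses 250–3000 depending on the sharpness of the assertion. Per-trace
random streams derive from (master seed, trace counter), so results are
bit-reproducible and changing the trace count never reshuffles earlier
traces. Simulated kinesin-3 traces take ~15 ms each (≈1350 steps); all
other constructs are cheaper.

## What the simulations do and do not show

The engine emulates the kinetic consequences of the stepping pathway, not
its structural detail: no explicit ADP·Pi intermediate, no Pi rebinding,
no lattice heterogeneity or protofilament switching, no backward steps
under no load, and no load-dependent stepping mechanics. Agreement with
the headline statistics therefore supports the kinetic architecture
(clock-gated Period-I dissociation plus E_w2-controlled Period II), not
any particular well shape or structural mechanism. Real traces carry
localization noise, photobleaching-limited observation windows and
short-run detection thresholds that the generator does not emulate; the
shape verdicts here apply to idealized complete runs.

Known quantitative limitation: with the Period-I escape probability
pinned at ~1 (as the E_w1 ≤ 18 k_BT regime demands) and
p_I = (k_c/ρ)/(k_c/ρ + k_NL) fixed by the preset rates, the
E_w2-enhanced kinesin-1 construct saturates near 1.9 μm, so its gap to
kinesin-3 comes out ≈ 6-fold rather than the ≈ 4-fold that would follow
if roughly a quarter of Period-I exposures were survivable. The
2.3-fold E_w2 effect, the ~10 μm kinesin-3 runs, the ≥ 10× family ratio
and the ~10-fold loop-8-mutant collapse are all reproduced.
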