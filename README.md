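# kinrun

Stochastic chemomechanical simulator of processive runs of dimeric
**kinesin-1** and cargo-dimerized **kinesin-3** motors on microtubules.

## The scientific problem

Kinesin-1 dimers walk ~1 μm before dissociating and show the
single-exponential run-length distribution expected of a motor with a
constant dissociation hazard. Cargo-dimerized kinesin-3 (KIF1/KIF13/KIF16)
is *superprocessive* — run lengths around 10 μm, more than 10-fold
kinesin-1 — and, puzzlingly, its run lengths are distributed like a
Gaussian, not an exponential. `kinrun` implements a kinetic model that
reproduces both behaviours from one stepping pathway, for researchers
studying motor-protein processivity and mechanochemical coupling.

## The model

Each 8-nm step cycles through an exact race of exponential channels:
trailing-head ATP hydrolysis + Pi release (rate k_c), leading-head ADP
release (k_D) and ATP binding (k_b·[ATP]), neck-linker (NL) docking of the
bound head in the one-head-bound INT state (k_NL), and slow hydrolysis
(k_c/ρ) in heads whose NL does not point forward. Dissociation happens
(essentially) only in two weak-binding exposures of a sole bound ADP head:

- **Period I** — right after Pi release at the still-perturbed local site
  (well depth E_w1 ≤ 18 k_BT, window t_r): escape is near certain. It is
  entered when bound-head hydrolysis beats NL docking in the INT state,
  with probability per passage p_I = (k_c/ρ)/(k_c/ρ + k_NL).
- **Period II** — the bound ADP head at an unperturbed site (depth E_w2),
  racing ADP release: entered per step with probability
  p_II,occ = k_c/(k_c + k_D); escape probability P_II(E_w2) follows a
  calibrated Arrhenius law k_off = A·e^(−E/k_BT).

The overall dissociation rate is ε = k_I·P_I + k_II·P_II. What makes
kinesin-3 special is the **dimerization clock**: its coiled-coil zips in n
sequential stages at rate k_0 = n·k_cc, so the completion time τ is
Gamma(n, k_0)-distributed, and until τ the INT-state ATPase is inhibited —
Period I cannot occur. With E_w2 ≥ 45 k_BT making P_II negligible, the
dimer barely dissociates before τ and then dies with a constant hazard:
run length ≈ v·τ + Exp(·), which for n = 10 is Gaussian-like and ~10 μm.
A backward load disrupts the INT-state inhibition (measured fold μ) and
slows NL docking λ-fold, raising the dissociation rate ≈ μλ-fold.

## Worked example

```python
import kinrun as kr

k1 = kr.default_parameters(kr.KINESIN1)
k3 = kr.default_parameters(kr.KINESIN3)          # n = 10 zipper stages
cfg = kr.SimulationConfig(atp_concentration=2000.0, n_traces=500, rng_seed=1)

for name, params in [("kinesin-1", k1), ("kinesin-3", k3)]:
    traces = kr.simulate_traces(params, cfg)
    s = kr.summarize(traces)
    shape = kr.classify_shape(kr.run_lengths(traces))
    print(f"{name}: run {s.mean_run_length/1000:.2f} um, "
          f"v {s.mean_velocity:.0f} nm/s, CV {s.cv_run_length:.2f}, {shape}")
```

prints

```
kinesin-1: run 0.83 um, v 883 nm/s, CV 0.97, exponential
kinesin-3: run 10.43 um, v 1484 nm/s, CV 0.35, gaussian
```

i.e. at saturating (2 mM) ATP the kinesin-1 preset walks ~0.8 μm with the
unit coefficient of variation of an exponential run-length distribution,
while the cargo-dimerized kinesin-3 preset walks ~10 μm (13-fold further)
with a narrow, Gaussian-classified distribution — the superprocessivity
signature. The same API drives construct variants
(`kr.preset_variant(k3, "l8_mutant")`, `"kif1a_393"`, `"kloop_swap"`,
`"ew2_enhanced_k1"`), ATP and backward-load sweeps
(`kr.kd_vs_force`), and the Brownian-dynamics validation layer
(`kr.escape_fraction`, `kr.forward_binding_time`).

The same experiments are available from a shell:

```bash
kinrun simulate --family kinesin3 --n-traces 500 --seed 1 --out out/
kinrun sweep --family kinesin3 --n-stages-list 1,2,5,10,20 --out sweep/
kinrun calibrate --out escape_model.json
```

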