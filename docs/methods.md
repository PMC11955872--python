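# Methods

## Model

Each neuron is a single cylindrical compartment (length 21 µm, diameter
21 µm, lateral area ≈ 1385 µm², end caps excluded, Cm = 1 µF/cm²,
nseg = 1). Its membrane equation sums a passive leak and the currents of
the channels present in the neuron's genotype:

    Cm dv/dt = −[ g_pas (v − E_pas) + Σ_k i_k(v, gates_k) ] + I_stim / A

Ohmic channels follow `i = ḡ · Π gate^p · (v − E)` with fixed reversal
potentials E_Na = 50 mV, E_K = −77 mV, E_h = −45 mV. The six Cav channels
use the Goldman–Hodgkin–Katz constant-field flux

    Φ(v) = 10⁻³ z F ( [Ca]ᵢ f(−u) − [Ca]ₒ f(u) ),   u = 10⁻³ z F v / (R T)

with `f(x) = x/(eˣ−1)` (first-order series inside |x| < 10⁻⁴), fixed
[Ca]ᵢ = 50 nM, [Ca]ₒ = 2 mM and T = 308.15 K. The flux reverses at the Ca²⁺
Nernst potential (+140.7 mV for these concentrations). The nominal ḡ of a
GHK channel is a lumped permeability scale chosen so that `ḡ · gates · Φ`
is a current density in mA/cm²; the tabulated "S/cm²" values for Ca
channels are interpreted on that scale.

Channel kinetics are stored as data (named functional forms + parameters)
in `icnsim.channels`, one block per gene, and are exportable as JSON
(`icnsim channels --out registry.json`). Three structural specialities:

* **Kv1.1 / β1 merge.** Co-expression of *Kcna1* and *Kcnab1* yields the
  four-gate delayed rectifier with an additional fast inactivation
  variable x; *Kcna1* without the subunit is the same channel with x ≡ 1
  (non-inactivating); *Kcnab1* alone contributes no conductance.
* **Kv3.1 two-component activation.** The conductance is a mixture
  `ḡ·(φ n² + (1−φ) p)` of fast (n) and slow (p) activation processes with
  fractional amplitude φ = 0.2 by default.
* **Kir3.1 scale.** The GIRK conductance carries a fixed source-model
  normalisation multiplier 2.716898432 (its reciprocal also scales τ_n).

Several rate expressions are 0/0 at isolated voltages (Nav1.1 αm at
−35 mV, Cav2.2 αm at +20 mV, Kir3.1 at −30 mV, Cav1.3 at −8.124 mV). A
shared guard substitutes the analytic limit (coefficient × slope constant)
within 10⁻⁴ mV of the singular voltage, so fixed-step integration cannot
land on an undefined value. Ambiguously typeset time-constant expressions
were resolved against the structure of their source models and are recorded
as comments in the registry: the Kv1.1 τn divisor 4.171167511 and the
Kir3.1 divisor 2.716898432 scale 1/(α+β); Cav1.3 τm = 1/(3(α+β)); the
Kv1.1 τx and both Kv3.1 τ's follow the bi-exponential form
`amp/(c₁ e^((v−v₀)/k₁) + c₂ e^(−(v−v₀)/k₂)) + base`; the Cav3.3 divisors
6.898648307 and 3.737192819 apply to the whole bracketed expressions
(Q10-style factors). No additional temperature scaling is applied beyond
what those expressions embed; simulations represent 35 °C.

## Numerics

Integration uses the staggered fixed-step scheme of compartmental
simulators at dt = 25 µs (configurable): gating variables advance by
exponential Euler — exact for the linear gate ODE at frozen voltage, with
rates at v(t), the midpoint of the gates' half-shifted interval — and the
voltage advances by a trapezoidal (Crank–Nicolson) step in which ohmic
conductances are implicit and the GHK currents are linearized about v(t)
via a tabulated dΦ/dv (their chord slope joins the implicit term, the
residual is explicit). The implicit treatment matters: with
ḡ_Na = 0.075 S/cm² the instantaneous membrane time constant during the
upstroke falls to ~13 µs, below the step, where a forward update is
unstable. The scheme is second-order on the passive response (the RC oracle
in the tests matches the closed form to ~10⁻⁵ relative) and halving dt
leaves spike counts unchanged while shifting spike times by ≲0.1 ms over a
29-spike train. Gate steady states, time constants and the GHK flux are
tabulated on a 0.02 mV grid over [−150, 100] mV and linearly interpolated
inside the JIT-compiled kernel; gates are clamped to [0, 1]; |v| > 200 mV
aborts the run as a numerical blow-up. Simulations are bit-reproducible
for identical inputs. Gates are initialized at their steady state for
v_init = −61 mV; there is no pre-equilibration randomness.

## Passive constraining

The leak is the free parameter that absorbs what the transcript panel
cannot see. `tune_epas` solves the steady-state current balance at the
target RMP (−61 mV) for E_pas given g_pas and rejects solutions outside the
physiological band [−80, −50] mV, mirroring the rejection step of the
conductance screen. `tune_leak` additionally chooses g_pas per genotype as
the largest of (a) the density needed for a 100 MΩ target input impedance
after subtracting the channels' own resting slope conductance, (b) the
density required to keep E_pas in band against the net channel current at
rest, and (c) a floor equal to a 300 MΩ leak-only impedance. The floor
reflects a structural fact of the full genotype: the published conductance
set alone contributes ≈50 MΩ of resting conductance (mostly GIRK and HCN3),
so any heavier leak would push the assembled model's Rin below the 40 MΩ
physiological floor, while very sparse genotypes need the heavier ~100 MΩ
leak to avoid hyper-excitable artifacts (post-stimulus firing).

Current-clamp pulses default to 100 ms delay, 800 ms duration, 100 ms tail
within a 1000 ms window. The source protocol specifies only the total
duration; the onset/duration split is this package's documented choice and
is configurable. Input impedance is measured with a −0.01 nA pulse
(steady deflection / current; rebound spikes after pulse release are
tolerated, spikes during the pulse invalidate the measurement), rheobase by
bisection to 1 pA resolution, and RMP as the mean over the final 10 % of a
stimulus-free second, with >1 mV residual oscillation or any spike flagged
as spontaneous activity rather than averaged away.

## Firing-pattern taxonomy

The phasic/tonic dichotomy is operationalised (the source literature names
the classes but no thresholds): a trace is **tonic** if it has ≥3 spikes
and its last spike falls within the final 20 % of the stimulus, **phasic**
if it spikes but fails that test, **silent** otherwise. Artifact classes
take precedence: **spontaneous** (any spike before stimulus onset),
**post-stimulus firing** (any spike later than 20 ms after offset),
**incomplete repolarization** (mean voltage over the final 50 ms more than
10 mV above the pre-stimulus baseline). Over an ordered amplitude sweep a
genotype is phasic / tonic / phasic-to-tonic / tonic-to-phasic; artifact
traces, all-silent sweeps and non-monotone patterns map to *other* and are
excluded from distribution statistics. All windows and thresholds live in
`ClassificationRules` so the sensitivity of population statistics to the
rule can be studied. Percentages are reported genotype-weighted by default
and cell-weighted (occurrence counts) on request.

## Conductance–expression correlation

Conductance fold = ḡ_gene / ḡ_ref with *Cacna1a* (the smallest conductance)
as reference. Expression level of a gene is the mean over its expressing
neurons of `2^(C̄t_ref − Ct)`, where C̄t_ref is the reference gene's mean Ct
over its own expressing neurons — i.e. mean qPCR fold difference relative
to the reference. Both folds are log₁₀-transformed before the Pearson
correlation (they span 3–4 decades; the correlation is otherwise dominated
by the largest fold). *Hcn3* and *Cacna1b* are excluded as outliers by
default. The exact averaging scheme behind the published correlation is
not specified; this transform is one documented, pluggable choice, and the
reported R² should be read with that caveat.

## Synthetic data generator

`generate_ct` emulates the structure of the HT-qPCR panel: per-transcript
expression probabilities (polarized towards 0/1 so that a few hundred
neurons yield a realistic mix of common genotypes and singletons — the
defaults give ~140 genotypes, of which 6–8 are "common" (>10 cells), from
405 neurons); expressed Ct ~ N(gene-specific mean, 2 cycles) truncated to
[5, 15] so the empirical presence rate converges to the configured
probability; unexpressed Ct ~ N(25, 3) floored at 18 cycles (above the
13–17 threshold range), with 15 % reported as the undetected sentinel
(40 cycles); gene-specific expressed means reproduce the qualitative
expression gradient of the panel (abundant channels amplify earlier),
which is the property the conductance–expression comparison rests on; a
configurable fraction (default 0.9) of neurons is forced to express the
Na⁺ channel plus ≥1 K⁺ channel; metadata assign neurons to four animals
(two male, two female) with a Bernoulli(0.5) SAN-projection flag. Optional
pairwise co-expression coupling exists (default independent). What the
generator does **not** emulate: animal-level batch effects, the real
panel's exact genotype frequency spectrum, and any genuine biological
co-expression modules — so pipeline tests on synthetic data demonstrate
mechanical and statistical correctness of every stage, not agreement with
the deposited dataset (which a dedicated test checks when the matrix is
supplied locally).

Because expressed Ct is truncated at the binarization threshold, raising
the threshold above 15 creates no new genotypes in synthetic data; the
upward arm of the threshold sweep is informative only on real data.

## Problem sizes

The default test and acceptance runs use synthetic cohorts of 405 neurons
(full pipeline) and 120 neurons (perturbation studies), three-amplitude
sweeps, and 1 s simulations at 25 µs — a full library run of ~135 genotypes
takes ~15 s on one core with the JIT-compiled kernel. The rejection screen
is exercised with tens of samples rather than the exhaustive campaigns a
cluster would run; its acceptance logic is identical at any n.

## Known limitations

* One compartment, fixed ionic concentrations: no dendrites, axon, calcium
  dynamics or synaptic input; firing classes reflect soma-level dynamics.
* The phasic/tonic split and the expression transform are operational
  definitions; population percentages shift within a few points under
  reasonable variations of either.
* The leak-tuning procedure is a deterministic stand-in for the manual
  conductance adjustments used during the original model calibration;
  genotypes whose balance cannot be achieved in-band are rejected rather
  than hand-tuned.
* Gate tables are linearly interpolated at 0.02 mV; kinetics outside
  [−150, 100] mV clamp to the table edges (saturated by construction).
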