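# mcellnet

**The zebrafish Mauthner-cell escape circuit in silico, with the behavioral
and molecular analyses that surround it.**

In social fish, stable dominance relationships reshape motor behavior:
dominant zebrafish swim more and startle less readily, subordinates the
reverse.  The startle escape is commanded by the paired hindbrain Mauthner
cells (M-cells), whose excitability is set by the interplay of dopaminergic
(excitatory, via Drd1b), glycinergic and GABAergic inputs.  `mcellnet` is a
package for exploring how that interplay produces status-dependent escape
sensitivity, and for analyzing the experiments used to test it.

It provides four tested pipelines:

1. **Circuit model** (`mcellnet.model`, `mcellnet.params`) — a four-neuron
   conductance-based network (modified Morris–Lecar with calcium-gated K
   current): excitatory sensory relay E, GABAergic interneuron GA,
   glycinergic interneuron GL, and the M-cell, integrated with fixed-step
   RK4 (dt = 0.01 ms, numba-compiled, with a pure-NumPy reference path).
   Each cell obeys

       C dv/dt = −I_Ca − I_K − I_L − I_KCa − I_syn + I_app(t),

   with synaptic gating ds/dt = α s∞(v)(1−s) − β s, dopaminergic gain
   (1+D1) on excitatory inputs, and a slow retrograde gain gI on all
   M-cell inputs that falls with M-cell calcium.  Two presets encode
   social status: dominant-like (D1_GL = 0.65, g_GA→GL = 0.2) and
   subordinate-like (D1_GL = 0.25, g_GA→GL = 0.4).
2. **In-silico pharmacology** (`mcellnet.experiments`) — receptor-blockade
   conditions (D1, GABA_A, glycine) crossed with the status presets and
   driven with repeated 2-ms pulses over a stimulus grid WE = 10..60;
   readout is the fraction of pulses answered by an M-cell spike, the
   model analogue of startle probability.
3. **Behavioral analysis** (`mcellnet.behavior`) — swim-burst detection
   (≥ 8 mV peak-to-peak, 30–200 ms), Mauthner-latency filtering (5–15 ms),
   startle-probability tabulation on the 70–100 dB grid, and Boltzmann
   sigmoid fitting Y = Bottom + (Top−Bottom)/(1+exp((V50−X)/Slope)).
4. **qPCR quantification** (`mcellnet.qpcr`) — comparative ΔΔCt with
   primer-efficiency correction (Pfaffl ratio or E^(−ΔΔCt)), normalized to
   the actb2 reference gene and the social-isolate control group, reported
   as log2 fold change.  The published primer-efficiency table ships with
   the package.

Seeded synthetic-data generators (`mcellnet.synth`) emulate each data type
with known ground truth, so every pipeline is validated by parameter
recovery without any external data.

## Worked example: startle psychometrics end to end

```python
from mcellnet.synth import StartleSimSpec, gen_startle_trials
from mcellnet.behavior import (filter_mauthner_trials, startle_probability,
                               fit_boltzmann)

spec = StartleSimSpec(v50=85.0, slope=3.0, n_animals=40,
                      trials_per_intensity=5, contaminant_fraction=0.1)
trials, truth = gen_startle_trials(spec, seed=7)     # 1400 Bernoulli trials
kept = filter_mauthner_trials(trials)                # 1326 after 5-15 ms filter
per_animal, mean = startle_probability(kept)
fit = fit_boltzmann(mean.index.to_numpy(float), mean.to_numpy())
```

This prints response probabilities rising sigmoidally across the grid
(0.010 at 70 dB, 0.414 at 85 dB, 0.994 at 100 dB) and recovers the
generating curve from the noisy cohort:

```
Bottom=0.016  Top=1.000  V50=85.95  Slope=2.56  R2=0.9999
```

i.e. the half-maximal intensity V50 is recovered within 1 dB of the true
85 dB, and the slope within 15 % — the resolution the assay's sampling
design (5 trials per intensity, 40 animals) supports.

The circuit model is driven the same way from Python or the CLI:

```bash
mcellnet sweep --preset dominant --condition gly_block --out out/
mcellnet pharm-compare --preset subordinate --condition gaba_block --out out/
```

`pharm-compare` reports the per-strength response fractions with and
without the blockade and their grid-summed difference — positive when the
blockade disinhibits the M-cell (e.g. glycine block in the dominant-like
circuit), negative when it recruits extra inhibition (GABA block in the
subordinate-like circuit).

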