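# Methods

## The circuit model

`mcellnet` models the zebrafish Mauthner-cell (M-cell) startle escape
circuit as four conductance-based neurons: an excitatory sensory relay (E)
standing in for VIIIth-nerve / hair-cell drive, a GABAergic interneuron
(GA), a glycinergic interneuron (GL), and the M-cell itself.  E excites GA,
GL and M; GA inhibits GL and M; GL inhibits M; a fixed small synaptic drive
(s_M = 0.029) stands in for the contralateral M-cell, which is not
simulated explicitly.

Each cell is a modified Morris–Lecar oscillator:

    C dv/dt = −I_Ca − I_K − I_L − I_KCa − I_syn + I_app(t)
    I_K   = g_K n (v − v_K)
    I_Ca  = g_Ca m∞(v) (v − v_Ca)
    I_KCa = g_KCa [Ca]/([Ca]+k1) (v − v_K)
    I_L   = g_L (v − v_L)

with instantaneous calcium activation m∞(v) = ½(1 + tanh((v−v1)/v2)), a
delayed-rectifier gate dn/dt = φ(n∞(v) − n)/τ_n(v), and a calcium pool
d[Ca]/dt = ε(−μ I_Ca − k_Ca [Ca]) feeding the Ca-gated K current.  Units
are mV and ms; conductances, currents and [Ca] follow the dimensionless
Morris–Lecar convention.  Presynaptic cells carry a first-order
activated-channel fraction ds/dt = α s∞(v)(1−s) − β s with
s∞ = 1/(1+exp(−(v−θs)/σs)) — the standard synaptic-gating sigmoid.

Two neuromodulatory mechanisms act multiplicatively on synaptic gain:

* **Dopamine (D1)** scales excitatory input as (1 + D1) onto the M-cell
  (D1_M = 0.015) and onto the glycinergic cell (D1_GL, status-dependent).
* **Retrograde calcium signaling**: a slow gain gI multiplies every
  synaptic input the M-cell receives and relaxes toward
  gI_max/([Ca_M]+k2) with time constant ρ = 10 s, so sustained M-cell
  activity (raising Ca_M) depresses its own synaptic drive.  The
  implemented law is dgI/dt = (gI_max/([Ca]+k2) − gI)/ρ.  The alternative
  reading dgI/dt = gI_max/([Ca]+k2) − gI/ρ is selectable via
  `ModulationParams.gI_law="linear_decay"`, but its fixed point
  (ρ·gI_max/([Ca]+k2) ≈ 1.4·10⁴) clamps the M-cell to the weighted synaptic
  reversal potential at rest, which is dynamically implausible; the
  relaxation form, whose resting gain is O(1), is the default.

### Social-status presets

Two parameter presets encode stable social phenotypes.  Only three
parameters differ:

| parameter | dominant-like | subordinate-like | meaning |
|---|---|---|---|
| D1_GL | 0.65 | 0.25 | dopaminergic gain on E→GL (Drd1b expression in glycinergic neurons) |
| g_GA→GL | 0.2 | 0.4 | GABAergic inhibition of the glycinergic cell |
| β_GL (under GABA block) | 0.024 | 0.0072 | glycinergic decay rate when GABA_A is antagonized |

Dominants have a strong dopaminergic→glycinergic→M-cell pathway (more
feed-forward inhibition of escape); subordinates have a strong
GABAergic→glycinergic pathway (glycinergic cell suppressed, M-cell less
inhibited).  The β_GL values apply only under the GABA-blockade condition:
applying them at baseline inverts the reported blockade effects (tested
during development), so the baseline glycinergic β stays at 0.08.

### Numerics, initialization and settling

Integration is fixed-step classical RK4 at dt = 0.01 ms (configurable up to
0.05 ms), compiled with numba; a pure-NumPy transcription of the same
equations (`mcellnet.model.derivatives`) is kept as the readable reference
and the test suite holds the two paths equal to machine precision.
Divergence (|v| > 500 mV or non-finite state) raises an error rather than
propagating NaNs.  Step-halving on the dominant-control WE=60 train leaves
the M-cell spike count unchanged with spike-time shifts below 0.1 ms.

The canonical initial state is v = v_L, n = n∞(v_L), [Ca] = 0, s = 0 for
every cell, and gI = gI_max/k2 = 1.5 (its quasi-steady value at an empty
calcium pool).  Each run starts with a stimulus-free settling period,
default 15 s.  The choice matters: every fast variable rests within
~1 s, but gI relaxes with τ = ρ = 10 s toward ≈1.387, and the M-cell's
stimulus threshold is sensitive to the gI baseline.  At 15 s gI ≈ 1.41
(within ~2 % of rest), a regime in which the M-cell's dynamic range spans
the stimulus grid and the status presets separate.  Much shorter settling
leaves gI high enough that both presets saturate; the source description
does not state an initialization or equilibration procedure, so this is a
package design choice.

### Stimulus protocol and readout

The in-silico startle assay applies 2-ms unit square pulses of strength WE
∈ {10, 15, …, 60} to the E cell (on top of its baseline drive
I_E0 = 43.9), 10 pulses per strength at 1-s intervals, from a freshly
settled state per configuration.  An M-cell response is an upward 0-mV
crossing (5-ms refractory) within the half-open window after the pulse;
the window defaults to the full interstimulus interval.  A short window
would be wrong here: near threshold the E cell answers one pulse with a
burst of 3–6 spikes spread over several hundred ms (its calcium adaptation
holds it just below a SNIC bifurcation), and the M-cell spike can trail
the pulse by 25–140 ms.  The primary readout is the response fraction over
the 10 pulses — the model analogue of startle probability; per-window
spike counts are kept as a secondary readout.  The fraction is graded
because slow calcium and gI dynamics accumulate over the train, so later
pulses can fail where early ones succeed.

### Blockade conditions

* `d1_block`: D1_M = 0, D1_GL = 0 (Drd1 antagonism, e.g. SCH 23390).
* `gaba_block`: g_GA→M = 0, g_GA→GL = 0 and β_GL lowered to the
  status-specific value (GABA_A antagonism, e.g. bicuculline; the β_GL drop
  prolongs glycinergic inhibition of the M-cell).
* `gly_block`: g_GL→M = 0 (glycine-receptor antagonism, e.g. strychnine).

With the defaults above, the grid-summed response fractions reproduce five
of the six reported directions: dominant D1-block +2.5, dominant
glycine-block +2.5 (both strong increases), subordinate D1-block and
glycine-block 0.0 (unchanged), subordinate GABA-block −0.4 (decrease).
The sixth direction — dominant GABA-block approximately unchanged — is not
reproduced: the summed delta is +1.0, because removing the direct GABA→M
synapse (g_GA→M = 0.4, equal in both presets) disinhibits the dominant
M-cell more than the β_GL = 0.024 glycine prolongation compensates.
Scanning the settling duration (2–30 s) and response window (50–950 ms)
shows this residual increase and the subordinate decrease trade off
monotonically through the gI baseline and cannot both sit inside their
reported bands; the corresponding acceptance test is left failing rather
than tuned around.

## Behavioral analysis

**Swim bursts.**  Far-field potential recordings are scanned for swim
bursts with the published acceptance rule: peak-to-peak amplitude ≥ 8 mV
and duration 30–200 ms.  Candidate events come from hysteresis
thresholding of |v − median(v)| (enter 4 mV, extend above 2 mV), merging
candidates separated by < 10 ms; acceptance is then applied to each merged
segment.  The hysteresis/merge parameters are package choices (the
original analysis used a commercial threshold tool without algorithmic
detail); the 8 mV / 30–200 ms acceptance values are the published ones.
Counts are normalized per minute.

**Startle psychometrics.**  M-cell-mediated startles are all-or-none with
5–15 ms latency; responded trials outside that window are excluded as
non-Mauthner responses.  Response probability is tabulated per animal per
intensity on the 70–100 dB (5-dB step) grid, averaged across animals, and
fitted with the four-parameter Boltzmann sigmoid
Y = Bottom + (Top−Bottom)/(1+exp((V50−X)/Slope)) by least squares
(scipy `curve_fit`; fixed initial-guess rule: Bottom = min y, Top = max y,
V50 = x nearest the mid-range response, Slope = 5 dB, for determinism).
Flat curves are returned flagged degenerate rather than fitted.

## Comparative-Ct quantification

Technical replicates are averaged per sample; ΔCt = Ct(gene) − Ct(actb2)
per sample; ΔΔCt = mean ΔCt(group) − mean ΔCt(isolate control) per gene.
Relative expression uses per-gene amplification factors E = 1 + p/100 from
the published primer-efficiency table (shipped with the package).  The
default correction is the Pfaffl ratio
E_target^(−ΔCt_target shift) / E_ref^(−ΔCt_ref shift) computed from raw
group-mean Ct shifts; the simpler E_target^(−ΔΔCt) form is selectable
(`method="simple"`).  Both collapse to 2^(−ΔΔCt) at 100 % efficiency.
Results are reported as fold change and log2(fold).  Efficiencies above
100 % (factors > 2.0) are accepted with a warning, as such values are
routinely reported assay artifacts; factors above 2.5 are rejected.

## Synthetic data

Generators are pure functions of (spec, seed) and carry their ground truth:

* **Swim traces**: flat-topped (Tukey α=0.2) sinusoid packets at 150 Hz
  atop Gaussian baseline noise (default sd 0.5 mV).  The fast carrier and
  flat envelope make the detectable extent track the scheduled duration,
  so detection depends on the envelope rather than carrier phase — a slow
  sinusoid would fragment under the 10-ms merge rule.  What this does not
  emulate: electrode/motion artifacts, drifting baselines, variable
  within-burst spectra; perfect recovery in tests bounds detector
  correctness, not field performance.
* **Startle trials**: per animal and intensity, Bernoulli draws from a
  ground-truth Boltzmann curve; response latencies uniform on 6–14 ms with
  an optional contaminant fraction of slow (> 15 ms) non-Mauthner
  responses to exercise the latency filter.  No between-animal curve
  heterogeneity is modeled, so cohort recovery tolerances (V50 ± 1 dB)
  reflect sampling noise only.
* **Ct tables**: reference-gene baseline ~20 cycles, target baselines ~24;
  group fold changes enter as Ct shifts of −log2F·ln2/lnE cycles; Gaussian
  noise per technical replicate.  No plate/batch effects.

## Known limitations

* Single explicit M-cell; the contralateral cell is a constant drive.
* No channel noise and no adaptive stepping; trial-to-trial gradation in
  the model arises only from slow deterministic adaptation across a pulse
  train.
* The dominant GABA-blockade direction is not reproduced (see above); all
  other simulated pharmacology directions are.
* The swim central pattern generator is outside the model's scope, so
  simulated and measured swim activity are connected only conceptually.
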