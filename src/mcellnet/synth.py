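"""Seeded generators for synthetic behavioral and molecular data.

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs.  Each returns both the synthetic dataset and the
ground truth used to build it, so downstream analyses can be validated by
parameter recovery.

The generators emulate the statistical structure of the study's recordings,
not their biophysics: swim traces are Gaussian baseline noise with enveloped
sinusoid packets standing in for swimming-bout field potentials; startle
outcomes are Bernoulli draws from a Boltzmann psychometric curve over the
70-100 dB grid; Ct tables have a reference-gene baseline, group fold shifts
expressed through the primer amplification factor, and Gaussian cycle noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows

from .behavior import INTENSITY_GRID, FieldPotentialTrace, BurstEvent, boltzmann

__all__ = [
    "SwimTraceSpec",
    "StartleSimSpec",
    "CtSimSpec",
    "gen_swim_trace",
    "gen_startle_trials",
    "gen_ct_table",
]


@dataclass
class SwimTraceSpec:
    """Schedule of synthetic swim bursts atop Gaussian baseline noise.

    Bursts are flat-topped (Tukey-windowed) sinusoid packets at
    ``carrier_hz`` whose peak-to-peak amplitude and duration are set per
    burst.  Swim-bout far-field potentials are trains of fast muscle-field
    deflections, so the default carrier is 150 Hz: fast enough that the
    rectified packet has no quiet gap longer than the detector's 10 ms merge
    window, making detection depend on the packet envelope rather than the
    carrier phase.  The flat envelope keeps the detectable extent close to
    the scheduled duration.
    """

    duration_s: float = 60.0
    sample_rate_hz: float = 5000.0
    onsets_ms: tuple = ()
    durations_ms: tuple = ()
    amplitudes_mV: tuple = ()
    carrier_hz: float = 150.0
    noise_sd_mV: float = 0.5

    def __post_init__(self):
        n = len(self.onsets_ms)
        if not (len(self.durations_ms) == len(self.amplitudes_mV) == n):
            raise ValueError("onsets, durations and amplitudes must have equal length")
        if any(d <= 0 for d in self.durations_ms) or any(
            a <= 0 for a in self.amplitudes_mV
        ):
            raise ValueError("durations and amplitudes must be positive")
        order = np.argsort(self.onsets_ms)
        for i, j in zip(order[:-1], order[1:]):
            if self.onsets_ms[i] + self.durations_ms[i] > self.onsets_ms[j]:
                raise ValueError("scheduled bursts overlap")


def gen_swim_trace(
    spec: SwimTraceSpec, seed: int = 0
) -> tuple[FieldPotentialTrace, list[BurstEvent]]:
    """Render a swim trace and return it with the scheduled ground truth."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    v = (
        rng.normal(0.0, spec.noise_sd_mV, size=n)
        if spec.noise_sd_mV > 0
        else np.zeros(n)
    )
    truth = []
    for onset, dur, amp in zip(spec.onsets_ms, spec.durations_ms, spec.amplitudes_mV):
        a = int(round(onset * spec.sample_rate_hz / 1000.0))
        b = int(round((onset + dur) * spec.sample_rate_hz / 1000.0))
        b = min(b, n)
        if a >= n:
            continue
        m = b - a
        t = np.arange(m) / spec.sample_rate_hz
        envelope = windows.tukey(m, alpha=0.2)  # flat top, 10% taper per edge
        packet = envelope * np.sin(2.0 * np.pi * spec.carrier_hz * t)
        peak = packet.max() - packet.min()
        if peak > 0:
            v[a:b] += packet * (amp / peak)
        truth.append(
            BurstEvent(
                onset_ms=a * 1000.0 / spec.sample_rate_hz,
                offset_ms=b * 1000.0 / spec.sample_rate_hz,
                peak_to_peak_mV=amp,
            )
        )
    return FieldPotentialTrace(v, spec.sample_rate_hz), truth


@dataclass
class StartleSimSpec:
    """Bernoulli startle trials drawn from a ground-truth Boltzmann curve.

    Each animal receives ``trials_per_intensity`` pulses at every grid
    intensity (the assay delivered each intensity three to five times).
    Responded trials get latencies uniform on ``latency_range_ms`` (inside
    the 5-15 ms Mauthner window); a ``contaminant_fraction`` of responses
    instead get slow (>15 ms) non-Mauthner latencies to exercise the filter.
    """

    bottom: float = 0.0
    top: float = 1.0
    v50: float = 85.0
    slope: float = 3.0
    grid: tuple = INTENSITY_GRID
    trials_per_intensity: int = 5
    n_animals: int = 40
    latency_range_ms: tuple = (6.0, 14.0)
    contaminant_fraction: float = 0.0
    contaminant_latency_range_ms: tuple = (16.0, 40.0)

    def __post_init__(self):
        if self.trials_per_intensity < 1 or self.n_animals < 1:
            raise ValueError("trials_per_intensity and n_animals must be >= 1")
        p = boltzmann(np.asarray(self.grid, float), self.bottom, self.top,
                      self.v50, self.slope)
        if (p < 0).any() or (p > 1).any():
            raise ValueError("truth curve yields probabilities outside [0, 1]")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must lie in [0, 1]")


def gen_startle_trials(spec: StartleSimSpec, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate startle trial tables for a cohort of animals.

    Returns (trials, truth) where trials has columns animal_id,
    intensity_dB, responded, latency_ms and truth records the generating
    Boltzmann parameters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(spec.n_animals):
        for x in spec.grid:
            p = float(boltzmann(x, spec.bottom, spec.top, spec.v50, spec.slope))
            for _ in range(spec.trials_per_intensity):
                responded = bool(rng.random() < p)
                if responded:
                    if spec.contaminant_fraction and rng.random() < spec.contaminant_fraction:
                        lo, hi = spec.contaminant_latency_range_ms
                    else:
                        lo, hi = spec.latency_range_ms
                    lat = float(rng.uniform(lo, hi))
                else:
                    lat = math.nan
                rows.append(
                    {
                        "animal_id": f"fish{a:03d}",
                        "intensity_dB": x,
                        "responded": responded,
                        "latency_ms": lat,
                    }
                )
    truth = {
        "Bottom": spec.bottom,
        "Top": spec.top,
        "V50": spec.v50,
        "Slope": spec.slope,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


@dataclass
class CtSimSpec:
    """qPCR Ct tables with known group fold changes vs the isolate control.

    ``log2_folds`` maps (group, gene) to the true log2 fold change relative
    to the control group.  Target-gene Ct values shift by
    -log2fold * log(2)/log(E_gene) cycles (so analysis with the same
    amplification factors recovers the folds); the reference gene is
    unshifted.  Gaussian noise of ``noise_sd`` cycles is added per technical
    replicate.
    """

    genes: tuple = ("drd1b", "dat")
    groups: tuple = ("dominant", "subordinate")
    control_group: str = "isolate"
    reference_gene: str = "actb2"
    log2_folds: dict = field(default_factory=dict)
    baseline_ct: dict = field(default_factory=dict)
    efficiencies: dict = field(default_factory=dict)  # gene -> amplification factor
    n_replicates: int = 10
    n_technical: int = 2
    noise_sd: float = 0.2

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be >= 1")


def gen_ct_table(spec: CtSimSpec, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate a tidy Ct table (sample_id, group, gene, replicate, Ct)."""
    rng = np.random.default_rng(seed)
    genes = (spec.reference_gene,) + tuple(
        g for g in spec.genes if g != spec.reference_gene
    )
    groups = (spec.control_group,) + tuple(
        g for g in spec.groups if g != spec.control_group
    )
    rows = []
    for group in groups:
        for i in range(spec.n_replicates):
            sample = f"{group}_{i:02d}"
            for gene in genes:
                base = spec.baseline_ct.get(
                    gene, 20.0 if gene == spec.reference_gene else 24.0
                )
                ct = base
                if group != spec.control_group and gene != spec.reference_gene:
                    lf = spec.log2_folds.get((group, gene), 0.0)
                    eff = spec.efficiencies.get(gene, 2.0)
                    # fold = eff^(-dCt shift)  =>  shift = -log2fold * ln2/ln(eff)
                    ct -= lf * math.log(2.0) / math.log(eff)
                for rep in range(spec.n_technical):
                    noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "Ct": ct + noise,
                        }
                    )
    truth = {
        "log2_folds": {f"{g}:{gene}": v for (g, gene), v in spec.log2_folds.items()},
        "seed": seed,
    }
    return pd.DataFrame(rows), truth
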