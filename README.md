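# betasync

Analysis pipeline for corticostriatal beta-band synchrony in multi-electrode
electrophysiology, aimed at the parkinsonian oscillation biomarker: excessive
high-beta/low-gamma (25–40 Hz) local field potential (LFP) activity and its
coupling between motor cortex and dorsolateral striatum in the 6-OHDA
hemi-lesioned rat model. It is written for electrophysiologists who need a
tested, reproducible implementation of the standard biomarker battery:

- **Band power** — Welch power spectral densities (1-s Hann windows, 50 %
  overlap) integrated over the conventional rodent bands: alpha (8–12 Hz),
  low-beta (12–18, 19–25 Hz), high-beta/low-gamma (25–40 Hz), high-gamma
  (40–50 Hz).
- **Corticostriatal coherence** — magnitude-squared coherence
  `Cxy(f) = |Pxy(f)|² / (Pxx(f)·Pyy(f))` from co-estimated Welch spectra,
  band-averaged per electrode pair and then across the cortex × striatum
  pair grid.
- **Spike–field phase locking** — the instantaneous 25–40 Hz phase at each
  spike (zero-phase band-pass + Hilbert transform), tested for circular
  uniformity with the Rayleigh test (`Z = nR²`) on exactly 40 randomly
  selected spikes per unit; units with fewer than 40 spikes are excluded.
- **STWA shuffle ratio** — the peak-to-trough magnitude of the band-filtered
  spike-triggered waveform average, divided by the mean magnitude over 20
  ISI-shuffled surrogate trains (≈ 1 under independence).
- **Unit metrics** — trough-to-peak waveform duration, firing rate, a
  putative pyramidal/interneuron split, the ≥ 1 ms refractory screen, and
  the spike-sorting separation indices (pseudo-F, J3, Davies–Bouldin).
- **Group statistics** — KS normality screening, one/two-way ANOVA with
  Bonferroni post-hoc (rank-based fallbacks), paired t, and the 2×2
  chi-square on locked-unit proportions.

Because recordings of this kind are rarely shared, the package includes a
first-class **synthetic cohort simulator**: two regions on ≥ 4 electrodes
each, 60-s rest/walking segments, a shared narrowband beta source with known
gains (hence a closed-form expected band coherence), 1/f backgrounds, and
cortical units spiking as von Mises-modulated inhomogeneous Poisson
processes (expected vector strength `I1(κ)/I0(κ)`). Every analysis stage is
validated against this ground truth.

## Worked example

```python
import betasync as bs

# simulate one 60-s rest segment: 4 cortex + 4 striatum electrodes,
# shared 25-40 Hz source, 8 cortical units (half locked at kappa = 2)
cfg = bs.SimulationConfig()
segment, truth = bs.synthesize_segment(cfg, "rest", seed=777)

# corticostriatal coherence, averaged over the 16 electrode pairs
coh, pairs = bs.region_pair_coherence(segment)
print(f"measured 25-40 Hz coherence {coh:.3f} "
      f"(ground truth {truth.expected_band_coherence:.3f})")

# phase locking of the first unit to the strongest cortical electrode
unit = segment.spikes[0]
i = bs.spikefield.select_target_channel(segment, "motor_cortex")
phase = bs.instantaneous_phase(segment.recording.samples[i], 1000.0)
angles, _ = bs.spike_phases(unit.spike_times_s, phase, 1000.0)
res = bs.rayleigh_test(angles, seed=0)
print(f"unit {unit.unit_id}: R={res.r:.2f} Z={res.z:.1f} p={res.p:.2g} "
      f"locked={res.locked}")
```

prints (seed 777):

```
measured 25-40 Hz coherence 0.138 (ground truth 0.128)
unit unit00: R=0.55 Z=12.3 p=1.8e-06 locked=True
```

The measured coherence sits just above the ground-truth value because the
Welch coherence estimator carries a positive bias of ≈ 1/K (K = 119 windows
here). The locked unit was simulated at κ = 2 (von Mises vector strength
0.70 against its true generating phase); the measured R of 0.55 is lower
because the phase is re-estimated from the chosen electrode, whose 1/f
background dilutes the oscillation — exactly the attenuation a real
recording would show.

A full cohort run (simulate → preprocess → all analyses → statistics):

```bash
betasync run-all --out report/ --seed 1 --scale smoke
```

writes `band_power.csv`, `coherence.csv`, `spikefield.csv`, `units.csv`,
`stats.json` and a run manifest with the config hash and seed.

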