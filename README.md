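# caminer

Tools for mining carbonic anhydrases (CAs) out of extreme-environment
metagenomes and for characterizing them as CO₂-capture biocatalysts.

Carbonic anhydrases accelerate the hydration of CO₂ to bicarbonate and a
proton, the rate-limiting step of hot potassium carbonate (HPC) carbon
capture. Enzymes that can serve as HPC promoters must survive ≥ 80 °C and
pH ≈ 11.5, so discovery efforts screen metagenomes from hot, alkaline
environments. `caminer` implements that screening cascade and the three
analyses used to qualify a hit:

* **`caminer.candidate_screen`** — the two-branch selection cascade over
  predicted proteins. Proteins with at least one domain hit against a
  curated set of CA-related Pfam profiles (the "SCAP" set, e.g. `Pro_CA`,
  `Carb_anhydrase`, `CsoSCA`) form one branch; the remainder qualify via a
  similarity hit (e-value ≤ 10⁻⁵⁰) against a keyword-filtered reference
  ("carbonic anhydrase" / "carbonic dehydratase" / whole-token "ca").
  Survivors are curated by β-CA active-site motifs (`CxDxR`, `HxxC`),
  gene start/stop codons (ATG/GTG/TTG, TAA/TGA/TAG), protein length against
  the family mean, signal-peptide/transmembrane flags, sampling-site
  environment (T ≥ 90 °C, alkaline pH), and greedy de-duplication at 90 %
  pairwise identity (global alignment, in-repo dynamic-programming aligner).
* **`caminer.stopped_flow`** — pH-indicator stopped-flow kinetics: initial
  absorbance rates, uncatalyzed-background subtraction, conversion to CO₂
  hydration rates through the buffering factor *Q* (Henderson–Hasselbalch
  derivatives of buffer + indicator at the working pH), and nonlinear
  Michaelis–Menten fits, v = V·S/(K_M + S), reporting k_cat, K_M and the
  catalytic efficiency k_cat/K_M.
* **`caminer.stability`** — Wilbur–Anderson activity units
  WA = (t₀ − t)/t, residual activity/solubility percentages, and half-life
  by log-linear interpolation of the first 50 % crossing (a transient
  thermal-activation bump is discarded by starting at the series maximum).
* **`caminer.reactor`** — closed pressurized batch absorption: the ideal-gas
  mass balance n_abs(t) = (P₀ − P(t))·V_head/(R·T) converts the recorded
  pressure drop into absorbed CO₂, from which the initial absorption rate,
  plateau time, productivity (mmol CO₂ L⁻¹ min⁻¹ up to the plateau) and
  removal efficiency (% of the initial CO₂ inventory) are computed; a
  pseudo-first-order forward simulator supports testing.
* **`caminer.synthetic_data`** — seeded generators for every input:
  screening fixtures with planted positives and per-criterion decoys,
  stopped-flow traces (mechanistic forward model), decay series, and
  reactor pressure curves.

Raw metagenomes and instrument traces are consumed, never produced: the
package reads the standard formats (FASTA, HMMER3 `domtblout`, 12-column
tabular BLAST, Phobius short output, TSV metadata, CSV time series) written
by the usual upstream tools.

## Worked example

```python
import numpy as np
from caminer import candidate_screen as cs, reactor as rx
from caminer import stopped_flow as sf, synthetic_data as sd

# screening: plant 4 positives among 12 proteins, run the cascade
fx = sd.make_screen_fixture(12, 4, seed=7)
reports = cs.compile_report(*fx.cascade_inputs())
print(sorted(cs.selected_ids(reports)))   # ['p0000', 'p0003', 'p0010', 'p0011']
print(sorted(fx.truth))                   # ['p0000', 'p0003', 'p0010', 'p0011']

# kinetics: noisy initial-rate data at 3.4-17 mM CO2, 350 nM enzyme
S, v = sd.make_mm_dataset(1.2e3, 4.9e-3, 350e-9,
                          [3.4e-3, 6.8e-3, 10.2e-3, 13.6e-3, 17e-3],
                          noise_frac=0.03, replicates=3, seed=1)
fit = sf.fit_mm(S, v, 350e-9)
print(f"kcat = {fit.kcat:.3g} 1/s  KM = {fit.KM*1e3:.3g} mM  "
      f"kcat/KM = {sf.round_sig(fit.kcat_over_KM, 2):.2g} 1/(M*s)")
# kcat = 1.18e+03 1/s  KM = 4.64 mM  kcat/KM = 2.5e+05 1/(M*s)

# reactor: enzyme-enhanced absorption run at 90 C, 7 bar, 20% CO2
cfg = rx.ReactorConfig(temperature=rx.celsius_to_kelvin(90.0))
run = rx.simulate_pressure(cfg, rx.ForwardParams(kla=0.03, enhancement=2.0),
                           np.arange(0.0, 211.0))
m = rx.analyze(run, cfg)
print(f"initial rate = {m.initial_rate:.2f} mmol/(L*min), "
      f"removal = {m.removal_efficiency:.0f}%, plateau = {m.plateau_time:.0f} min")
# initial rate = 4.94 mmol/(L*min), removal = 100%, plateau = 67 min
```

The selected ids equal the planted truth: every cascade criterion was
satisfied only by the positives. The fitted constants recover the
generating values (k_cat 1.2 × 10³ s⁻¹, K_M 4.9 mM) within the 3 % assay
noise, and the efficiency rounds to 2.5 × 10⁵ M⁻¹ s⁻¹ for this replicate.
In the reactor run the doubled mass-transfer enhancement shows up directly
in the initial absorption rate, and the closed vessel approaches complete
CO₂ removal.

A command-line interface mirrors the library
(`caminer synth|screen|kinetics|stability|reactor --help`).

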