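# barct — carbonate budgets of coral blocks from paired micro-CT scans

Coral reef frameworks persist only while calcium-carbonate construction
(accretion by corals, crustose coralline algae, molluscs) outpaces
destruction (macroboring worms and sponges, microboring flora, grazing
fishes and urchins). Ocean acidification shifts that balance. A direct
way to measure it is to deploy small blocks of cleaned coral skeleton
("bioerosion accretion replicates", BARs) on a reef for ~2 years, scan
them by micro-CT before and after, and incubate the recovered blocks in
closed chambers to measure community calcification.

`barct` implements that whole measurement chain for users who have the
reconstructed scan volumes and chamber records (or who want to study the
method itself on simulated data with known ground truth):

* **Voxel partition.** The post-deployment scan (pitch 64.23 µm) is
  rigidly registered onto the pre-deployment scan (59.51 µm). With
  carbonate masks `M_pre`, `M_post` and "solid hulls" `H` (the block plus
  its internal voids, built by morphological closing of tunnel apertures
  and flood-filling), every voxel of the pre-scan grid is classified by
  set algebra:

      accretion        = M_post \ H_pre
      grazed           = H_pre \ H_post
      macroboring_void = (H_post \ M_post) ∩ H_pre
      original_remaining = M_post ∩ H_pre

  which makes `|H_pre| = remaining + macroboring + grazed` an exact
  identity, asserted on every run.

* **Densitometry.** Aragonite phantoms of known density give a linear
  calibration ρ = a·attenuation + b; microboring (boreholes < 100 µm,
  unresolvable at the scan pitch) is measured as the bulk density loss of
  the non-bored, non-grazed carbonate: Δρ̄ × V_remaining (grams).

* **Incubation chemistry.** Calcification by the alkalinity anomaly:
  G = −(ΔA_T/2)·m_sw / (SA·Δt) in µmol CaCO₃ cm⁻² h⁻¹ (2 mol alkalinity
  per mol CaCO₃; blank-corrected, normalized to the post-deployment
  surface area); O₂ fluxes in µg O₂ cm⁻² min⁻¹; 24-h net calcification as
  (11·G_light + 13·G_dark)/24. A total-scale carbonate-system solver
  (Lueker K₁/K₂, Dickson K_B, Mucci aragonite K_sp) turns field A_T/DIC
  into pH, pCO₂ and Ω_arag.

* **pH-response models.** Gaussian-identity or Gamma-log GLMs of each
  metric against pH, rank-sum/Welch site contrasts, and the headline
  statistic: the pH at which pooled 24-h calcification crosses zero (net
  accretion → net dissolution), with a case-resampling bootstrap CI.

* **Synthetic data.** Every input can be simulated with exact
  voxel-counted ground truth: textured carbonate blocks with imposed
  accretion patches, capsule-shaped borer tunnels, grazing scars, bulk
  density loss, a rigid pre→post offset with differing voxel pitches,
  scanner noise; phantom scans; incubation records; pH-response scatter.

## Worked example

```python
import barct
from barct.synthetic_data import make_batch_specs, make_bar_pair, make_phantom_set
from barct.volume_io import fit_densitometry

phantoms = make_phantom_set([1.2, 1.6, 2.0, 2.4], noise_sd=2.0, seed=7)
cal = fit_densitometry([(v.values.mean(), d) for v, d in phantoms])

spec = make_batch_specs(n=1, seed=7)[0]          # one simulated deployment
pre, post, truth = make_bar_pair(spec)
result = barct.analyze_bar_pair(pre, post, cal)

r = result.rates
print(f"macroboring {r.macroboring_cm3_per_cm2:.2e} cm3/cm2 "
      f"(truth {truth.macroboring_volume_cm3 / truth.initial_surface_area_cm2:.2e})")
print(f"microboring {r.microboring_g_per_cm2:.2e} g/cm2")
print(f"initial surface area {r.initial_surface_area_cm2:.2f} cm2")
```

prints (exact values depend on the seed):

```
macroboring 7.73e-04 cm3/cm2 (truth 7.61e-04)
microboring 1.38e-02 g/cm2
initial surface area 1.99 cm2
```

The `analysis/` directory holds the full narrative study on simulated
data: `01_simulate_deployment.py` (two sites spanning a pH gradient, the
volumes land in `scratch/`), `02_quantify_blocks.py`,
`03_incubation_rates.py`, and `04_ph_response.py`, which ends with, e.g.

```
pooled 24-h calcification crosses zero at pH 7.804 (95% CI 7.786-7.817, n = 12)
```

— the simulated communities switch from net accretion to net dissolution
near pH 7.8, the condition imposed by the generator.

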