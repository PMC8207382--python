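# shellbands

Quantitative morphometrics of banded snail shells.  The package is
aimed at researchers studying shell colour-pattern polymorphism (the
*Cepaea* model system and similar banded gastropods) who want to move
from qualitative banding scores ("12345", "00300") to measured band
positions, widths and growth rates — and to test how bands interact with
each other, with the gaps between them, and with shell growth.

It provides:

* a **3D logarithmic-helicospiral shell model** with circular apertures:
  aperture centre `(r0 e^{g_r θ} cos θ, ±r0 e^{g_r θ} sin θ, −z0 e^{g_z θ})`
  and aperture radius `a0 e^{g_a θ}`, including the suture-to-umbilicus
  measurement arc, swept surface meshes (OBJ/PLY) with band labelling,
  and whorl height/width increments for allometry tests;
* **band parameterization** on the growing aperture: bands as
  material-fixed angular sectors, region-width profiles at the five
  quarter-whorl stations of the last whorl, and per-region growth rates
  (log-ratio per quarter whorl — exactly `g_a π/2` for isometric
  shells);
* **landmark-based model fitting** from aperture-up photographs
  (orthographic projection + similarity pose, trust-region least squares
  with multi-start), and band extraction from edge landmarks on the lip;
* **tape-method data handling**: banding-formula parsing (`0`, `.`,
  `:`, fusions `123(45)`), standardization of caliper marks to
  percent-of-arc metrics, CSV I/O with row-level error reporting;
* the **statistical toolkit** used in banding studies: exact/corrected
  Mann-Whitney, Kruskal-Wallis + Dunn-BH, mean-centered KS, Wilcoxon
  signed-rank, band×gap Pearson correlation matrices, Bland-Altman
  agreement, 1-D Gaussian-mixture modality selection by BIC, AIC
  model-set averaging with full-coefficient (zero-substitution)
  averages, fixed-effect deletion LRTs and Tukey-adjusted least-square
  means over linear mixed models;
* **synthetic-data generators** for all of the above: parameterized
  shells, noisy landmark sets, measurement populations with
  phenotype-specific band shifts and negative band-gap width coupling,
  and paired two-method tables.

## Worked example

Simulate a measured population (100 five-banded and 100 mid-banded
shells), standardize it, and ask whether the mid-band sits higher on the
shell when the other bands are absent:

```python
from shellbands import (PopulationConfig, gen_population, standardize_table,
                        mann_whitney, band_gap_correlations)

cfg = PopulationConfig(seed=42)
cfg.n_per_phenotype = {"12345": 100, "00300": 100}
table = standardize_table(gen_population(cfg))

mid  = table.loc[table.phenotype == "00300", "b3_pos"].dropna()
five = table.loc[table.phenotype == "12345", "b3_pos"].dropna()
print(mid.mean(), five.mean())      # 26.52 27.60  (% of suture-umbilicus arc)
print(mann_whitney(mid, five))      # <W = 3754, p = 0.00234>

r, p = band_gap_correlations(table[table.phenotype == "12345"])
print(r.loc["b3_w", "g4_w"], p.loc["b3_w", "g4_w"])   # -0.28, 0.0046
```

The mid-banded band 3 sits about a percentage point closer to the suture
than the same band on five-banded shells, and a wider band 3 predicts a
narrower gap below it — the band expands into its neighbouring gaps.

Region growth along the last whorl of an allometric shell
(`g_z = 0.10 > g_r = g_a = 0.08`):

```python
from shellbands import region_profile, default_band_config
from shellbands.banding import mean_region_rates
from shellbands.synthesis import default_allometric_shell

means = mean_region_rates(region_profile(default_allometric_shell(),
                                         default_band_config()))
print(means.round(4))
# gap1 0.1661, band1..band5 and gap2..gap5 all 0.1257, gap6 0.1663
```

Every band and interior gap grows at the same rate (0.1257 per quarter
whorl = `g_a π/2`); only the outermost regions — above all at the gap
between the last band and the umbilicus — grow faster.  Lower bands are
wider because they start wider, not because they grow faster.

The same measures can be taken from a photograph via the CLI:

```bash
shellbands simulate landmarks --seed 5 --out lm.csv     # or your own landmark CSV
shellbands fit --landmarks lm.csv --mm-per-px 0.05 --out fit.json
# rms residual: 0.7303 px -> fit.json
# band 1: position 8.79% width 3.80%   (true 9.1 / 3.6)
# band 3: position 26.70% width 8.73%  (true 27.0 / 9.1)
```

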