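# prolylkin

Analysis toolkit for peptidyl-prolyl isomerase (PPIase) studies on long
peptide substrates, built around the two-domain bacterial isomerase SlyD:
a catalytic FKBP domain and an inserted chaperone ("IF") domain, each with
its own substrate site.

The package implements the full computational chain such a study needs:

* **NMR lineshape kinetics** (`prolylkin.lineshape`) — simulation and
  fitting of 1D two-site chemical-exchange absorption lineshapes.  A
  leucine methyl resonance splits into cis and trans lines; an isomerase
  raises the apparent exchange rate k_ex = k_ct + k_tc and broadens the
  lines.  Spectra follow the steady-state Bloch–McConnell equations; the
  single free shape parameter k_ex is fitted with populations, positions
  and intrinsic widths held fixed, and uncertainties come from seeded
  Monte-Carlo refits.
* **Catalytic efficiency** (`prolylkin.kinetics`) — for substrate
  concentrations below K_M, k_app([E]) = k_0 + (k_cat/K_M)·[E]; the slope
  of a (weighted) linear regression over an enzyme titration is k_cat/K_M.
  Includes the limiting-regime algebra k_cat/K_M = k_on·k_cat/(k_off+k_cat)
  with its binding-equilibrated ("EX2-like", → k_cat/K_D) and
  association-limited ("EX1-like", → k_on) limits, and the dissociation
  rate bound k_off ≤ k_on·K_D.
* **ITC binding models** (`prolylkin.itc`) — Wiseman isotherms for one or
  two independent site classes (n, K_D, ΔH per class), with perfusion-cell
  dilution bookkeeping, displaced-volume-corrected differential heats per
  mole of injectant, and least-squares fitting with c-value diagnostics.
* **Structure geometry** (`prolylkin.structure`) — PDB/mmCIF Cα parsing
  (gemmi), Kabsch superposition, core-domain and per-residue peptide RMSDs,
  and the inter-domain metrics d (Cα 99–146 distance) and δ (angle at Cα 19
  subtended by Cα 145 and 95) with nearest-centroid classification into
  closed / tight / loose / open conformations.
* **Outlier-robust statistics** (`prolylkin.stats`) — exact 2D Tukey
  halfspace depth, depth-contour bagplots (fence = 3× bag) for bivariate
  outlier screening, Spearman rank correlation with exact permutation
  p-values at small n, OLS with confidence bands, and centred/scaled PCA.
* **Synthetic data** (`prolylkin.synthetic`) — seeded generators for
  titration spectra, isotherms and toy two-domain structures with
  machine-readable truth manifests, emulating the assay conditions
  (100 µM substrate, 0–6 µM enzyme; 1×3 µl + 42×6.5 µl injections of
  1.2 mM peptide into 50 µM protein).

A transcription of the published thermodynamic/activity table for the
S2-derived peptide variant library ships as a packaged fixture
(`prolylkin.datasets.load_binding_activity_table`).

## Worked example

Screen the variant table for bivariate outliers and correlate the
catalytic-site dissociation constants of the full-length protein against
the construct lacking the chaperone domain:

```python
from prolylkin.datasets import load_binding_activity_table
from prolylkin.stats import PairedObservations, bagplot_outliers, spearman

table = load_binding_activity_table()
obs = PairedObservations.from_frame(table, "kd_fkbp_uM", "kd_dif_uM")
outliers = bagplot_outliers(obs).outlier_labels
res = spearman(obs, exclude=outliers)
print(outliers, round(res.rho, 2), res.p_value, res.n_used)
```

prints

```
('W4E',) 0.98 2.0943562610229278e-05 10
```

i.e. the bagplot flags the W4E variant as the sole outlier, and across the
remaining 10 variants the two dissociation constants correlate with
Spearman ρ = 0.98 (exact permutation p ≈ 2·10⁻⁵): the chaperone domain
strengthens substrate binding to the catalytic site without reordering the
variants.  The same machinery gives ρ = −0.79 (p < 0.05, Y3A excluded)
for K_D versus activity of the chaperone-less construct, and ρ = −0.53
across the 9 complete variants for total binding enthalpy versus
full-length activity.

The same analyses are available from the shell:

```bash
prolylkin stats correlate --x kd_fkbp_uM --y kd_dif_uM --bagplot
prolylkin synth itc --out /tmp/itc && prolylkin itc fit --data /tmp/itc/isotherm.csv --sites 2
```

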