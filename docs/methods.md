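# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer should know about.

## Two-site exchange lineshapes

The cis/trans prolyl isomers give a methyl resonance two environments with
populations p_cis + p_trans = 1, positions ν_cis, ν_trans (Hz) and
intrinsic transverse relaxation rates r2_cis, r2_trans (s⁻¹; Lorentzian
FWHM = r2/π).  Exchange at total rate k_ex = k_ct + k_tc, with detailed
balance k_ct = p_trans·k_ex and k_tc = p_cis·k_ex, couples the transverse
magnetizations M = (M_cis, M_trans):

    dM/dt = L M,
    L = [[−r2_cis + 2πi·ν_cis − k_ct,  k_tc],
         [k_ct,  −r2_trans + 2πi·ν_trans − k_tc]],  M(0) = (p_cis, p_trans).

The absorption spectrum is I(ω) = Re[ 1ᵀ (iωI − L)⁻¹ M(0) ], evaluated via
the eigendecomposition of L (a sum of two complex Lorentzians).  This is
algebraically identical to inverting the 2×2 system at every frequency —
the tests verify agreement to better than 1e−8 relative — but needs one
diagonalization per parameter set.  The integral over the frequency axis
is amplitude/2, independent of k_ex, which the tests assert to 0.1%.

Known limits used as oracles: at k_ex = 0 the spectrum is two Lorentzians
with areas p_cis : p_trans; in slow exchange (k_ex ≪ 2πΔν) the cis line
gains width p_trans·k_ex (holds to 2% in tests); in fast exchange the
coalesced line sits at the population-weighted position with exchange
broadening p_cis·p_trans·(2πΔν)²/k_ex (5%).

**Fitting protocol.**  Populations and line positions are determined once
from the enzyme-free spectrum, intrinsic widths from a second,
non-exchanging methyl group (`fit_intrinsic_linewidth`, a four-parameter
Lorentzian fit that refuses windows containing two resolved maxima).  With
those fixed, `fit_apparent_exchange` floats only k_ex (bounded to
[0, 1e5] s⁻¹), one global amplitude and a flat baseline — a single shared
amplitude rather than per-line amplitudes, because the exchange model
itself fixes the relative line intensities through the populations.
k_ex is initialized from the excess width of the cis line.  Non-convergence
and bound-hitting are reported as flags, never silently clipped.

**Uncertainties** are one-standard-deviation Monte-Carlo estimates:
synthetic replicates = best-fit model + Gaussian noise at the spectrum's
noise level (or, if unknown, the fit residual RMS), refitted; default 500
replicates (tests use 50–120 for speed), seeded and bit-reproducible.
Fewer than 50 replicates triggers a warning.

**Units.**  Frequencies are Hz throughout; a ppm axis requires a
spectrometer frequency and is deliberately out of scope of the core
(two-column text spectra are assumed to be in Hz).

## Catalytic efficiency and regimes

Below K_M the observed exchange rate is linear in enzyme concentration;
`fit_activity_slope` fits k_app = k_0 + (k_cat/K_M)[E] by weighted
(1/σ², when uncertainties are given) or ordinary least squares via
statsmodels, reporting the slope in µM⁻¹ s⁻¹ — the concentration unit of
the packaged table — with a converter to M⁻¹ s⁻¹.  The intercept is left
free rather than pinned to the zero-enzyme rate, so a slightly
miscalibrated baseline cannot bias the slope; the zero-enzyme point simply
participates as data.  Estimates are invariant under uniform rescaling of
the uncertainties (only relative weights matter).

`efficiency_regimes` evaluates k_cat/K_M = k_on·k_cat/(k_off + k_cat) and
labels the regime by the rate ratio: ≥ 100× in either direction gives the
limit label ("EX2-like" binding-equilibrated, value → k_cat/K_D;
"EX1-like" association-limited, value → k_on), because at 100× the
limiting expression is accurate to ~1%; anything in between is
"intermediate".  `koff_upper_bound(k_on, K_D) = k_on·K_D` encodes the
diffusion-limit argument: with k_on ≤ 1e8 M⁻¹s⁻¹ and K_D = 50 µM,
k_off ≤ 5000 s⁻¹; with K_D ≤ 1 µM, k_off ≤ 100 s⁻¹.

## ITC isotherms

Independent site classes j with stoichiometry n_j, dissociation constant
K_D,j (µM) and enthalpy ΔH_j (kcal/mol).  Free titrant [X] solves the mass
balance X_t = [X] + M_t·Σ_j n_j[X]/(K_D,j + [X]) by Brent bracketing on
[0, X_t] (residual < 1e−8·X_t asserted).  Cumulative heat content
Q_i = V₀·M_t,i·Σ_j n_j·ΔH_j·[X]_i/(K_D,j+[X]_i).

**Dilution convention** (perfusion cell): after cumulative injected volume
ΔV, M_t = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀) and X_t = X_syr(ΔV/V₀)/(1 + ΔV/2V₀).
Differential heats carry the displaced-volume correction
dQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2 and are normalized per
mole of injectant.  Without the correction the differential heats
telescope exactly to Q_final (asserted); with it, the integrated heat
matches the total binding enthalpy budget to 2% when cumulative dilution
is small, degrading to ~5% under the default 43-injection protocol
(ΔV/V₀ ≈ 0.2), because protein expelled mid-titration never releases its
full binding heat.

**Fitting** floats (n_j, log₁₀K_D,j, ΔH_j) per class (n optionally fixed
at 1), excludes the first (pre-)injection by default — the community
convention for the small priming injection — and orders the fitted classes
by K_D ascending.  Standard errors come from the Jacobian covariance with
log-K_D errors propagated to K_D.  c = M_t·n/K_D outside [1, 1000] warns
that K_D is weakly determined.  The default cell volume is 1400 µl
(VP-ITC-class instrument).  All-zero heats return a flagged, unconverged
result instead of a spurious fit.

## Structure geometry

Cα-only models keyed by (chain, residue number, insertion code), read by
gemmi from PDB or mmCIF; altlocs resolve to the highest-occupancy
conformer; missing residues stay missing.  Superposition is the Kabsch SVD
solution constrained to a proper rotation.  Domain selections: FKBP
residues 1–66 + 125–150, IF residues 70–117, and a "core FKBP" subset
1–57 + 126–150 used for cross-construct comparisons.  Per-residue peptide
RMSDs first superpose all models on the FKBP domain of the first, then
collect Cα distances over all unordered model pairs per substrate
position; positions resolved in fewer than two models report NaN with
n_pairs = 0, never a fake zero.

The inter-domain metrics are d = |Cα99 − Cα146| and δ = the angle at Cα19
between the vectors to Cα145 and Cα95, both on Cα atoms (the conventional
coarse-grained choice).  Classification is nearest-centroid in (d, δ)
standardized by the reference table's mean/SD — the two axes live on
different scales — with a cutoff (default 2 standardized units) beyond
which a structure is labelled "intermediate".  The packaged reference
centroids are synthetic constructions (see the data file header): they
exercise the classifier but are not measurements of deposited structures,
so classifications of real structures should use project-specific
reference tables.

## Robust statistics

**Halfspace depth** is exact in 2D: the minimizing closed halfplane can be
taken with its boundary through the query point and normal perpendicular
to some point-to-point direction, so sweeping the candidate normals (each
direction, its perpendiculars, and ±1e−9 nudges to realize both open and
closed sides) and counting is exact; tests confirm against a dense angular
grid augmented with the critical directions.

**Bagplot.**  The depth median T is the centroid of the deepest data
points.  The bag interpolates radially about T between the exact depth
contours D_k and D_{k−1} — computed as intersections of all closed
halfplanes containing ≥ n−k+1 points (polygon clipping; verified against
pointwise depth on grids) — where k is chosen so that D_k holds at most
⌊n/2⌋ data points and D_{k−1} more, with
λ = (⌊n/2⌋ − #D_k)/(#D_{k−1} − #D_k).  The fence inflates the bag 3-fold
about T (the conventional factor); points beyond it are outliers.  Using
the contours rather than convex hulls of the deep points matters: hulls
produce degenerate, overly small bags at these sample sizes.  The whole
construction is affine-equivariant, so the optional standardization
(default on) changes only the stored geometry, never the flags — a
property the tests assert.  On the packaged variant table the screen flags
exactly W4E (K_D–K_D comparison) and Y3A (K_D–activity comparison), and
nothing in the enthalpy–activity comparison.  Small-sample caveat: with
n ≲ 20 the sample contours are jagged and points at ~2.5 SD radius are
occasionally flagged even in Gaussian clouds; the far-outlier behaviour is
unaffected.

**Spearman correlation** uses midranks (scipy).  p-values: for n ≤ 12
without ties, the exact permutation null of D = Σd² is computed by bitmask
dynamic programming over rank assignments (O(2ⁿ·n·D_max), cached per n)
and the two-sided p counts permutations with |ρ| at least as extreme; with
ties and n ≤ 7, full enumeration over rank permutations; otherwise the
asymptotic approximation.  "auto" (default) picks exact for n ≤ 10.  The
DP distribution is verified against full enumeration for n ≤ 7.  Missing
values drop the pair; constant margins raise rather than returning a
meaningless coefficient.

**Linear fits** are statsmodels OLS with pointwise confidence bands
(default 95%), optionally through the origin; **PCA** is centred, by
default unit-variance-scaled SVD on complete cases with the sign
convention that each component's largest-magnitude loading is positive.

## Synthetic generators

`FixtureConfig` holds all ground truths; one seed makes every fixture
bit-reproducible, and each generator emits a JSON-serializable truth
manifest consumed by the recovery tests.

* Titration spectra: k_ex([E]) = baseline + (k_cat/K_M)·[E] at the assay
  conditions (100 µM substrate; enzyme 0, 1, 2, 4, 6 µM), Gaussian noise
  scaled so the tallest peak sits at the configured SNR (default 100).
  Spectral defaults p_cis = 0.25, Δν = 20 Hz, r2 = 8 s⁻¹, baseline
  0.5 s⁻¹: plausible values for a leucine methyl pair of a proline
  peptide; the real peptide's cis population is not published, so 0.25 is
  an arbitrary fixed choice.  Not emulated: phase errors, baseline roll,
  solvent artefacts, field drift — so passing recovery tests demonstrate
  estimator correctness under the stated noise model, not robustness to
  real spectrometer artefacts.
* Isotherms: the default truth is the two-site constants of the
  pseudo-wild-type peptide (K_D = 0.22/3.5 µM, ΔH = −15.4/−6.4 kcal/mol,
  n = 1 each) under the standard protocol, with 0.1 kcal/mol Gaussian
  noise.  Baseline drift and injection-volume errors are not modelled.
* Toy structures: two-domain Cα traces with residues 19/95/99/145/146
  anchored so that (d, δ) are exact by construction, one model per
  conformational state, each carrying a 15-residue peptide whose core
  (positions 5–11) scatters at 0.3 Å and whose termini scatter at 3 Å —
  reproducing the qualitative pattern of a substrate conserved around the
  proline and disordered at the ends — plus a random global rigid motion
  that all metrics must ignore.  These are geometric stand-ins, not
  physically plausible protein backbones.

## Problem sizes and defaults used in the reported numbers

The acceptance script runs the table analyses at their natural sizes
(n = 8–11 variants), the lineshape oracle on 2001-point axes, the
end-to-end recovery at three efficiencies (0.5, 2, 5 µM⁻¹s⁻¹) × five
enzyme concentrations with 100 Monte-Carlo replicates per spectrum, and
the ITC round trips on the 43-injection protocol.  These sizes keep a full
run under a minute while leaving the stochastic recovery errors well
inside their tolerances (≤ ~6% for k_cat/K_M at SNR 100; exact recovery at
zero ITC noise).

## Known limitations

* The lineshape module handles exactly two exchanging sites; no
  three-site or ¹³C-edited variants.
* ITC fitting is per-experiment; no global multi-isotherm fits, no raw
  power-trace integration, no ΔG/−TΔS decomposition.
* The conformational classifier ships only synthetic reference centroids;
  real-structure classification requires user-supplied references.
* Exact Spearman p-values with ties stop at n = 7 (enumeration); larger
  tied samples fall back to the asymptotic approximation.
* The bagplot is 2D only, by definition.
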