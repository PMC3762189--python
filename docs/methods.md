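# Methods

## Reaction network and variants

The model is a deterministic mass-action ODE system in µM and seconds.
Bimolecular constants are tabulated in M⁻¹s⁻¹ (`src/branchkin/data/
rate_table.yaml`) and converted at load. Species carry an explicit
composition in conserved moieties (actin, GST-VCA dimer, Arp2/3 complex,
cortactin); every reaction channel is validated to conserve all four, so
any drift in a trajectory is purely numerical. Five variants share the
channel definitions (`reaction_sets.yaml`): actin-only (reactions 1–4),
GST-VCA monomer sequestration (1–12), Arp2/3 branching (1–25), cortactin
displacement (1–28) and GST-VCA recycling (1–25 + 29).

Filament bookkeeping uses three species: polymerized subunits (the
pyrene-equivalent readout), barbed ends, and free side-binding sites. Every
polymerized subunit contributes one side site; Arp2/3-family complexes
occupy one site reversibly; nucleation converts a nascent junction into a
mature junction (which keeps its site) plus one new barbed end and two
daughter subunits. `preformed_side_sites` adds sites without ends — the
recruitment emulation. Pointed ends are not modeled (nucleation creates
none and monomer levels keep pointed-end flux negligible).

Choices where the tabulated kinetics are ambiguous:

- **GST-VCA dimer convention.** Assay concentrations are quoted as
  monomer; the network species is the GST-linked dimer initialized at half
  the quoted value (`gv_as_dimer=True` disables the halving). Sequential
  actin loading follows the table literally, up to five monomers.
- **Reactions 14/20 (GST-VCA·Arp2/3).** The tabulated k_off (0.072 s⁻¹)
  and K_D (0.009 µM) disagree tenfold at the tabulated k_on. Because the
  K_D is the directly measured quantity (dimerization tightens VCA binding
  ~180-fold to ~9 nM) and the k_off was an adjusted, derived value, we use
  k_off = K_D·k_on = 0.0072 s⁻¹. Reaction 16 disagrees by 29% with no
  clear direction; its kinetic columns are kept and the discrepancy is
  flagged in the table.
- **Elongation from VCA-bound monomers (reactions 5/6).** Their reverse —
  a filament subunit re-forming a VCA-bound monomer — is structurally
  ill-defined; all depolymerization flux is carried by reaction 4's
  reverse at k_off·[barbed ends], giving the 1.4/11.6 ≈ 0.12 µM critical
  concentration that underlies the fluorescence calibration.
- **Cortactin side binding (reaction 26)** uses a site pool of one per six
  filament subunits (the cortactin:F-actin stoichiometry) in its rate law
  without depleting the Arp2/3 site species — occupancy is nM against µM
  of sites.
- **Sequestered GST-VCA** counts the fully assembled nascent junction
  species and GV-retaining mature junctions. Side-bound partial complexes
  (GST-VCA·Arp2/3 on a filament without both recruited monomers) are not
  junctions under this definition.
- **Spontaneous nucleation (k₃)** defaults to the midpoint (1165 s⁻¹) of
  its tabulated range; **k_nuc** defaults to 0.0038 s⁻¹, the globally
  optimized value. Both are per-scenario configurable, and the tabulated
  ranges are the dominant uncertainty on the recycling-model
  sequestered-VCA figure.

Integration uses LSODA (`scipy.integrate.solve_ivp`) with rel_tol 1e-8,
abs_tol 1e-12 µM, on a fixed output grid of ≥ 600 points; the actin dimer
pool equilibrates on ~2×10⁻⁸ s while nucleation takes ~10³ s, so a stiff
implicit method is mandatory. Rates are evaluated on concentrations clipped
at zero; excursions beyond 10³·abs_tol abort with the failure time. Total
actin drift is reported with every run and is ~10⁻¹⁴ relative in practice.
Synergy-assay simulations run to t_end = 2000 s, comfortably past the
polymerization plateau; "end of reaction" quantities are read at the final
grid point.

## Trace analytics

Fluorescence calibration anchors the initial baseline at 0 and the
equilibrium plateau at total actin − 0.1 µM (the unpolymerized monomer at
equilibrium). The plateau criterion (trailing 5% of samples within 1% of
the signal range around their mean) is configurable. The maximum
polymerization rate is the peak first derivative of a centered local
quadratic (Savitzky–Golay) fit, default window 11 points — a standard,
noise-robust choice; the underlying rate algorithm is not otherwise
prescribed. Half-time is the first linear-interpolated crossing of half the
plateau. Synergy vs cortactin is fit with fold(c) = b + a·c/(K+c) with the
background b *fixed* to the measured zero-cortactin activity; the fit is
least squares on log K (positivity, exact scale equivariance).

## Global fitting

`global_fit` floats the variant's tabulated parameters (log-transformed,
bounded, Levenberg–Marquardt via lmfit) jointly across all traces of an
ensemble. The residual of trace j is (sim − obs)/(mean_j(obs)·√T), so the
summed squares equal the documented quality-of-fit statistic

    qof = (1/T) Σ_j RSS_j / mean_j(obs)² ,

which is invariant to a common rescaling of all traces. Whether traces of
different lengths should be length-normalized is not prescribed; this
implementation does not normalize by length, and the statistic is covered
by a regression test. `scan_k_fil_on` clamps the single global
filament-side on rate across reactions 13/19/21/22 and re-optimizes the
remaining floats per grid point; the threshold is the smallest grid value
at or below the qof cutoff.

The recruitment comparison (`recruitment_test`) adds preformed side sites
to the cortactin-free branching model. Its half-time falls monotonically
toward an asymptote (~156 s at k_fil_on = 1.4×10⁶ M⁻¹s⁻¹) up to ~2 µM of
added sites, and rises slowly beyond — a hook effect: excess sites spread
Arp2/3 complexes thinly over unproductive side-bound states. Even at its
minimum the recruitment half-time stays far above the displacement model's
~74 s at saturating cortactin, which is the decisive comparison.

## Single-molecule pipeline

Preprocessing is rolling-ball background subtraction (radius 10 px)
followed by Gaussian smoothing (σ 0.5 px). The rolling ball is implemented
as a grey opening with a half-sphere structuring element; for radii ≥ 8 px
the background is estimated on a block-minimum-shrunken copy and
interpolated back (the classic ImageJ speed-up), which also keeps spots out
of the background estimate. Detection applies a difference-of-Gaussians
band-pass (σ 1.0/3.0 px — cutoffs are a documented default, not
prescribed), a global threshold at median + 5 robust SD, connected-component
segmentation and intensity-weighted centroids; components within 3 px of
the frame border are discarded as un-localizable.

Linking is greedy mutual-nearest-neighbor between consecutive frames within
a displacement gate (default 2 px), with **no gap closing** — a one-frame
disappearance ends a track. The four-rule filter then removes tracks that
(1) touch the first or last frame, (2) last a single frame, (3) have a mean
intensity beyond one SD of the population of track means (computed over
tracks passing rules 1–2; the "population" definition is a documented
choice), or (4) lie off the filament mask (dilated 2 px). Rules are
individually toggleable and rejection counts are reported.

Binding-class assignment, manual in the original assays, is automated: a
track is a branch-junction binder if its centroid lies within 3 px of an
annotated junction existing at track start, a nascent-branch binder if a
junction appears there during its lifetime, else a side binder. Junction
annotations are caller-supplied (ground truth for synthetic movies).

Off rates: lifetimes are binned at 5 s, the survival curve
(1 − cumulative frequency at bin upper edges) is fit with A·e^(−kt) by
unweighted least squares (weighting is not prescribed), τ = 1/k. The
estimator inherits two biases from the method itself: ~+bin/2 quantization
at coarse bins, and a boundary-censoring bias ≈ 2τ/T from discarding
tracks that touch the acquisition limits — the acquisition span must be
long relative to τ.

The census implements
sites = ⌊((pixels − 5·junctions)/3)·0.1067·370/6⌋: junction footprints
(5 px) removed, width-3 normalization to length, 106.7 nm pixels, 370
subunits/µm, one cortactin site per 6 subunits. Affinities come from the
average per-frame occupancy via K_D = c/f_bound − c, valid in the
excess-ligand regime verified by `excess_ligand_check` (≈0.0075% of
ligand surface-bound under the documented chamber geometry).

## Synthetic data

Trace ensembles add seeded i.i.d. Gaussian noise of SD = 1% of each
trace's amplitude (a realistic pyrene noise floor; not a measured value).
Fluorescence mode applies a random positive affine gain so consumers must
run the calibration. Dwell-time samples are exponential draws placed
uniformly in a movie span, frame-quantized, with boundary-censoring flags
matching filter rule 1.

The movie generator renders static filaments as random polylines of ~3 px
width (bouncing off a 12-px interior margin so PSFs stay in-frame),
junctions sampled along them at 0.08–0.1/µm, and molecules as Gaussian
PSF spots (σ 1.2 px, 1000 photons/frame — typical smTIRF signal) over
Poisson shot noise plus Gaussian read noise, stored as uint16 camera
counts. Side events arrive as a Poisson stream at k_on·c·(census sites),
placed on filament pixels outside the 5-px junction footprints (those
pixels are not side sites, by the census definition); each junction is a
single site simulated as an alternating renewal process, so events at one
junction never overlap — this matters, because merged double-occupancy
tracks would otherwise be rejected by the intensity rule in a
length-biased way. Kinetic defaults are the measured cortactin constants
(side 1.21×10⁴ M⁻¹s⁻¹ / 0.063 s⁻¹; junction 2.0×10⁶ M⁻¹s⁻¹ / 0.034 s⁻¹)
at 1.5–2 nM label.

What the generator does *not* emulate: filament growth during acquisition,
photobleaching, camera gain nonlinearity, localized background structure,
or diffusing unbound molecules. Passing recovery tests therefore
demonstrates correctness of the analysis chain under the stated noise
model, not robustness to every artifact of real acquisitions.

Study scales used by the test suite (chosen to keep statistical and
censoring errors small relative to the stated tolerances): pyrene recovery
ensembles use the full 9-concentration GST-VCA ladder and 7-concentration
cortactin ladder at 1% noise; the end-to-end movie uses a 384² px field
(~46,000 side sites, ~65 junctions — the experimental census scale), 3500
frames at 0.25 s, giving ~900 side and ~190 junction events after
filtering.

## Known limitations

- The network is well-mixed and deterministic; no spatial structure,
  filament geometry, or stochastic branching (single-branch statistics are
  outside scope).
- Printed experimental fit qualities depend on the original raw traces and
  are not reproducible; fitting machinery is validated by parameter
  recovery on synthetic ensembles instead.
- Automated binding classification is purely positional; events within the
  classification radius of a junction are indistinguishable from junction
  binders, where the original analysis used visual context.
- The survival-curve off-rate estimator is mildly biased at short
  acquisition spans (see above); the package reports, but does not
  correct, this bias.
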