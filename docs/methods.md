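# Methods

`ldhsim` models drug loading on an MgFe-carbonate layered double hydroxide
(LDH, pyroaurite structure) at two levels: an atomistic rigid-molecule
Monte Carlo description of the mineral-organic interface, and the
macroscopic sorption/kinetics/release model chain used to analyse uptake
measurements, together with the standard powder-characterization formulas.
This note records the models, their assumptions, the tunable parameters and
the design decisions taken where the problem was genuinely open.

## Structure model

The LDH is built as brucite-like M(OH)2 layers (M = Mg2+/Fe3+) stacked
along the hexagonal c axis, three metal layers per cell, with
charge-compensating carbonate and water at the gallery midplanes.

* **Cation lattice.** The in-layer metal spacing of pyroaurite is ~3.1 A;
  the builder tiles metal sites at `a / round(a/3.1)` so the printed cell
  constant (a = 12.4 A, four primitive repeats) is honoured literally.
  Hydroxyl O sits at the two triangular hollow sites above/below each metal
  plane at an M-O distance of 2.10 A; protons point along +-c with an O-H
  length of 0.96 A. Successive layers carry a rhombohedral-like lateral
  shift. Fe occupies a seeded random sublattice with no Fe-Fe nearest
  neighbours (x = 1/4 admits this exactly); the trivalent fraction must
  give integer, layer-divisible Fe counts or the builder refuses.
* **Gallery content.** One CO3(2-) per two Fe (exact charge balance) and
  `n_water` molecules per 8-metal formula unit (4.5 by default, the bulk
  composition), placed at seeded random, overlap-checked positions at the
  gallery midplanes; carbonates lie flat, as in layered carbonates.
* **Charges.** Hydroxyl O/H carry -0.95/+0.425 e (magnitudes typical of
  hydroxide force fields); Mg/Fe charges follow from exact layer charge
  balance (+1.05/+2.05 at x = 1/4). A periodic charge-equilibration
  assignment is available (`charge_method="eqeq"`) but is *not* the
  default: with the generic published electronegativity/hardness table the
  equilibration over-polarizes a dense ionic layer (it yielded Mg +5.8 /
  O -3.6 on this lattice), a known failure mode of unconstrained
  electronegativity equalization in solids. Gallery and guest molecules
  carry the packaged fixture charge sets (below).
* **Slabs.** `build_slab` keeps a/b periodicity and extends c so the gap
  between periodic images equals the requested vacuum (>= 2 x LJ cutoff,
  i.e. >= 25 A; 30 A default). The gallery cut by the cell boundary keeps
  its molecules whole; they end up lying on the exposed face, which is how
  the surface acquires its carbonate population.

## Energy model

Rigid framework, rigid guests; only framework-guest and guest-guest terms
are evaluated (the framework-framework energy is an additive constant under
rigid moves and is excluded).

* **Dispersion/repulsion:** 12-6 Lennard-Jones with the published UFF
  (x_i, D_i) parameters (element-wise; UFF LJ does not depend on
  hybridisation), Lorentz-Berthelot mixing, plain truncation at 12.5 A
  (no shift, no tail correction — the simplest faithful reading of a bare
  cutoff specification).
* **Electrostatics:** 3D Ewald summation. `EwaldParams.from_accuracy`
  chooses (alpha, kmax) with safety margins such that perturbing alpha by
  +-20% moves the energy by less than the target accuracy;
  `EwaldParams.for_simulation` drops the margins for speed (default
  accuracy 1e-4 in the Monte Carlo engine, 1e-6 in reference
  calculations). Slabs use 3D Ewald with the vacuum gap; no 2D correction
  is applied, with the error controlled by the >= 30 A gap. Non-neutral
  periodic systems are rejected (no background correction), but
  subsystem energies inside a neutral total are combined through the
  implicit-background route, which is exact for differences.
* **Units:** kcal/mol, angstrom, elementary charges;
  kB = 0.0019872041 kcal/(mol K), Coulomb constant 332.0637 kcal A/(mol e2).

### Charge equilibration

`eqeq_charges` minimises `sum chi_i q_i + 1/2 J_i q_i^2 + sum J_ij(r) q_i q_j`
under a total-charge constraint, as one linear solve with fixed per-element
(chi, J) from the published QEq set. The pair coupling is the Coulomb
integral of two Gaussian charge clouds whose widths reproduce the atomic
hardness (`J_i = k/(s_i sqrt(pi))`); this keeps the quadratic form positive
definite for any geometry, which a bare 1/r coupling does not (for CO3(2-)
the bare form is a saddle). Periodic systems evaluate the coupling by Ewald
summation with the same Gaussian short-range correction. Known limitation:
like all two-parameter equilibration schemes it over-polarizes multiply
charged molecular anions and dense ionic phases; the package therefore uses
it for what it is reliable at (neutral molecules, pairs, sanity
assignments) and ships fixed charge sets elsewhere.

### Guest molecules

Packaged fixtures (methyl orange anion, neutral tetracycline, ibuprofen,
an alginate monomer carrying 2-, carbonate, water, Na+, and a
non-interacting ghost probe) hold ETKDG-embedded, MMFF94-relaxed
geometries with PEOE (Gasteiger) partial charges symmetrised over
topologically equivalent atoms and normalised to the exact formal charge.
These charge sets are substitutes for the study-specific DFT charges,
which are not published; they reproduce sign patterns and net charges, not
any particular ab initio magnitudes. Users can supply their own per-atom
charges through `GuestMolecule`.

## Monte Carlo

Canonical Metropolis sampling of rigid guests: a uniformly random guest, a
translation or rotation (50/50), acceptance `min(1, exp(-dE/kT))`.
Rotations perturb the orientation quaternion about a uniform random axis.
Energies are cached per guest pair and updated incrementally (structure
factors included); a full recomputation is available and the incremental
path is required to agree to 1e-6 after 1e5 steps.

* **Step counts.** Defaults are the production protocol (2e7 equilibration
  + 1e7 production at 300 K). The `scaled_down` preset (1e5 + 1e5,
  sampling every 1e3) is the desk-scale profile used by the test-suite and
  the reproduction script; it relaxes a pre-built surface configuration
  but cannot fold a system from scratch.
* **Move amplitudes.** 0.2 A / 0.2 rad, fixed (no auto-tuning). The
  translation amplitude was set by the conventional acceptance-rate
  criterion: on the carbonate-covered slab it gives ~33% translation
  acceptance, where 0.5 A gave ~5-7%.
* **Surface systems.** `slab_adsorption_system` makes the face carbonates
  mobile and strips the face water (a surface in contact with solution
  exchanges water with the bulk; a frozen interfacial water monolayer
  blocks the hydroxyl surface entirely). Gallery water and interior
  carbonates stay rigid with the framework. Adsorbates are initialised by
  a seeded rigid docking pass: random orientations and in-plane positions
  are lowered to van der Waals contact and the lowest-energy candidate
  pose becomes the starting configuration, which the Monte Carlo run then
  relaxes (or rejects). At the desk-scale step budget a diffusive
  approach from the vacuum does not reliably reach the bound state, so
  the runs are relaxations of a constructed adsorbed state.
* **Saturation loading** inserts guests at random poses (overlap criterion:
  heavy-atom pair distance >= 0.7 x mixed LJ sigma), relaxing between
  insertions with short hard-sphere Monte Carlo shuffles, and stops after
  50 consecutive failed rounds. This is a documented operational
  definition of "gallery saturation", not a thermodynamic solubility.
* **Insertion scans** place a rigid guest on an in-plane grid at the
  gallery midplanes in several seeded orientations and evaluate the
  LJ + screened-Coulomb insertion energy; feasibility means the scan
  minimum is below a threshold (10 kcal/mol by default — comfortably above
  thermal energies, far below steric-overlap energies, so the verdict is
  insensitive to its exact value over orders of magnitude).

## Geometric analysis

Hydrogen bonds use a pure geometric criterion: H...acceptor <= 3.0 A and
donor-H...acceptor angle >= 120 deg; the reported distance is H...A, the
scale of the printed 2.1-2.8 A interaction distances. Nearest-contact
summaries record, per frame and per molecule, the closest approach between
two selections. Orientation statistics report the angle between a guest
principal inertia axis and the layer normal, folded to [0, 90]; the default
axis is the plane normal (largest moment; a flat-lying planar guest scores
0), `axis="long"` selects the long axis of an elongated guest.

The surface-protocol summary statistics are: the tetracycline-surface
hydrogen-bond distances of the converged snapshot — the sampled frame that
minimises the adsorbate's own interaction energy, the desk-scale analogue
of the "typical configuration" such studies depict with annotated bond
lengths — and the minimum over frames and carbonates of the nearest
carbonate-to-surface-hydroxyl contact. With the substitute PEOE guest
charges the tetracycline hydrogen bonds come out ~0.1 A longer
(snapshot bonds ~2.7 A, per-frame strongest bonds spanning ~2.4-3.0 A)
than would be expected from more polarized ab initio charge sets; the
carbonate-surface contact range (~2.09-2.52 A) is insensitive to this
because the carbonate charge is fixed by its formal value.

## Sorption model chain

Kinetics (pseudo-first-order, pseudo-second-order, Elovich), isotherms
(Freundlich `Q = k C^(1/n)`; Sips `Q = Qm Ks C^m/(1+Ks C^m)`, with m > 1
flagged as positive adsorbate-adsorbate cooperativity) and release laws
(zero/first order, Higuchi, Hixson-Crowell, Korsmeyer-Peppas `F = k t^n`,
fitted only below 60% release; n < 0.5 labelled Fickian diffusion).

* **Fitting.** Multi-start nonlinear least squares (log-spaced starts; the
  log-log or linearised solution seeds the power-law models). The loss is
  on *relative* residuals (weights proportional to the signal with a 5%
  floor), matching the relative-error character of UV-vis-derived
  concentrations; with unweighted residuals the Gauss-Newton standard
  errors of the 8-point Sips refit under-covered by a factor ~3.
  Standard errors come from the weighted Gauss-Newton covariance.
* **R^2** is always `1 - SS_res/SS_tot` on the untransformed response, so
  that models of different functional form (and the single-R^2 reporting
  convention of sorption studies) remain comparable. Model comparison
  ranks by R^2, ties broken toward fewer parameters.
* **Identifiability.** Without a plateau the Sips (Qm, Ks) pair is weakly
  identified; the fit is returned anyway with a `plateau=False` flag and
  correspondingly wide uncertainties — the exponent m is the robust
  quantity, mirroring how such isotherms are interpreted.
* Loading arithmetic `Q = (C0 - C_eq) V/m` and the UV-vis calibration-line
  conversion (with dilution factors, e.g. 10 for tetracycline and 100 for
  ibuprofen) complete the chain; ppm means mg/L throughout.

## Characterization formulas

Scherrer size `D = K lambda/(beta cos theta)` with K = 0.9 and beta the
FWHM in radians, no instrumental-broadening correction (none is specified
for the reference diffractometer); basal spacings `d(00l) = c/l` and Bragg
angles at Cu K-alpha (1.5406 A). BET analysis regresses the linear
transform on p/p0 in [0.05, 0.30] and converts the monolayer capacity with
the 0.162 nm2 N2 cross-section; total pore volume follows the Gurvich rule
at p/p0 = 0.99 with the 34.67 cm3/mol liquid N2 molar volume. Theoretical
density `rho = Z M/(N_A V)` takes Z explicitly (never inferred: the
tabulated 2.276 g/cm3 for this composition is not reproducible from
standard Z and water-content choices, which give ~2.1 g/cm3, so the
discrepancy is exposed rather than hidden). Densification is
`100 d_app/d_th`; mercury porosity `P_tot = d_app x V_Hg x 100`.

## Synthetic data

Generators reproduce the study's sampling designs: kinetics on 5-1440 min
grids, isotherms on 30 log-spaced points over 120-3500 ppm (dye) or
caller-supplied g/L windows (drugs), release on 5-180 min horizons capped
below the 60% validity limit, closed-form BET N2 isotherms, and
Gaussian/Lorentzian diffraction peaks on the 5-70 deg, 0.02 deg-step scan
grid. The default noise model is 2% multiplicative Gaussian — consistent
with the reported fit uncertainties (for example +-0.01 on a Freundlich
exponent near 2.35 at ~30 points) — and generation is byte-reproducible
from the seed. `STUDY` records the generating parameters: the fitted
Freundlich pairs (powder k = 0.455, n = 2.35; monolith k = 0.035,
n = 1.04), the tetracycline Sips exponent m = 2.7 (Qm, Ks set to plausible
magnitudes consistent with the ~0.2-0.3 g/g loading at 20 g/L, since the
study's own fit leaves them undetermined), the release exponent n = 0.23
with k = 0.15 min^-0.23 (keeping the 3 h maximum below 60%), and
pseudo-second-order pairs matching the reported uptake plateaus (~90 mg/g
monolith, 5.4x higher for powder) and ~13 h stabilisation.

What the generators do *not* emulate: instrument drift and baselines,
UV-vis spectral overlap (the ethanol-dissolution artefact seen with
ibuprofen is documented, not simulated), desorption hysteresis shapes, or
correlated errors between time points. Passing recovery tests therefore
demonstrates that the estimators are unbiased and well-calibrated under
the stated error model, not that they are robust to every instrumental
pathology of real assays.

## Desk-scale limits

The scaled-down surface simulation (1e5 + 1e5 steps, ~19 mobile species)
relaxes the interfacial carbonates and one adsorbed tetracycline from a
contact starting configuration; it does not diffuse molecules across the
cell or exchange carbonates between face and gallery, and single-run
extreme statistics (a minimum contact over 1800 samples) retain
run-to-run scatter of a few hundredths of an angstrom. The full-length
protocol remains available through the default `MCParams`.
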