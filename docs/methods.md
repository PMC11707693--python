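# Methods

## Model overview

The package studies stockholder partitioning of a molecular electron
density and its consequences for crystallographic refinement. The chain is:

1. **Densities** (`atomic_densities`). Isolated-atom densities are
   single-zeta Slater 1s profiles `rho°(r) = N (ζ³/π) exp(−2ζr)` (bohr
   units), one per element, with packaged defaults (`data/slater_zeta.txt`:
   H ζ=1.0; He 1.6875; pseudo-heavy X ζ=1.8 with 6 electrons; Y ζ=2.4 with
   8). Any object with the `RadialDensity` protocol can replace them — the
   partition algebra is density-source-agnostic, and the Slater family is
   only the shipped default at desk scale. A one-electron two-centre
   density `|N(φ_A + φ_B)|²` with `N² = 1/[2(1+S)]`,
   `S = e^{−ζR}(1 + ζR + (ζR)²/3)`, models a covalently bonded pair.

2. **Partition** (`partition`). `w_A(r) = rho°_A(r)^n / Σ_B rho°_B(r)^n`,
   `n ≥ 1`. The exponent applies to the isolated-atom densities only, never
   to the total density, so `Σ_A w_A ρ = ρ` pointwise for every `n` and
   `n = 1` is the classic Hirshfeld partition through the same code path.

3. **Form factors** (`form_factors`). `f_A(h) = ∫ w_A ρ e^{2πi h·(r−x_A)}`
   by atom-centred numerical integration, atom-local phase convention (the
   lattice phase is applied in the structure-factor engine). Tables are
   serialized in a minimal `.tsc` dialect: `TITLE:`, `SYMM: expanded`,
   `SCATTERERS:`, `DATA:` followed by `h k l re,im ...` rows; the reader
   accepts extra header keys.

4. **Refinement** (`refinement`). Gauss–Newton least squares on F² with
   SHELX-type weights `w = 1/(σ² + (aP)² + bP)`; the model is
   `F(h) = k Σ_A occ_A f_A(h) exp(−2π² sᵀU_A s) e^{2πi h·x_A}` with
   analytic derivatives for the overall scale, fractional coordinates and
   the six Cartesian U components per selected atom. An outer macro-cycle
   regenerates the form-factor table from the current geometry, mimicking
   the HAR outer loop, until max |shift|/su < 0.1.

5. **ADP statistics** (`adp_metrics`) and the **synthetic laboratory**
   (`synthetic_crystal`), described below.

## Quadrature

Angular integration uses product grids with the algebraic exactness of the
classic Lebedev–Laikov grids: `sphere_grid(nominal)` accepts the standard
Lebedev point counts and returns a Gauss–Legendre(cos θ) × uniform(φ) grid
exact for spherical harmonics up to the order tied to that count (590 → 41,
5810 → 131). Generating the grid keeps the package free of large embedded
node tables; the cost is a somewhat larger point count than the genuine
Lebedev grid of the same order (degree 41: 882 vs 590 points), which for
these smooth integrands is a constant-factor overhead only. Radial
integration is the Mura–Knowles Log3 map `r_i = −α ln(1 − (i/(N+1))³)` with
chain-rule weights, default `N = 75`, `α = 5` bohr for every element (the
α and pruning scheme are free choices here; both are exposed).

Atom-local quantities (form factors, populations, overlaps) use a single
atom-centred grid; no Becke fuzzy-cell multi-centre scheme is implemented
because every integrand here is dominated by one centre. **Caveat:** for
diffuse two-centre products the cusp at the far nucleus limits single-grid
accuracy to ~1e−4 (590×75) … ~1e−5 (2354×300); the 1s–1s overlap integral
itself is instead computed in prolate spheroidal coordinates
(`slater_overlap_1s_quadrature`), where the product is smooth and a
Gauss–Laguerre rule is exact to machine precision.

Stockholder weights are evaluated in log space (a softmax over
`n·log rho°_A`), exact arbitrarily far from the molecule for densities that
provide `log_density`. Only when every density truly underflows (e.g. a
truncated numerical density) does the far-field convention assign the point
to the geometrically nearest site (`zero_threshold` default 1e−30) — the
affected region carries negligible integral weight.

## ADP similarity statistics

* `MSD_corr` correlates `MSD_n = nᵀUn` over uniformly distributed
  directions. With the isotropic fourth-moment identity
  `<n_i n_j n_k n_l> = (δδ+δδ+δδ)/15`, the covariance reduces to
  `cov = (2/45)[3 tr(U₁U₂) − tr U₁ tr U₂]`, giving the analytic path; a
  5810-class quadrature path is retained as an independent route and the
  two agree to better than 1e−6. Isotropy (relative eigenvalue spread
  < 1e−9) raises a dedicated error — the index is undefined there, and mean
  reports skip such atoms with a count.
* The overlapping coefficient is computed in the frame whitening U₁: p₁
  becomes standard normal and p₂ becomes N(0, Λ) with Λ the eigenvalues of
  `U₁^{−1/2} U₂ U₁^{−1/2}`. Along each direction of a Lebedev-class grid
  the two radial Gaussians cross at most once; both branch integrals are
  expressed through erf, so only the angular factor is quadratured.
  The construction is exactly invariant under common invertible transforms
  of both covariances. `η_r` is implemented as `100·η` (percent probability
  mass by which the PDFs differ); the factor lives in one function
  (`eta_r_from_eta`) so an alternative rescaling can be swapped in without
  touching callers.
* `CC` uses the Gaussian closed form `√8 (det U₁ det U₂)^¼/det(U₁+U₂)^½`,
  `S₁₂ = 100(1 − CC)` exactly.
* `fit_isotropic_scale` defaults to the full-tensor Frobenius estimator
  `q = Σ tr(U_ref U_tgt)/Σ tr(U_tgt²)`; a `U_eq`-ratio estimator is
  available as an alternative.
* ADPs are compared in the Cartesian convention; CIF-style reciprocal-basis
  `U` values are converted on input via `U_cart = A N U_cif Nᵀ Aᵀ`,
  `N = diag(a*, b*, c*)`.

## Refinement numerics

* Weights use the literal printed form `P = 2F_c² + max(F_o², 0)` by
  default; the conventional `P/3` is available via `p_convention="shelx"`
  (the /3 is probably intended in most software, but the literal form is
  the default for fidelity, and with `a = b = 0` — the package default —
  the choice is moot).
* Reported standard uncertainties come from the goof-scaled inverse normal
  matrix. The shift/su **convergence ratio**, however, uses the unscaled
  (σ-based) uncertainties: on noise-free data the goof tracks the residual,
  which contracts at the same geometric rate as the macro-cycle shifts, so
  a goof-scaled ratio would stall at a constant value and never satisfy any
  threshold. With real noise the two are equivalent up to the ~constant
  goof.
* Step control: plain Gauss–Newton with halving on χ² increase; the normal
  matrix is eigen-checked and a singular system raises an error naming the
  null-space parameters (e.g. the global translation when all positions
  plus the scale are freed in P1).
* The resolution cutoff keeps exactly the reflections with `d ≥ d_min`.

## Synthetic crystals and the neighbour-bias experiment

`make_structure` builds a P1 cell (6.0 × 5.4 × 5.8 Å) with a compact heavy
pseudo-atom X bonded to H at 1.00 Å in a seeded random orientation. ADPs:
X has principal values (0.012, 0.015, 0.018) Å² in a random frame; H has
MSD ≈ 0.018 Å² along the bond and ≈ 0.027–0.032 Å² transverse (the
riding-motion shape, with 5 % seeded jitter). These magnitudes are typical
of ~100 K organic structures; they are a modelling choice, not a fit to any
particular compound. Intensities are `|F|²` with optional multiplicative
Gaussian noise; when the data are exact the σ column mimics 1 % counting
statistics so that weights and uncertainty estimates remain meaningful.

The neighbour-bias experiment fixes the heavy-atom U at `q_fix` times its
true value and refines the hydrogen (position + U + scale) with the
exponent-`n` partition regenerated every macro-cycle. **Design choice:**
each condition simulates its data with the *same* exponent `n` used in the
refinement, so the refinement model can represent the truth exactly and the
`q_fix = 1` condition is a rigorous unbiased control; the bias recorded at
`q_fix < 1` then isolates the neighbour-compensation mechanism at that
overlap level, uncontaminated by density-model mismatch. Trends across `n`
(bond-direction MSD excess, `U_eq` ratio) are evaluated across the
`q_fix = 0.9` records, whose truth tensors are identical for all `n`. A
`model-mismatch` style study (one fixed truth density for all exponents) can
be assembled from the same building blocks by passing a prebuilt
`fftable` / total density into `simulate_intensities`, but is not part of
the default experiment because it entangles the two effects.

Default experiment grid: `q_fix ∈ {1.0, 0.9}`, `n ∈ {1, 1.25, 1.5, 2, 3,
4}`, `d_min ∈ {0.8, 1.0} Å`, noise-free; the full grid runs in ~1.5 min on
one CPU at the default grid sizes (590-class angular × 75 radial).

## What the synthetic tests do and do not show

The generator reproduces the *structure* of the problem — overlapping
atom-centred densities, Debye–Waller smearing, least-squares coupling
between neighbouring atoms' parameters — but not real electron densities
(no bonding deformation unless the two-centre density is used, no core/
valence structure), no experimental noise model beyond multiplicative
Gaussian, no symmetry, absorption, extinction or disorder. Passing tests
therefore demonstrate the partition algebra, the statistics and the bias
mechanism; they do not certify accuracy for any real compound, and
published per-compound statistics (which require quantum-chemical
wavefunctions and the original data) are deliberately out of scope.

## Known limitations

* Single-centre quadrature accuracy for strongly overlapping two-centre
  products (~1e−4 relative at default grids; see caveat above).
* The overlap-coefficient definition is pluggable ("min" default,
  "product") — both satisfy symmetry, decay and exponent-monotonicity, but
  no numerical equivalence to any published per-compound overlap table is
  claimed.
* No automatic (a, b) weighting optimization; parameters are user-fixed
  per run.
* P1 only; occupancies fixed; no F-based (HKLF-3) mode.
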