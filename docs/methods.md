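# Methods

This note records the models, conventions and defaults behind each
analysis stage, the design choices made where more than one convention is
defensible, and what the synthetic ground-truth systems do and do not
establish about real trajectories.

## Units and data model

All internal quantities use Å, ps, elementary charge e, amu and
kcal·mol⁻¹; conversions (mV for potentials, m²·s⁻¹ for diffusion,
chains·nm⁻² for grafting density) happen only at reporting boundaries.
The Coulomb constant e²/(4πε₀) = 332.0637 kcal·mol⁻¹·Å·e⁻² and the
field-conversion constant e/(4πε₀·Å) = 14.3996 V are evaluated from CODATA
constants at import time, never hard-coded.

Atoms are 0-based internally; GRO/PDB writers emit native 1-based serials.
Only orthorhombic boxes are supported — the study systems are cubic — and
triclinic input raises an explicit unsupported-format error.  Coordinate
files carry no chemistry, so a JSON/YAML topology sidecar supplies per-atom
element, partial charge, mass, LJ parameters, heavy-atom and H-bond-role
flags, bonds, group labels (NP_CORE, PEG, WATER, ION_NA, ION_CL,
extensible) and per-chain ordered heavy-atom lists from the grafting
anchor to the solution-side terminus.

## Radial profiles

Profiles are spherical-shell averages about the nanoparticle center with a
0.1 Å bin width (configurable).  Two center conventions exist because
different analyses traditionally reference different origins: the core's
geometric center (default, used for volume fractions) and a fixed central
atom or the core's center of mass (RDF convention).  Positions are
minimum-image wrapped about the center before binning; the default radial
range stops at half the shortest box edge, beyond which shells sample the
periodic cell incompletely.  Water is located at its oxygen.

Number density is mean shell count over frames divided by the exact shell
volume 4π/3·(r₂³ − r₁³).  The RDF divides by the selection's mean density
over the box, so it tends to 1 in a homogeneous bulk.  The cumulative
fraction weights each bin by its shell volume and normalizes by the total,
giving the probability of finding the species within r.

**Bulk onset.**  The radius where the bulk water phase begins is the first
*sustained* crossing of RDF = 1: linearly interpolated between bin
centers, and required to stay above 1 − 0.05 for the following 2 Å.  A
first-touch rule would fire on the solvation-shell peaks that decorate the
polymer region; the sustain window suppresses them.

## Chain metrics and brush scaling

Chains are unwrapped from their anchor atom by sequential minimum-image
restitching before any metric; a chain whose bonded step still exceeds
half the box (possible only for corrupt input) raises an error demanding
an unwrap.  The radius of gyration defaults to the *unweighted* sum over
heavy atoms about their centroid, for which the pairwise identity
R_g² = (1/2N²)ΣᵢΣⱼ|rᵢ − rⱼ|² holds exactly and anchors the test oracle; a
mass-weighted variant is provided since the two conventions coexist in the
literature.  End-to-end distance is first-to-last heavy atom of the
ordered chain; the PEG–NP distance is terminus to core center.

The polymer layer thickness takes the 5% and 95% crossings of the
cumulative radial distribution by linear interpolation between bin edges —
the shell holding 90% of the polymer.  It is invariant to uniform
amplitude rescaling of the profile.

Volume fractions assign 20 Å³ to every PEG heavy atom and 30 Å³ to each
water molecule.  Assigning 20 Å³ to *all* PEG heavy atoms (including
terminal and anchor groups, not only −CH₂ and ether O) is a deliberate
simplification: the synthetic chains are bead-like monomers, and the
distinction would require atomistic PEG chemistry that is out of scope.

The Daoud–Cotton fit regresses log φ on log r over a user window measured
from the particle *surface* (the brush-scaling variable), dropping
nonpositive bins with a warning and requiring ≥ 5 bins.  The semidilute
brush regime of a densely grafted star polymer predicts the exponent
−4/3; the fit recovers planted exponents in {−2, −4/3, −1, 0} to better
than 0.02 under 1% multiplicative noise on a 100-bin window.

## Hydrogen bonds and nonbonded energies

A hydrogen bond requires donor-heavy/acceptor-heavy minimum-image distance
< 3.0 Å and an angular deviation < 20°.  The phrase "angle between the
H-donor–acceptor" is ambiguous about the vertex, so both conventions are
implemented: the default measures ∠(donor→H, donor→acceptor) at the donor;
the alternative measures the deviation from linearity of donor–H···acceptor
at the hydrogen.  A donor carrying two polar hydrogens can contribute two
bonds; a donor with no bonded polar hydrogen is a topology error.

Pair energies sum Coulomb q_iq_j·k_C/r (truncated at the cutoff) and
Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶] over unique minimum-image pairs,
with arithmetic-σ/geometric-ε combining rules, 1–2 and 1–3 bonded pairs
excluded and 1–4 included unscaled.  An optional CHARMM energy-switching
function extinguishes the LJ term between r_on and r_off = cutoff.
Electrostatics use a **direct truncated sum** (12 Å default) rather than a
reciprocal-space method: the group-pair decompositions this package
reports are short-range-dominated comparisons, and a no-cutoff direct-sum
mode exists for point-charge reference systems where exactness matters.
Absolute Coulomb energies of periodic charged systems are therefore not a
supported use.

## Electrokinetics

The chain is σ(r) → E(r) → φ(r) → ζ.  The charge density multiplies each
atom type's number density by its partial charge and sums — equivalently a
charge-weighted radial histogram.  The field follows the spherically
symmetric Gauss law with vacuum permittivity (explicit solvent carries its
own polarization):

    E(r) = [Q_core + 4π ∫_{r₀}^{r} σ(r′) r′² dr′] / (4π ε₀ r²),

integrated by the trapezoid rule on the 0.1 Å grid from the particle
surface r₀.  The potential φ(r) = ∫_r^{r_bulk} E dr′ fixes its zero at a
bulk reference radius (default: the outermost grid point), so the zeta
potential ζ = φ(r_shear) is bulk-referenced.  The shear plane defaults to
the water RDF's bulk onset.  For planted charged shells the whole chain
reproduces the Coulomb superposition to ≲ 0.5% (quadrature error at 0.1 Å
bins), and a net-negative mobile layer inside the shear plane yields
ζ < 0, fixing the sign convention.

## Diffusion and aggregation

The MSD averages over all time origins via an FFT autocorrelation
(O(T log T)); coordinate series are mean-centered first, which the MSD
permits and which avoids catastrophic cancellation for trajectories far
from the origin.  Two tracking modes exist: center-of-mass of the
selection (the nanoconjugate convention — core plus grafted chains move as
one object) and per-atom averaging (for ensembles of independent walkers).
Frames must be uniformly spaced and unwrapped; a per-step displacement
beyond half the box aborts with an unwrap error.  The diffusion
coefficient is the least-squares MSD slope over a lag window divided by
2n (n = 3), converted via 1 Ų·ps⁻¹ = 10⁻⁸ m²·s⁻¹; a fit R² below 0.9 is
flagged as non-diffusive.  The analysis window convention for production
data is the trailing 10% of the trajectory (`Trajectory.last_fraction`).

Two-particle aggregation uses the per-frame minimum-image minimum
atom-atom separation between the two core selections.  The verdict is
explicit configuration, not inference: *non-aggregated* if the gap exceeds
the contact threshold (default 10 Å) in more than 90% of frames,
*aggregated* if it stays at or below it in more than 90%, otherwise
*transient-contact*.  The mean intersystem nonbonded energy between the
full coated systems is reported alongside when requested.

## Synthetic ground truth

The generators are seeded (`numpy.random.default_rng`) and byte-
deterministic; their metadata carries the planted truth and is consumed
only by tests, never by the analyses.

* **Grafted particle** — freely-jointed chains (default) on a Fibonacci-
  sphere anchor lattice, first bond radial, conformations resampled per
  frame.  Ideal chains have exact statistics (⟨h²⟩ = N·b²,
  ⟨h²⟩/⟨R_g²⟩ → 6(N+1)/(N+2)), which is why they, and not self-avoiding
  chains, back the quantitative tests.  A straight-chain mode pins every
  terminus at exactly R + N·b.
* **Water bath** — `floor(density·V)` three-site molecules (TIP3P-like
  geometry and charges, default 0.0334 Å⁻³) at uniform random
  non-overlapping positions, optional excluded cavity, ion pairs from
  molarity (rounded, exactly neutral).  This is a random packing, not an
  equilibrated liquid: it validates density/RDF/charge-profile estimators
  and bulk-onset detection, but supports no claims about hydrogen-bond
  networks or water structure.
* **Charged shells** — uniform point charges on randomly oriented spheres;
  the Coulomb superposition gives E and φ in closed form.
* **Brownian walkers** — Gaussian steps of per-dimension variance 2·D·dt;
  the Einstein relation closes the loop on the MSD/diffusion estimators.
* **Power-law profiles** — φ(r) = A·rᵅ with optional lognormal noise for
  the brush-fit regression properties.

Passing these tests establishes estimator correctness — binning,
normalization, bookkeeping, quadrature, fitting — under known ground
truth.  It does not reproduce any production-simulation observable:
absolute structural or energetic values of real PEGylated nanoparticles
depend on force fields and sampling outside this package's scope.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for interactive runs: chain
ensembles of 50 chains × 100–200 bonds × 30–40 frames (≥ 1500 samples),
100 Brownian walkers × 10⁴ steps with lags to 10³, 400-point charged
shells, and 50-atom brute-force energy oracles.  Tolerances follow the
estimator class: exact identities at 10⁻¹⁰–10⁻⁸, quadrature-limited
closed forms at 0.5–2%, stochastic recoveries at 3 standard errors or 10%.
Ties and degenerate inputs are defined errors, not silent results: empty
selections where a mean is required, all-zero profiles under cumulative
normalization, non-monotone cumulative distributions, RDFs that never
reach 1, zero reference values in percent changes, and overlapping core
selections all raise with actionable messages.

## Known limitations

* No reciprocal-space electrostatics; absolute Coulomb sums of periodic
  charged systems are cutoff-dependent.
* Orthorhombic boxes only; no binary trajectory formats (XTC/DCD) or
  velocities.
* The vacuum permittivity enters the Gauss-law chain; no dielectric
  continuum or electrophoresis model (Poisson–Boltzmann, Smoluchowski) is
  layered on top.
* Diffusion coefficients carry no finite-size periodic-boundary
  correction.
* Published per-system standard deviations mix over-chain and over-frame
  variance; summaries here pool chains × frames and expose the full
  matrices so either decomposition can be formed.
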