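# Methods

`femtoplasma` is a zero-dimensional, non-thermal collisional-radiative
solver for the electronic damage suffered by biomolecular targets under
femtosecond X-ray pulses.  It evolves, per element, the population
vector P_xi(t) of ionic electron configurations xi, coupled to a single
shared free-electron energy distribution f(eps, t):

    dP_xi/dt = sum_eta Gamma_{xi,eta}(f, t) P_eta
    df/dt    = Q_photo + Q_auger + Q_eii + Q_tbr + Q_ee

The modeled processes are photoionization, Auger decay and fluorescence
(bound-bound with photon emission), electron-impact ionization (EII),
three-body recombination (TBR), and elastic electron-electron (EE)
Coulomb collisions.  Nuclear motion, ionization-potential depression,
resonant bound-bound excitation, spatial transport and beam-profile
inhomogeneity are outside the model's scope.

## Atomic data

**Configurations.** For each element all occupancy vectors with each
(sub)shell between 0 and its ground-state occupancy are enumerated
lazily through a mixed-radix index (the ionization-reachable set; the
rate model never over-fills a shell past its initial occupancy).  For
Z >= 30 the n >= 2 subshells are merged per principal quantum number
into single collapsed levels, otherwise the configuration count grows
factorially (Gd still has 400,140 collapsed configurations).

**Mean field.** Orbitals come from a configuration-average
Hartree-Fock-Slater solve: radial Schroedinger equation on a
logarithmic grid (480 points for Z < 30, 440 above), Xalpha exchange
with alpha = 0.7, Latter tail correction, Numerov integration with
node-count bisection for the eigenvalues.  Collapsed shells distribute
their electrons over the merged (n, l) subshells proportionally to the
ground occupancies; shell-level binding B and mean kinetic energy U are
occupancy-weighted means.  Process thresholds are total-energy
differences between configurations (Delta-SCF), which makes the energy
ledger exactly consistent.  One-electron ions are treated analytically
(exact hydrogenic); the bare nucleus is a valid zero-orbital state.

**Occupation-energy surface.** Elements whose configuration set exceeds
200 members (S, Cl, and all collapsed heavy elements) are served from a
piecewise-quadratic expansion of the total energy in the shell
occupation numbers, anchored on direct SCF solutions (reference
configurations along the proportional-stripping path, plus all single-
and pair-removal samples at each anchor; anchor spacing ~Z/7 charge
units).  Shell B and U are interpolated linearly from the same samples.
Against direct Delta-SCF thresholds the surface is accurate to a few
percent up to charge ~+35 for Gd, at the cost of a few hundred SCF
solutions per element instead of one per visited configuration (tens of
thousands in a heavy-atom run).

**Photoionization.** Scaled-hydrogenic subshell cross-sections: the
exact nonrelativistic dipole (Stobbe) form for n = 1 (6.30e-18 cm^2 at
threshold for hydrogen) and the Kramers form (Gaunt factor 1) for
n >= 2.  The hydrogenic energy scale of the formula is set by the
orbital mean kinetic energy U — for hydrogenic orbitals <T> equals the
binding exactly, and U carries the inner-screened effective charge that
governs the high-energy magnitude.  A threshold-derived effective
charge instead underestimates light-element K-shell cross-sections by
~2.5x at hard-X-ray energies.  The cross-section is gated at the
Delta-SCF threshold.  With this choice the model reproduces reference
photoelectric magnitudes for C/N/O/S at 7–9 keV to ~10%, and the Gd
total (2.5e-20 cm^2 at 7.112 keV, below the L edges) to ~10%.

**Impact ionization.** The binary-encounter-Bethe (BEB) member of the
Kim & Rudd (1994) binary-encounter-dipole family,
sigma = S/(t+u+1) [ln t/2 (1-1/t^2) + 1 - 1/t - ln t/(t+1)], with
S = 4 pi a0^2 N (Ry/B)^2, t = T/B, u = U/B.  The singly-differential
spectrum is the matching symmetric form whose half-range integral
equals the total exactly.  Full BED would need differential oscillator
strengths that the mean field does not provide; BEB is the standard
fallback.

**Recombination.** The TBR kernel is constructed from the BEB
differential cross-section by microreversibility, normalized as an
ordered-pair kernel so that with a Maxwellian plasma and Saha-balanced
populations the net EII-TBR flux vanishes (verified to ~0.1% at the
operator level).  Statistical weights are configuration-average
binomial counts over full quantum capacities.  Recombination into
holes deeper than 500 eV is neglected (Auger refills such holes orders
of magnitude faster).

**Inner-hole decay.** Total level widths and fluorescence yields per
(Z, shell) follow Krause-style compilations, log-interpolated in Z,
scaled by the electron pairs actually available above the hole;
final-state branching is proportional to pair counts; energetically
closed channels are suppressed.  Lifetimes (carbon K: 6.6 fs; sulfur
K: 1.1 fs; Gd M: ~0.2 fs) drive the dynamics; line structure is not
modeled.

## Free-electron representation

f(eps) = sqrt(eps) * phi(eps), with phi expanded in clamped cubic
B-splines over [0, emax].  Pulling out the phase-space sqrt makes
Maxwellians smooth at the origin; without it the EE operator cannot
keep a discrete Maxwellian stationary (the cubic spline cannot
represent sqrt(eps)).  All weak forms use one fixed 4-point
Gauss-Legendre rule per knot interval under the sqrt(eps)-weighted
inner product; because the same rule builds the mass matrix, the
moments and every operator, the discrete bookkeeping identities hold
exactly: each EII event adds net +1 electron and -B kinetic energy,
each TBR event the reverse, sources carry exact (rate, rate*eps0)
moments.

Moment exactness is enforced *locally*: every repaired shape (an EII
secondary-spectrum column, a projected point source, a TBR update) is
multiplied by a linear tilt a + b*eps solved for the two exact moments,
so the correction lives on the support of the shape being corrected.
This locality matters more than it may appear.  A minimal-norm
correction in the mass metric — the obvious alternative — places its
density wherever the metric is cheap, which on these grids is the
sparse multi-keV region; with valence EII columns needing O(10%)
quadrature repairs, that variant effectively converted part of every
soft ionization event into spurious fast electrons and made the charge
observables swing by tens of percent between grids.  With the local
tilt the same observables vary by only a few percent across grid and
step-tolerance refinement.

The knot layout is adapted to the run before it starts: a log-dense
backbone through the thermal region (0.15–400 eV), sparser log spacing
up to emax = omega + 1.4 keV, plus 5-knot clusters around every primary
photoelectron peak (omega - B per ionizable subshell of every element's
initial configuration) and the dominant first Auger lines.  Typical
basis sizes are K ~ 60–120.  A moment-preserving regrid operation is
available; under the studied pulse conditions the precomputed layout
already covers the thermal bulk and all primary peaks, so no mid-run
re-adaptation is triggered.

**EE collisions.** Isotropic energy-space Fokker-Planck operator for
like particles in cumulative-integral form,

    df/dt = d/de { a [3 A1 F0 + 2 (A2 + e^{3/2} A3) F0'] },
    A1 = int_0^e f,  A2 = int_0^e e' f,  A3 = int_e^inf f/sqrt(e'),

with F0 = phi.  Maxwellians are exact stationary points (the identity
A2 + e^{3/2} A3 = (3T/2) A1 holds), and the magnitude a = (4 pi/3) e^4
lnLambda / sqrt(2 m) is fixed by the Landau high-velocity drag limit
de/dt = -4 pi n e^4 lnLambda/(m v).  The Coulomb logarithm uses the
instantaneous density and effective temperature (2/3 of the mean
energy), floored at 2.  The A-integrals are evaluated through
precomputed cumulative matrices (interval totals by the main rule,
partial intervals by a 3-point sub-rule), so stationarity survives
discretization to ~1e-3.

## Time integration

Embedded Bogacki-Shampine RK2(3) with adaptive step for every coupling
except EE, which is advanced by linearly implicit Crank-Nicolson
half-steps on either side of the RK step (Strang splitting; the
thermal bulk makes EE stiff, nu_ee ~ 10/fs at 1e23 cm^-3 and 10 eV).
Because each right-hand-side evaluation is exactly balanced, any
Runge-Kutta combination conserves the linear invariants to round-off:
full runs show electron-number drift ~1e-8 and energy-ledger residuals
~1e-6 relative (criteria: 1e-6 / 1e-3).  The error norm tracks the
configuration populations (atol 1e-9) and the density/energy moments of
f (rtol 3e-4 by default).  Square-pulse edges and tracer-injection
times are integration breakpoints; the flux argument is clamped to the
current smooth branch so no Runge-Kutta stage straddles a
discontinuity.

Configurations are activated lazily: transition tables once the
population exceeds 1e-10, spline-space EII/TBR operators at 1e-5
(light) / 1e-4 (heavy) population, TBR at 1e-4.  Populations below
these thresholds are invisible in the reported observables at the 1e-3
level.

## Cascade partition

Auxiliary distributions g_n(eps, t) partition f by seeding process
(element x {photo, auger}, plus artificial tracers).  Photo/Auger
sources feed their own channel; EII applies the same linear gain/loss
operators to each g_n, which credits secondaries to the impactor in
proportion to its share g_n/f of the impacting density; TBR removes by
each node's own channel share and splits the merged electron 50/50
between the two channels involved; EE propagates each channel with the
test-particle linearization against the full f, whose channel sum is
exactly the nonlinear operator.  The sum rule sum_n g_n = f holds to
round-off through full runs.  Tracers are injected either as an
impulse of 1e-8 of the instantaneous density (linear-response regime)
or continuously at a multiple of the undamaged target's photoionization
rate.

## Targets and pulses

Targets are element counts per unit cell plus exactly one of unit-cell
volume or mass density; dopants may carry an initial ionic charge
("Zn2+").  The reference compositions (gadolinium-derivative lysozyme
with its solvent variants, the doped C613 N193 O185 X10 targets) are
registered as fixtures.  At the default 1.2 g/cm^3 biomolecular density
the lysozyme unit-cell volume comes out at 2.34e-19 cm^3, matching the
tetragonal lysozyme cell.  Pulses are Gaussian or square in time
(t = 0 at peak/window centre), parameterized by photon energy, fluence
and FWHM; the default simulation window is +-1.2 FWHM, overridable
(the headline runs use -18..+18 fs).

## Problem sizes and accuracy budget

Default solver settings (rtol 3e-4, n_log 64 backbone knots, 4-point
quadrature, SCF grids of 440–480 points) run the lysozyme-in-water
system in ~2–4 minutes on one CPU and keep every verified invariant
(conservation, Saha balance, Maxwellian stationarity, Monte Carlo
cascade agreement) within its stated tolerance.  The defaults sit at
the knee of a measured convergence table: between n_log 48 and 96 and
step tolerances 3e-4 to 1e-4 the headline charge observables vary by
~±4%, with a slow residual downward drift (~5% per grid doubling) from
the finite resolution of the migrating photoelectron peak — the
phenomenon that makes grid adaptation around primary peaks essential
in this class of solver.  Reported charges therefore carry a ~5%
discretization uncertainty.  The heavy-element study cases (the
Gd-holding targets) in the test suite use the same physics at a
reduced problem size — n_log 48, rtol 1e-3 (n_log 40, rtol 2e-3 for
the Gd-solvent pair), shared runs between observables, and the
all-processes comparison covering the leading half of the pulse —
shifting light-element charges by a further ~2–4%.

Enabling heavy-atom secondary ionization changes the Gd charge itself
by under 1% — the collisional stripping of its outer shells is nearly
balanced by recombination — which is why the test suite carries the
Gd-charge observable on the shared primary-only run and reserves the
all-processes run for the carbon-insensitivity comparison.

## What the model does and does not capture

The study conditions reproduce the printed unit-cell compositions and
pulse parameters exactly; the atomic data are an independent
Xalpha/BEB realization rather than the Hartree-Fock/BED data of the
reference implementation.  The realization runs systematically *hot*:
light-atom charge observables come out ~25–50% above the reference
values (carbon at +10 fs: 1.60 vs 1.28; intensity-averaged light-atom
charge 0.85 vs 0.57 at 7.112 keV, 0.58 vs 0.34 at 9 keV), while
ratio- and structure-type observables (the heavy-seeded cascade
fraction, the square-vs-Gaussian pulse-shape effect, the
insensitivity of carbon to heavy-atom secondary ionization, the
fluence and photon-energy monotonicities) reproduce well.  The
over-ionization is atomic-data driven, not a solver artifact: the
cascade machinery agrees with an independent particle Monte Carlo to
3 sigma, and photoionization magnitudes match reference values to
~10%.  Its dominant source is the Xalpha valence thresholds — the
carbon 2p Delta-SCF ionization energy comes out at 8.8 eV against the
physical ~11.3 eV, and that threshold enters the BEB prefactor as
(Ry/B)^2, inflating the dominant carbon impact-ionization channel by
~1.65x and lowering the effective energy per ion pair.  Faster
cascades also shift the most-damaging primary-electron energy upward:
in this realization an 8.5 keV tracer cascade out-averages a 2 keV one
over a 15 fs pulse, and the Zn K-edge charge jump compresses to ~1.6x.
The average Gd charge saturates near +10 rather than +20, limited by
the photon budget (sigma F ~ 4.4 absorptions per Gd) with collisional
stripping of the outer shells almost balanced by three-body
recombination at the prevailing electron temperatures.

Real-crystal effects that the zero-dimensional model ignores (spatial
beam profile, crystal boundary transport, bound-to-bound electron
transfer to highly charged heavy ions, ionization-potential
depression, SASE temporal structure) bias experimental comparisons in
known directions discussed in the literature; none are modeled here.
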