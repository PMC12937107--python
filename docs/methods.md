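# Methods

## The sampling problem

Training data for machine-learned interatomic potentials (MLIPs) must cover
the configurations a production simulation will visit, but plain molecular
dynamics at the target temperature stays near its starting basin for any
affordable trajectory length.  This package biases the dynamics along
collective variables (CVs) learned on the fly from the model-style
descriptor itself, so that the system is pushed toward regions of
configuration space whose *descriptors* have not been seen — precisely the
structures an MLIP would be least informed about.

## Global descriptor

Per atom i, Cartesian moments of order L combine a radial expansion of the
neighbor distances with tensor powers of the unit bond vectors,

    Psi_{i,L,n} = sum_{j != i} R_n(r_ij) rhat_ij^(x L),      L = 0..3,

and fully contracted products of moments give invariant per-atom features
G_i (the Gaussian-moment construction, used here in its element-agnostic
form: atomic numbers are carried but do not enter the default descriptor).
The default contraction set is the pair invariant Psi_1.Psi_1 over radial
channel pairs (n1 <= n2), the triple invariant Psi_1 Psi_3 Psi_2 over all
channel triples, and the plain L = 0 channel sums; further invariants
("2,2", "3,3", "1,1,2", "2,2,2") are available but off by default, because
the default set is small enough to verify against scalar oracles while
already resolving conformational change.

The global descriptor is the system average s' = (1/N) sum_i G_i.  It is
invariant under rigid motions and atom relabeling and differentiable in the
positions; both the full Jacobian ds'/dR and the adjoint (vector-Jacobian
product) are implemented as hand-coded chain rules through the moment
tensors.  The MD loop only ever needs the adjoint against a single
co-vector, which costs O(pairs) per step independent of the feature count's
internal structure.

Radial bases: Gaussians with evenly spaced centers in [0, r_cut] and width
r_cut/n_radial (default), or sine-type (zeroth spherical Bessel) functions;
both are multiplied by a cosine cutoff envelope so values and first
derivatives vanish at r_cut.

### Descriptor scale

The descriptor's overall magnitude fixes the *unit* of CV space, and kernel
bandwidths are quoted in that unit.  `DescriptorSettings.scale` divides all
invariants by a constant.  For the alanine-dipeptide study we set
scale = 25, chosen so that the standard deviation of the leading CV over an
unbiased 10 ps run at 300 K is about 0.05 — the finest bandwidth in the
bias's conventional scan range — making bandwidth values meaningful for
this system.  The calibration uses only unbiased thermal fluctuations.
With a grossly mismatched scale the kernels are effectively delta
functions, bias gradients reach thousands of eV/Å and the molecule is torn
apart; runs that reach absurd potential energies (default limit 1e6 eV)
are terminated and flagged unstable.

## Collective variables

Reference descriptors collected every `deposition_stride` steps are stacked,
centered by the per-feature mean mu, and decomposed by SVD; the top-k right
singular vectors V^(k) define phi(s') = (s' - mu) V^(k).  Components are
sign-fixed (largest-magnitude entry positive) so refits are reproducible.
In the default *variable-basis* mode the basis is refit after every new
reference; kernels store their full-dimensional descriptors and are
re-projected into each new basis, which is the only lossless way to combine
CV-space kernels with a moving basis.  Until two references exist no basis
is defined and the bias is zero.  When the basis gains dimensions,
per-kernel variances keep their values along surviving dimensions and new
dimensions start at the nominal bandwidth; this is an approximation (merge
history in the old basis cannot be replayed), adequate because early-run
kernels are few.  CVs are not rescaled by singular values before the
isotropic bandwidth is applied.

## Bias potential

Normalized Gaussian kernels deposited at the visited CV positions model the
well-tempered density p_WT(s) as their weighted average.  The bias is

    V_n(s) = (gamma - 1) kB T log(p_WT(s)/Z_n + eps),
    gamma = dE/(kB T),   eps = exp(-gamma/(gamma - 1)),

bounded below by -dE; Z_n is the mean of p_WT over the kernel centers
(quadrature at the centers), which increases only when kernels overlap and
therefore rewards depositing into unexplored space.  Forces follow the
chain rule dV/dR = (dV/ds) V^(k)T (ds'/dR) through the descriptor adjoint.

Compression: a deposit landing within `compression_threshold` (default 1, in
bandwidth units, Mahalanobis under the neighbor's covariance) of an
existing kernel merges into it — weights add, the center becomes the
weighted mean and the per-dimension variances the weighted second moment,
the incoming deposit contributing the nominal isotropic bandwidth.  With
threshold 0 compression is off and density, Z and V reduce exactly to the
all-deposit formulas.  Z is recomputed exactly after every deposit (stores
stay small, at most thousands of kernels).  The first kernel is deposited
at step 0 (as soon as a basis exists), then every `deposition_stride` steps.

All energies are in eV with kB = 8.617333e-5 eV/K.

## Dynamics

A Langevin "middle" integrator (kick dt, half drift, Ornstein-Uhlenbeck
velocity refresh, half drift) propagates the system: one force evaluation
per step, velocity-Verlet in the zero-friction limit, excellent
configurational sampling at dt = 0.5 fs.  Units are eV, Å, fs, amu;
friction in 1/fs (default 0.01).  All randomness flows from one seeded
generator, so trajectories are bitwise reproducible.  Reference collection
and kernel deposition share one stride.

The uncertainty-driven comparison bias is E_UDD = A [exp(-sigma_E^2 c) - 1]
with c = 1/(N_ens N_atoms B^2) by default; the alternative reading
c = N_ens/(N_atoms B^2) is selectable, since the published formula's
operator placement is typographically ambiguous and both share the E(0) = 0
and E -> -A limits.  Forces use the exact ensemble energy-force covariance.
An optional guard resets the geometry to the starting configuration (and
redraws Maxwell-Boltzmann momenta) whenever the backend's per-atom force
uncertainty crosses a threshold, logging each reset step.

## Backends and what the toys do and do not show

Any object with `energy`/`forces` (eV, eV/Å) plugs in.  Shipped backends:

- a diatomic whose bond length lives in a double well (barrier 0.3 eV —
  about 12 kB T at 300 K, so unbiased runs stay trapped on test timescales);
- a Müller-Brown-style two-dimensional surface (scaled to ~1 eV features);
- Lennard-Jones clusters;
- a torsional chain: harmonic bonds/angles plus threefold torsions of
  barrier 0.25 eV with minima at 60/180/300 degrees, the desk-scale analog
  of a dihedral-governed molecule; its marginal torsion Boltzmann factor is
  known in closed form up to weak bond-angle coupling;
- an all-atom Amber-class model of alanine dipeptide (ACE-ALA-NME):
  harmonic bonds/angles, cosine torsions and impropers, 12-6 LJ and
  Coulomb point charges with Amber 1-4 scalings, ff99-family parameters
  and charges; backbone Phi/Psi quadruples exposed for Ramachandran
  analysis.  It reproduces the qualitative landscape (trapped unbiased
  dynamics, sterically excluded bands) rather than the exact published
  free-energy surface of the original parameterization.

The mock ensembles perturb a base backend with analytic per-member terms,
so ensemble disagreement has exact derivatives; a scheduled variant scripts
the reported force uncertainty per query.  These toys validate the
machinery (bounds, chain rules, exploration gain) — they do not establish
accuracy for condensed-phase systems, large molecules, or real MLIP
uncertainty landscapes.

## Analysis

- Dihedral coverage: both angles wrapped to [-180, 180), tiled into
  squares (15 degrees by default, 576 tiles), coverage = visited/total.
- MSD: time-origin averaged over all frames, atoms individually or
  mass-weighted molecular centers; periodic input is unwrapped by
  minimum-image accumulation and rejected if no cell is available.
- Diffusion: D = slope/6 by least squares over a window (default 10-50% of
  the maximum lag, excluding ballistic onset and poorly averaged tails);
  the standard error is the scatter of per-block estimates over five equal
  contiguous trajectory segments.  The finite-size correction adds
  xi kB T/(6 pi eta L) with xi = 2.837297 for a cubic box.
- Descriptor-PCA projection: per-frame global descriptors, one common PCA
  basis, first-k coordinates per frame for cluster visualization.

## Problem sizes

The shipped study runs 160,000 steps (80 ps) of the 22-atom dipeptide with
kernel deposits every 10,000 steps — minutes on one CPU core with the
default 145-feature descriptor.  Test-suite simulations use 15,000-40,000
steps on 2-6 atom toys.  Statistical assertions (equipartition, exploration
gain, flattening, Einstein relation) run over three seeds or tens of
independent particles and use tolerances of 3-10%.

## Known limitations

- NVT only; no constant-pressure dynamics.
- PCA is the only dimensionality reduction; the interface would admit
  nonlinear maps but none is provided.
- Kernel variances are carried approximately across basis refreshes with
  changing k (see above).
- The kinetic-temperature estimator inherits the usual O(gamma dt)
  half-step bias of one-force-per-step Langevin splittings (~1-3% at the
  defaults).
- The Amber-class dipeptide model is a faithful functional form with
  standard parameters, not a validated reproduction of any published
  force-field distribution.
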