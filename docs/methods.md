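# Methods

## The pulling model

All pulling data in this package come from overdamped Langevin dynamics of a
single coordinate ξ on a model landscape U(ξ), coupled to a moving harmonic
restraint:

    ξ_{n+1} = ξ_n + βD·F_total(ξ_n, t_n)·dt + √(2D·dt)·η_n,
    F_total = −dU/dξ + k_s(λ(t) − ξ),    λ(t) = λ₀ + v·t,

with η_n i.i.d. standard normal. This is the minimal dynamics that carries
the full nonequilibrium thermodynamics of constant-velocity pulling —
dissipation, work fluctuations satisfying the fluctuation–dissipation
relation, and Jarzynski's identity — while staying cheap enough that
hundreds of replicas run in seconds. It deliberately replaces all-atom
molecular dynamics: the six "routes" of a real unbinding problem are
emulated as distinct 1D landscapes, not as 3D directions.

Parameters (units, defaults, rationale):

| parameter | default | meaning |
| --- | --- | --- |
| v | 0.015 Å/ps | restraint velocity; the headline pulling protocol |
| k_s | 5 kcal·mol⁻¹·Å⁻² | pulling spring stiffness |
| T | 310 K | bath temperature; k_BT = 0.6160 kcal/mol |
| duration | 1750 ps | pulling time (26.25 Å of travel at the default v) |
| D | 0.1 Å²/ps | diffusion coefficient; sets the relaxation time 1/(βDk_s) ≈ 1.2 ps, comfortably shorter than all default pulling timescales |
| dt | 0.01 ps | Euler–Maruyama step; βDk_s·dt ≈ 0.008 keeps the discretization bias of the equilibrium variance below 1 % |
| equilibration | 50 ps | pre-pull relaxation at fixed λ₀ (≈ 40 relaxation times), so pulling starts from restrained equilibrium as Jarzynski's identity requires |

k_B is taken as 0.0019872041 kcal·mol⁻¹·K⁻¹; an explicit k_BT override is
accepted everywhere the temperature enters an estimator, for
reproducing analyses that used a rounded constant (0.6186 kcal/mol is a
common printed value at body temperature).

Work is accumulated at every integration step by the trapezoidal rule on
the spring force, W += ½(f_n + f_{n+1})·v·dt. Samples are stored at a
configurable stride (default ≈ 2000 samples per replica); the stored work
at a sample is the fully accumulated integral, so coarse storage never
biases the estimators. With stride 1 the stored force and work satisfy the
trapezoid identity exactly, which is how the work–force consistency test is
phrased. Replicas whose coordinate leaves the model domain are truncated
and flagged incomplete.

Per-replica seeds derive from the ensemble master seed through
`SeedSequence(master, spawn_key=(replica,))`, so ensembles are bit-for-bit
reproducible and extensible without reshuffling existing replicas.
Deliberately corrupted replicas (for exercising the filter) are truncated
at a uniform random fraction of the duration in [0.2, 0.8] — a stand-in for
whatever makes real pulling runs unusable, which is rarely documented.

## Free-energy estimation

The reaction coordinate is the restraint-center displacement λ − λ₀
(stiff-spring convention): work is a functional of the protocol, not of the
fluctuating ξ, so profiles from different replicas align exactly. No
second-order stiff-spring deconvolution (mapping Φ(λ) → Φ(ξ)) is applied;
the estimate is the free energy of the *restrained* system as a function of
λ. Consequently a landscape feature sharper than the spring — curvature
|U″| exceeding k_s — appears broadened and lowered. The validation
fixtures respect this: quantitative barrier recovery is only claimed for
barriers whose curvature stays below k_s, and all analytic comparisons use
the quadrature free energy of the restrained system,
F(λ) = −k_BT·ln ∫ e^{−β[U(x)+½k_s(x−λ)²]} dx, not the bare U.

Per displacement bin (half-open, default 0.25 Å) the work of every replica
covering the bin center is interpolated there linearly and one of two
estimators applied:

* exponential: −k_BT·ln⟨e^{−βW}⟩, computed with a log-sum-exp shift by
  min W. Exact in expectation at any v, but its finite-sample bias grows
  like e^{β²σ_W²/2}/n; with σ_W ≳ 2–3 k_BT it needs thousands of replicas.
* cumulant (2nd order): ⟨W⟩ − (⟨W²⟩ − ⟨W⟩²)/(2k_BT) with the population
  (÷n) variance, matching the δW² definition. Exact for Gaussian work and
  the default for ranking.

Profiles are anchored to zero at the first defined bin. Uncertainties are
bootstrap SDs over replicas (default 200 resamples, seeded); resampling
replicas rather than time points respects the only true independence in the
data. Bins reached by fewer than the estimator's minimum replica count are
flagged undefined rather than extrapolated.

Replica filtering drops incomplete runs first, then final works outside
median ± c·1.4826·MAD with c = 4 (≈ 4σ for Gaussian data). MAD = 0 means
no spread and keeps everything. Ensemble summaries report mean ± *sample*
SD (÷(n−1)) of final works — the conventional "±" for a table — while the
cumulant estimator keeps the population convention; the two conventions are
deliberate and documented here because they differ at small n.

The barrier of a profile is max ΔF minus the first bin, floored at zero,
ties resolved toward smaller displacement; routes are ranked by ascending
barrier (ties lexicographic), the lowest barrier being the most probable
unbinding route.

## Force profiles and rupture

Instantaneous spring forces of all samples of all replicas are averaged in
displacement bins (not time), so short and long replicas align. Smoothing
is a centered moving average (default window 5 bins) with truncated windows
at the ends; the rupture force is the global maximum of the smoothed
profile, ties toward smaller displacement. Forces are reported both in
kcal·mol⁻¹·Å⁻¹ and per molecule in pN (1 kcal·mol⁻¹·Å⁻¹ = 4184 J·mol⁻¹·Å⁻¹
/ N_A ≈ 69.477 pN). Published pulling studies sometimes print pN values
orders of magnitude below this conversion without stating their scaling;
the package surfaces both columns and leaves any rescaling to the user.

## State decomposition

Interior local maxima of a PMF whose topographic prominence reaches a
threshold (default 1.0 kcal/mol — large enough to ignore bootstrap noise,
small against any barrier of interest) become transition states; the minima
between consecutive transition states become metastable states; the first
bin is the bound state (ΔF = 0) and the last the unbound terminus. Plateaus
collapse to their midpoint bin. The kinds always follow the pattern
`bound (transition metastable)* transition? unbound`, which is validated on
construction. Letter labels (P for the bound pocket state, A/B/C/… for
interior states in displacement order, F for the free terminus) follow the
common lettering of unbinding-pathway figures and are cosmetic. With a
constant-velocity protocol each state maps to the pulling time
displacement/v.

## Tunnel analysis

A deliberately simple, self-contained grid method in the spirit of
Voronoi-based tunnel finders (it is CAVER-*like*, not CAVER-identical, and
no numerical agreement with any particular tool is claimed):

1. **Clearance field**: on a regular grid (default 0.25 Å) the additively
   weighted distance min_i(|p − c_i| − r_i) to the nearest atom surface,
   evaluated via a k-nearest-neighbor query (k = 16; exact whenever the vdW
   radius spread is below the kNN distance margin, which packed sphere sets
   satisfy easily). Van der Waals radii come from the PDB B-factor column
   when present, else an element table (C 1.7, N 1.55, O 1.52, S 1.8,
   H 1.2 Å).
2. **Start optimization**: within a shift budget (3 Å) the start moves to
   the voxel maximizing min(clearance, desired clearance = 5 Å), nearest
   wins ties; a start with no traversable voxel in reach is an error.
3. **Search**: Dijkstra over the 26-connected graph of voxels with
   clearance ≥ probe radius (0.9 Å); edge cost = step length divided by the
   squared mean clearance of its endpoints, clamped at the desired
   clearance. Tunnel priority = exp(−cost) ∈ (0, 1]: wide, short channels
   score near 1, and extending a path at fixed clearance strictly lowers
   priority (cost additivity).
4. **Distinct exits**: after accepting the cheapest start→boundary path,
   the free region within the clustering threshold (3.5 Å, grown to the
   local clearance where the channel is wider) of that path is blocked —
   never within the threshold of the start, so the cavity keeps its
   corridors — and the search repeats until no exit remains. A sealed
   cavity therefore returns an empty list, and two carved channels are
   found as two tunnels. This replaces the naive "one tunnel per connected
   boundary region" rule, which cannot work: outside a closed structure the
   free region is a single connected component, so every exit would merge
   and the cheapest channel would absorb all paths.
5. **Reporting**: each tunnel is truncated where it first reaches open
   space (clearance ≥ desired, past the bottleneck); bottleneck = minimum
   clamped clearance along the path, average radius = mean clamped
   clearance, length = polyline arc length.
6. **Clustering across snapshots**: average-linkage agglomerative
   clustering under the mean pointwise distance between arc-length
   resampled paths (64 points), cut at the clustering threshold;
   representative = highest-priority member; occurrence = fraction of
   snapshots with a member. Bottleneck residues are those whose atom
   surface lies within 0.5 Å of a member's bottleneck sphere, counted once
   per member.

The carved-shell fixture generator places an explicit ring of atoms at the
requested bottleneck radius (so the ground truth is exact by construction)
inside a sealed collar tube; grid discretization can only underestimate the
bottleneck, by at most the voxel half-diagonal, hence the one-grid-spacing
recovery tolerance.

## Trajectory metrics

Rigid superposition is the least-squares optimal proper rotation
(reflection-corrected, via quaternion/SVD machinery); RMSD is computed from
the transformed coordinates, so exact rigid-motion copies give RMSD at
machine precision. RMSF uses an iterated mean structure (two passes of
superpose-then-average, seeded with the first frame) — a common convention
where none is universal — and is reported per atom about the final mean.
Note the estimator is mildly biased low by the 6 rigid-body degrees of
freedom absorbed in the fit: the absorbed variance fraction is ≈ 6/(3N) for
N atoms, which is why the Gaussian-fixture validations use N ≥ 60.
Atom-pair distances are internal coordinates and skip superposition.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure of pulling data —
work distributions with the right fluctuation–dissipation behavior, replica
scatter, dropouts, barrier-dependent work, geometric bottlenecks with exact
ground truth — so passing tests demonstrate the estimators, filters and
searches are implemented correctly. It does not emulate a real protein:
there is no 3D ligand, no route-dependent friction, no memory effects from
slow solvent or conformational gating, and landscape "routes" share nothing
but the protocol. Conclusions about any specific molecular system still
require that system's trajectories.

## Numerical choices and degenerate inputs

* Linear interpolation of work in displacement; exact sample points return
  the stored value bitwise.
* Half-open bins [a, a+w); the first bin anchors ΔF = 0 exactly.
* Ties: barrier and rupture maxima toward smaller displacement; route
  ranking lexicographic on equal barriers; start optimization toward the
  original point.
* Degenerate spread (MAD = 0) keeps all replicas; a single replica reports
  SD 0 with an explicit flag; the cumulant estimator refuses n = 1 and
  points at the exponential estimator.
* All randomness flows from explicit seeds through `SeedSequence` spawn
  keys; fixed seeds give byte-identical CSV outputs across runs.

## Validation problem sizes

The shipped validation (test suite and `scripts/acceptance.py`) uses
n = 200 replicas at the default protocol for the Jarzynski identity check,
10⁴ Gaussian works for the closed form, 16 slow replicas (v = 0.001 Å/ps)
for harmonic recovery, 20 repetitions × 3 routes × 6 replicas at
v = 0.005 Å/ps for ranking recovery, carved fixtures of 1–3·10³ atoms on
0.25–0.5 Å grids, and 10⁴ frames for RMSF recovery. These sizes make the
statistical checks decisive (3-SE criteria) while a full run stays within a
few minutes on one CPU. Where "slow pulling" was open, v = 0.005 Å/ps was
chosen for ranking (dissipation cancels between routes, so ranking only
needs moderate slowness) and v = 0.001 Å/ps for quantitative profile
recovery (dissipation must itself be negligible).

## Known limitations

* One-dimensional dynamics only; routes are independent landscapes.
* No stiff-spring deconvolution; sharp features are spring-broadened.
* The exponential estimator's finite-sample bias at σ_W ≳ 2–3 k_BT makes
  its 3-SE identity check marginal at n = 200 — roughly one seed in three
  fails it even though the underlying data are unbiased (the cumulant
  estimator on the same ensembles returns ≈ 0). This is a property of the
  estimator, not a defect of the simulator; the cumulant route is the
  recommended default.
* The tunnel search is grid-based: bottlenecks are resolved to the voxel
  scale, cost is clamped, and the iterative blocking heuristic can in
  principle miss an exit narrower than the clustering threshold that runs
  parallel to an accepted one.
* No bidirectional (Crooks/BAR) estimators, umbrella sampling/WHAM, or
  higher-order cumulants; no force-clamp mode.
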