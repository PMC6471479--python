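"""Synthetic inputs for the unbinding-route pipeline.

Everything downstream of this module (PMF estimation, force profiles, state
decomposition, tunnel scoring, trajectory metrics) is exercised against data
generated here:

* 1D model free-energy landscapes built from analytic terms (harmonic wells,
  Gaussian barriers, linear ramps), with exact energies and forces;
* constant-velocity pulling ensembles from overdamped Langevin (Brownian)
  dynamics of a particle on such a landscape, dragged by a harmonic spring —
  the desk-scale surrogate for all-atom steered MD, with exact external-work
  bookkeeping;
* sphere-set "protein" structures: a packed spherical shell with carved
  cylindrical exit channels of known bottleneck radius and length;
* harmonic-fluctuation coordinate-frame series for RMSD/RMSF analysis.

The pulling defaults mirror a typical constant-velocity steered-MD protocol:
v = 0.015 Å/ps, spring constant 5 kcal·mol⁻¹·Å⁻², 310 K, 1.75 ns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import quad

from .units import kBT as thermal_energy

logger = logging.getLogger(__name__)

TERM_KINDS = ("flat", "harmonic", "gaussian_bump", "linear")


# ---------------------------------------------------------------------------
# Model landscapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PMFTerm:
    """One analytic term of a model landscape.

    kind:
      ``flat``           U = 0
      ``harmonic``       U = ½·height·(x − center)²   (height = stiffness,
                         kcal·mol⁻¹·Å⁻²)
      ``gaussian_bump``  U = height·exp(−(x − center)²/(2·width²))
      ``linear``         U = height·(x − center)      (height = slope,
                         kcal·mol⁻¹·Å⁻¹)
    """

    kind: str
    center: float = 0.0
    height: float = 0.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}; choose from {TERM_KINDS}")
        if self.kind == "gaussian_bump" and self.width <= 0:
            raise ValueError("gaussian_bump width must be > 0")

    def energy(self, x: float) -> float:
        if self.kind == "flat":
            return 0.0
        if self.kind == "harmonic":
            return 0.5 * self.height * (x - self.center) ** 2
        if self.kind == "gaussian_bump":
            u = (x - self.center) / self.width
            return self.height * math.exp(-0.5 * u * u)
        return self.height * (x - self.center)  # linear

    def dU_dx(self, x: float) -> float:
        if self.kind == "flat":
            return 0.0
        if self.kind == "harmonic":
            return self.height * (x - self.center)
        if self.kind == "gaussian_bump":
            u = (x - self.center) / self.width
            return -self.height * u / self.width * math.exp(-0.5 * u * u)
        return self.height  # linear


@dataclass(frozen=True)
class ModelPMF:
    """Sum-of-terms 1D free-energy landscape on a finite domain [Å]."""

    terms: tuple[PMFTerm, ...]
    domain: tuple[float, float] = (-50.0, 50.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"empty domain {self.domain}")

    def __contains__(self, x: float) -> bool:
        return self.domain[0] <= x <= self.domain[1]

    def energy(self, x: float) -> float:
        self._check_domain(x)
        return sum(t.energy(x) for t in self.terms)

    def force(self, x: float) -> float:
        """Mechanical force −dU/dx at ``x`` [kcal·mol⁻¹·Å⁻¹]."""
        self._check_domain(x)
        return -sum(t.dU_dx(x) for t in self.terms)

    def _check_domain(self, x: float) -> None:
        lo, hi = self.domain
        if not lo <= x <= hi:
            raise ValueError(f"x = {x} outside model domain [{lo}, {hi}]")

    def force_fn(self) -> Callable[[float], float]:
        """A fast unchecked −dU/dx callable for the integrator inner loop."""
        terms = self.terms
        if not terms or all(t.kind == "flat" for t in terms):
            return lambda x: 0.0
        if len(terms) == 1:
            t = terms[0]
            if t.kind == "harmonic":
                k, c = t.height, t.center
                return lambda x: -k * (x - c)
            if t.kind == "gaussian_bump":
                h, c, w = t.height, t.center, t.width
                inv_w2 = 1.0 / (w * w)
                exp = math.exp
                return lambda x: h * (x - c) * inv_w2 * exp(-0.5 * (x - c) ** 2 * inv_w2)
            if t.kind == "linear":
                s = t.height
                return lambda x: -s
        dU = [t.dU_dx for t in terms]
        return lambda x: -sum(d(x) for d in dU)


def evaluate_pmf(model: ModelPMF, x: float) -> tuple[float, float]:
    """Energy [kcal/mol] and force −dU/dx [kcal·mol⁻¹·Å⁻¹] at ``x``.

    Raises ValueError when ``x`` lies outside the model domain.
    """
    return model.energy(x), model.force(x)


def flat_model(domain: tuple[float, float] = (-50.0, 50.0)) -> ModelPMF:
    return ModelPMF(terms=(PMFTerm("flat"),), domain=domain)


def harmonic_model(stiffness: float, center: float = 0.0,
                   domain: tuple[float, float] = (-50.0, 50.0)) -> ModelPMF:
    return ModelPMF(terms=(PMFTerm("harmonic", center=center, height=stiffness),),
                    domain=domain)


def barrier_model(height: float, center: float, width: float,
                  domain: tuple[float, float] = (-50.0, 50.0)) -> ModelPMF:
    """Single Gaussian barrier of the given height [kcal/mol]."""
    return ModelPMF(terms=(PMFTerm("gaussian_bump", center=center,
                                   height=height, width=width),),
                    domain=domain)


# ---------------------------------------------------------------------------
# Pulling protocol and trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity pulling protocol for the Brownian simulator.

    velocity           restraint-center speed v [Å/ps]
    spring_constant    pulling spring k_s [kcal·mol⁻¹·Å⁻²]
    temperature        bath temperature [K]
    duration           pulling time [ps]
    timestep           Euler–Maruyama integration step [ps]
    diffusion_coefficient  D [Å²/ps]; sets the relaxation time 1/(βDk)
    lambda0            initial restraint-center position [Å]
    seed               master RNG seed
    equilibration      pre-pull relaxation at fixed lambda0 [ps], so pulling
                       starts from a restrained-equilibrium sample
    sample_interval    integration steps between stored samples; None → choose
                       so roughly 2000 samples are kept. Work is accumulated
                       at every integration step regardless.
    noise              False switches the thermal noise off (deterministic
                       ODE limit; drift still uses βD at ``temperature``)
    """

    velocity: float = 0.015
    spring_constant: float = 5.0
    temperature: float = 310.0
    duration: float = 1750.0
    timestep: float = 0.01
    diffusion_coefficient: float = 0.1
    lambda0: float = 0.0
    seed: int = 0
    equilibration: float = 50.0
    sample_interval: int | None = None
    noise: bool = True

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.duration < self.timestep:
            raise ValueError("duration must be >= timestep")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if self.equilibration < 0:
            raise ValueError("equilibration must be >= 0")

    @property
    def kBT(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def beta(self) -> float:
        return 1.0 / self.kBT

    def n_steps(self) -> int:
        return max(1, int(round(self.duration / self.timestep)))

    def effective_sample_interval(self) -> int:
        if self.sample_interval is not None:
            if self.sample_interval < 1:
                raise ValueError("sample_interval must be >= 1")
            return self.sample_interval
        return max(1, self.n_steps() // 2000)


@dataclass
class WorkTrajectory:
    """One pulling replica: sampled restraint schedule, coordinate, spring
    force on the system and accumulated external work."""

    route_id: str
    replica_id: int
    t: np.ndarray          # ps, strictly increasing, t[0] = 0
    lam: np.ndarray        # restraint-center position λ(t) [Å]
    xi: np.ndarray         # system coordinate ξ(t) [Å]
    force: np.ndarray      # spring force on the system k_s(λ−ξ) [kcal·mol⁻¹·Å⁻¹]
    work: np.ndarray       # accumulated external work W(t) [kcal/mol], W(0)=0
    completed: bool = True
    protocol: PullingProtocol | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.lam) == len(self.xi) == len(self.force) == len(self.work) == n):
            raise ValueError("sample arrays must share one length")
        if n == 0:
            raise ValueError("trajectory must have at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.work[0] != 0.0:
            raise ValueError("work must start at 0")

    @property
    def displacement(self) -> np.ndarray:
        """Restraint-center displacement λ(t) − λ(0) [Å]."""
        return self.lam - self.lam[0]

    @property
    def final_work(self) -> float:
        return float(self.work[-1])

    @property
    def final_displacement(self) -> float:
        return float(self.lam[-1] - self.lam[0])


def simulate_pulling(model: ModelPMF, protocol: PullingProtocol, *,
                     route_id: str = "route", replica_id: int = 0,
                     _duration_override: float | None = None,
                     _completed: bool = True) -> WorkTrajectory:
    """Pull a Brownian particle across ``model`` with a moving harmonic spring.

    Euler–Maruyama overdamped Langevin dynamics,

        ξ_{n+1} = ξ_n + βD·F_total(ξ_n, t_n)·dt + √(2D·dt)·η_n,

    with F_total = −dU/dξ + k_s(λ(t) − ξ) and λ(t) = λ0 + v·t. External work
    is accumulated by the trapezoidal rule at every integration step,
    W += ½·(f_n + f_{n+1})·v·dt with f = k_s(λ − ξ). The initial state is
    relaxed at fixed λ0 for ``protocol.equilibration`` ps.

    If ξ leaves the model domain the trajectory is truncated at the last
    in-domain sample, marked ``completed = False``, and a warning is logged.
    """
    v = protocol.velocity
    ks = protocol.spring_constant
    dt = protocol.timestep
    duration = protocol.duration if _duration_override is None else _duration_override
    lo, hi = model.domain

    pulled_hi = protocol.lambda0 + v * protocol.duration
    guard = 5.0 * math.sqrt(protocol.kBT / ks)
    if protocol.lambda0 - guard < lo or pulled_hi + guard > hi:
        raise ValueError(
            "model domain must cover the pulled range "
            f"[{protocol.lambda0}, {pulled_hi}] plus {guard:.2f} Å of spring slack")

    rng = np.random.default_rng(np.random.SeedSequence(protocol.seed))
    a = protocol.beta * protocol.diffusion_coefficient          # mobility βD
    namp = math.sqrt(2.0 * protocol.diffusion_coefficient * dt) if protocol.noise else 0.0
    force_fn = model.force_fn()

    n_steps = max(1, int(round(duration / dt)))
    stride = protocol.effective_sample_interval()

    # equilibrate at fixed restraint position
    x = protocol.lambda0
    n_eq = int(round(protocol.equilibration / dt))
    if n_eq:
        eq_noise = rng.standard_normal(n_eq)
        lam0 = protocol.lambda0
        a_dt = a * dt
        for i in range(n_eq):
            x += a_dt * (force_fn(x) + ks * (lam0 - x)) + namp * eq_noise[i]
            if not lo <= x <= hi:
                raise ValueError("system left the model domain during equilibration")

    noise = rng.standard_normal(n_steps)
    a_dt = a * dt
    lam = protocol.lambda0
    w = 0.0
    f = ks * (lam - x)

    ts = [0.0]
    lams = [lam]
    xis = [x]
    forces = [f]
    works = [0.0]
    completed = _completed
    v_dt_half = 0.5 * v * dt

    for i in range(n_steps):
        x = x + a_dt * (force_fn(x) + ks * (lam - x)) + namp * noise[i]
        lam = protocol.lambda0 + v * (i + 1) * dt
        if not lo <= x <= hi:
            logger.warning(
                "replica %s/%s: coordinate left model domain at t=%.3f ps; truncating",
                route_id, replica_id, (i + 1) * dt)
            completed = False
            break
        f_new = ks * (lam - x)
        w += v_dt_half * (f + f_new)
        f = f_new
        step = i + 1
        if step % stride == 0 or step == n_steps:
            ts.append(step * dt)
            lams.append(lam)
            xis.append(x)
            forces.append(f)
            works.append(w)

    return WorkTrajectory(
        route_id=route_id, replica_id=replica_id,
        t=np.asarray(ts), lam=np.asarray(lams), xi=np.asarray(xis),
        force=np.asarray(forces), work=np.asarray(works),
        completed=completed, protocol=protocol)


def generate_ensemble(model: ModelPMF, protocol: PullingProtocol,
                      n_replicas: int, corrupt_fraction: float = 0.0, *,
                      route_id: str = "route"):
    """An ensemble of independent pulling replicas for one route.

    Per-replica seeds are derived from the protocol seed through a
    counter-based spawn (replica i always gets the same stream, so ensembles
    can be extended without reshuffling). ``round(corrupt_fraction·n)``
    replicas are deliberately truncated at a uniform random fraction of the
    duration in [0.2, 0.8] and marked incomplete, to exercise downstream
    replica filtering.
    """
    from .pmf import WorkEnsemble

    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if not 0.0 <= corrupt_fraction < 1.0:
        raise ValueError("corrupt_fraction must be in [0, 1)")

    n_corrupt = int(round(corrupt_fraction * n_replicas))
    pick_rng = np.random.default_rng(
        np.random.SeedSequence(protocol.seed, spawn_key=(0xC0FFEE,)))
    corrupt_idx = set(pick_rng.choice(n_replicas, size=n_corrupt, replace=False).tolist())
    fractions = pick_rng.uniform(0.2, 0.8, size=n_replicas)

    trajectories = []
    for i in range(n_replicas):
        seed_i = int(np.random.SeedSequence(protocol.seed, spawn_key=(i,)).generate_state(1)[0])
        proto_i = replace(protocol, seed=seed_i)
        if i in corrupt_idx:
            traj = simulate_pulling(model, proto_i, route_id=route_id, replica_id=i,
                                    _duration_override=float(fractions[i]) * protocol.duration,
                                    _completed=False)
        else:
            traj = simulate_pulling(model, proto_i, route_id=route_id, replica_id=i)
        trajectories.append(traj)

    logger.info("ensemble %s: %d replicas simulated (%d deliberately truncated)",
                route_id, n_replicas, n_corrupt)
    return WorkEnsemble(route_id=route_id, trajectories=trajectories, protocol=protocol)


def restrained_free_energy(model: ModelPMF, spring_constant: float, kbt: float,
                           lambdas: Sequence[float]) -> np.ndarray:
    """Analytic (quadrature) free-energy profile of the restrained system.

    F(λ) = −kBT·ln ∫ exp(−β[U(x) + ½k_s(x−λ)²]) dx over the model domain,
    returned relative to the first λ. This is the quantity a quasi-static
    pulling experiment measures, and the oracle the Jarzynski estimators are
    validated against.
    """
    beta = 1.0 / kbt
    lo, hi = model.domain
    vals = []
    for lam in lambdas:
        u0 = model.energy(float(lam))  # shift for quadrature conditioning

        def integrand(x: float, lam=lam, u0=u0) -> float:
            u = model.energy(x) + 0.5 * spring_constant * (x - lam) ** 2
            return math.exp(-beta * (u - u0))

        # hint the integrator at the restraint peak, which is narrow on the
        # scale of the domain
        sd = math.sqrt(kbt / spring_constant)
        hints = [p for p in (lam - 5 * sd, lam, lam + 5 * sd) if lo < p < hi]
        z, _ = quad(integrand, lo, hi, limit=200, points=hints)
        vals.append(-kbt * math.log(z) + u0)
    out = np.asarray(vals)
    return out - out[0]


# ---------------------------------------------------------------------------
# Sphere-set structures with carved tunnels
# ---------------------------------------------------------------------------

@dataclass
class SphereStructure:
    """A set of pseudo-atoms (hard spheres) standing in for a protein."""

    names: list[str]
    resnames: list[str]
    resids: np.ndarray
    coords: np.ndarray      # (n, 3) Å
    radii: np.ndarray       # van der Waals radii, Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        n = len(self.coords)
        if n == 0:
            raise ValueError("structure must contain at least one atom")
        if not (len(self.names) == len(self.resnames) == len(self.resids) == len(self.radii) == n):
            raise ValueError("per-atom fields must share one length")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be > 0")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.coords.min(axis=0), self.coords.max(axis=0)

    def residue_label(self, atom_index: int) -> str:
        return f"{self.resnames[atom_index]}{int(self.resids[atom_index])}"


@dataclass(frozen=True)
class TunnelSpec:
    """Ground-truth description of one carved exit channel."""

    direction: tuple[float, float, float]
    bottleneck_radius: float
    length: float           # Å, measured from the cavity surface

    @property
    def cost_estimate(self) -> float:
        """length/bottleneck² — the idealized path cost used for ordering."""
        return self.length / self.bottleneck_radius ** 2


def carve_tunnel_structure(wall_thickness: float,
                           tunnel_specs: Sequence[tuple | TunnelSpec], *,
                           cavity_radius: float = 4.0,
                           atom_spacing: float = 1.0,
                           atom_radius: float = 1.7,
                           clearance_margin: float = 0.8) -> SphereStructure:
    """A spherical shell of packed pseudo-atoms with carved exit channels.

    The shell spans radii [cavity_radius, cavity_radius + wall_thickness].
    Each tunnel spec (direction, bottleneck_radius, length) carves a
    cylindrical channel along its axis whose clearance is
    bottleneck_radius + clearance_margin everywhere except at a ring of
    atoms placed mid-channel, where the clearance is exactly the requested
    bottleneck radius. Channels longer than the wall are extended with a
    sealed collar tube. Ground truth (specs sorted by idealized cost,
    cheapest first) is stored in ``metadata["tunnels"]``.
    """
    specs = [s if isinstance(s, TunnelSpec) else TunnelSpec(tuple(s[0]), float(s[1]), float(s[2]))
             for s in tunnel_specs]
    for s in specs:
        if s.bottleneck_radius <= 0:
            raise ValueError("bottleneck radii must be > 0")
        if s.length <= 0:
            raise ValueError("tunnel lengths must be > 0")
    dirs = [np.asarray(s.direction, dtype=float) for s in specs]
    dirs = [d / np.linalg.norm(d) for d in dirs]

    holes = [s.bottleneck_radius + clearance_margin for s in specs]
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            cosang = float(np.clip(dirs[i] @ dirs[j], -1.0, 1.0))
            sep = 2.0 * cavity_radius * math.sin(math.acos(cosang) / 2.0)
            if sep < (holes[i] + atom_radius) + (holes[j] + atom_radius):
                raise ValueError(
                    f"tunnel specs {i} and {j} overlap near the cavity surface")

    r_in = cavity_radius
    r_out = cavity_radius + wall_thickness
    reach = max([r_out] + [r_in + s.length for s in specs])

    # cubic lattice for the shell
    grid = np.arange(-r_out, r_out + 0.5 * atom_spacing, atom_spacing)
    gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    rad = np.linalg.norm(pts, axis=1)
    shell = pts[(rad >= r_in) & (rad <= r_out)]

    keep = np.ones(len(shell), dtype=bool)
    for d, hole in zip(dirs, holes):
        s_ax = shell @ d
        rho = np.linalg.norm(shell - np.outer(s_ax, d), axis=1)
        keep &= ~((s_ax > 0) & (rho < hole + atom_radius))
    coords = [shell[keep]]

    def _rings(center_ax: np.ndarray, radii: Iterable[float], d: np.ndarray,
               spacing_on_ring: float) -> np.ndarray:
        e1 = _any_perpendicular(d)
        e2 = np.cross(d, e1)
        pts_ = []
        for rr in radii:
            n_ring = max(8, int(math.ceil(2 * math.pi * rr / spacing_on_ring)))
            ang = 2 * math.pi * np.arange(n_ring) / n_ring
            pts_.append(center_ax[None, :]
                        + rr * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)))
        return np.vstack(pts_)

    # Sealed collar tube per channel: an annular wall of inner radius
    # hole + atom_radius running from where the shell stops providing that
    # wall out to the channel end, so the only way forward is along the axis.
    for spec, d, hole in zip(specs, dirs, holes):
        end = r_in + spec.length
        wall_r = hole + atom_radius
        s_start = math.sqrt(max(r_out ** 2 - wall_r ** 2, 0.0))
        if end <= s_start + 0.5 * atom_spacing:
            s_start = max(s_start - 2.0 * atom_spacing, r_in)
        ax_pos = np.arange(s_start, end + 0.25 * atom_spacing, atom_spacing)
        ring_r = np.arange(wall_r, wall_r + 2 * atom_spacing + 1e-9, atom_spacing)
        coords.append(np.vstack([_rings(s * d, ring_r, d, atom_spacing)
                                 for s in ax_pos]))

        # bottleneck diaphragm: concentric rings from the exact bottleneck
        # radius out to the collar wall, placed where the collar seals it
        s_ring = min(max(r_in + 0.5 * spec.length, s_start + atom_spacing),
                     end - atom_spacing)
        dia_r = np.arange(spec.bottleneck_radius + atom_radius,
                          wall_r + 2 * atom_spacing + 1e-9, 0.8)
        coords.append(_rings(s_ring * d, dia_r, d, 0.8 * atom_radius))

    xyz = np.vstack(coords)
    n = len(xyz)
    resids = np.arange(n) // 10 + 1
    names = [f"C{i % 10 + 1}" for i in range(n)]   # unique names per residue
    meta = {
        "tunnels": sorted(specs, key=lambda s: s.cost_estimate),
        "cavity_radius": cavity_radius,
        "wall_thickness": wall_thickness,
        "atom_radius": atom_radius,
        "clearance_margin": clearance_margin,
        "reach": reach,
    }
    return SphereStructure(
        names=names, resnames=["SPH"] * n, resids=resids,
        coords=xyz, radii=np.full(n, atom_radius), metadata=meta)


def _any_perpendicular(d: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(d, trial)
    return e / np.linalg.norm(e)


# ---------------------------------------------------------------------------
# Harmonic-fluctuation coordinate frames
# ---------------------------------------------------------------------------

def generate_fluctuation_frames(n_atoms: int, n_frames: int,
                                sigma_per_atom: Sequence[float], seed: int = 0, *,
                                reference: np.ndarray | None = None,
                                rigid_motions: bool = False,
                                frame_interval: float = 1.0):
    """Frames = reference + isotropic Gaussian displacements per atom.

    Each atom i is displaced by N(0, σ_i²) independently along x, y, z, so at
    large frame counts its RMSF about the mean tends to σ_i·√3. With
    ``rigid_motions`` every frame is additionally rotated and translated
    rigidly (exercising superposition, which must remove the effect).
    """
    from .metrics import FrameSeries

    sigma = np.asarray(sigma_per_atom, dtype=float)
    if sigma.shape != (n_atoms,):
        raise ValueError("sigma_per_atom must have one value per atom")
    if np.any(sigma < 0):
        raise ValueError("sigma values must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if reference is None:
        # spread reference points out so the set is never near-degenerate
        side = max(3.0, 2.0 * n_atoms ** (1.0 / 3.0))
        reference = rng.uniform(-side, side, size=(n_atoms, 3))
    reference = np.asarray(reference, dtype=float)

    disp = rng.standard_normal((n_frames, n_atoms, 3)) * sigma[None, :, None]
    frames = reference[None, :, :] + disp

    if rigid_motions:
        from scipy.spatial.transform import Rotation
        rots = Rotation.random(n_frames, random_state=np.random.RandomState(
            int(np.random.SeedSequence(seed, spawn_key=(1,)).generate_state(1)[0]) % (2**31)))
        shifts = rng.uniform(-10.0, 10.0, size=(n_frames, 3))
        frames = np.einsum("fij,faj->fai", rots.as_matrix(), frames) + shifts[:, None, :]

    names = ["CA"] * n_atoms
    resids = list(range(1, n_atoms + 1))
    times = frame_interval * np.arange(n_frames, dtype=float)
    return FrameSeries(names=names, resids=resids, frames=frames, times=times)
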