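"""Segmented Frenkel-exciton system models and stochastic bath trajectories.

A system is a set of two-level chromophores with fluctuating site energies,
static excitonic couplings ``J`` and fixed transition dipoles, partitioned
into segments.  Within a segment the full coherent Hamiltonian is kept;
between segments only the (weak) static coupling block and an incoherent
rate description survive.

Site-energy fluctuations follow independent Ornstein-Uhlenbeck processes
(overdamped Brownian oscillator bath in the classical, high-temperature
sense): each site energy is a stationary Gaussian process with standard
deviation ``sigma`` and exponential memory ``exp(-Lambda*t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


__all__ = [
    "BathParams",
    "SiteTrajectory",
    "CouplingMatrix",
    "DipoleSet",
    "Segmentation",
    "SystemModel",
    "generate_ou_trajectory",
    "segment_hamiltonian",
    "intersegment_coupling",
    "make_dimer_fixture",
    "make_two_ring_fixture",
    "segmentation_report",
]


@dataclass
class BathParams:
    """Per-site overdamped-bath parameters.

    Parameters
    ----------
    sigma : array of float
        Root-mean-square site-energy fluctuation per site (cm^-1), >= 0.
    lambda_inv : array of float
        Bath correlation time per site (fs), > 0.  ``Lambda = 1/lambda_inv``
        is the inverse correlation time appearing in the autocorrelation
        ``sigma**2 * exp(-Lambda * t)``.
    """

    sigma: np.ndarray
    lambda_inv: np.ndarray

    def __post_init__(self):
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.lambda_inv = np.atleast_1d(np.asarray(self.lambda_inv, dtype=float))
        if self.sigma.shape != self.lambda_inv.shape:
            raise ValueError("sigma and lambda_inv must have the same length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if np.any(self.lambda_inv <= 0):
            raise ValueError("correlation times lambda_inv must be positive")

    @property
    def n_sites(self) -> int:
        return self.sigma.size


@dataclass
class SiteTrajectory:
    """Instantaneous site energies on a uniform time grid.

    ``energies[k, n]`` is the energy of site ``n`` at time ``k * dt`` (cm^-1).
    """

    energies: np.ndarray
    dt: float
    means: np.ndarray

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        if self.energies.ndim != 2 or self.energies.shape[0] < 1:
            raise ValueError("energies must be a (frames, sites) array with >= 1 frame")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("trajectory contains non-finite energies")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.means.size != self.energies.shape[1]:
            raise ValueError("means length must match number of sites")

    @property
    def n_frames(self) -> int:
        return self.energies.shape[0]

    @property
    def n_sites(self) -> int:
        return self.energies.shape[1]


@dataclass
class CouplingMatrix:
    """Static excitonic coupling matrix J (cm^-1); symmetric, zero diagonal."""

    J: np.ndarray

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-10):
            raise ValueError("J must have zero diagonal")

    @property
    def n_sites(self) -> int:
        return self.J.shape[0]


@dataclass
class DipoleSet:
    """Ground-to-excited transition dipoles, one 3-vector per site."""

    mu_ge: np.ndarray

    def __post_init__(self):
        self.mu_ge = np.asarray(self.mu_ge, dtype=float)
        if self.mu_ge.ndim != 2 or self.mu_ge.shape[1] != 3:
            raise ValueError("mu_ge must be an (n_sites, 3) array")
        if not np.all(np.isfinite(self.mu_ge)):
            raise ValueError("dipoles must be finite")

    @property
    def n_sites(self) -> int:
        return self.mu_ge.shape[0]


@dataclass
class Segmentation:
    """Assignment of every site to exactly one segment.

    ``assignment[n]`` is the integer id of the segment containing site ``n``.
    Segment ids are the sorted unique values of ``assignment``.
    """

    assignment: np.ndarray

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1 or self.assignment.size == 0:
            raise ValueError("assignment must be a non-empty 1-D array")

    @property
    def n_sites(self) -> int:
        return self.assignment.size

    @property
    def segment_ids(self) -> np.ndarray:
        return np.unique(self.assignment)

    @property
    def n_segments(self) -> int:
        return self.segment_ids.size

    @property
    def counts(self) -> np.ndarray:
        """Per-segment site counts D_S, ordered as ``segment_ids``."""
        return np.array([np.sum(self.assignment == s) for s in self.segment_ids])

    def sites_of(self, segment_id: int) -> np.ndarray:
        sites = np.flatnonzero(self.assignment == segment_id)
        if sites.size == 0:
            raise KeyError(f"unknown segment id {segment_id!r}")
        return sites


@dataclass
class SystemModel:
    """Full segmented Frenkel-exciton system definition.

    ``temperature`` is in kelvin; ``None`` selects the high-temperature (HT)
    limit in which every segment equilibrium density matrix is the
    maximally mixed state ``I / D``.
    """

    means: np.ndarray
    bath: BathParams
    J: CouplingMatrix
    dipoles: DipoleSet
    segmentation: Segmentation
    temperature: float | None = 300.0
    kB: float = field(default=0.695035)

    def __post_init__(self):
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        n = self.means.size
        for name, m in [
            ("bath", self.bath.n_sites),
            ("J", self.J.n_sites),
            ("dipoles", self.dipoles.n_sites),
            ("segmentation", self.segmentation.n_sites),
        ]:
            if m != n:
                raise ValueError(f"{name} has {m} sites, expected {n}")
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError("temperature must be positive (or None for the HT limit)")

    @property
    def n_sites(self) -> int:
        return self.means.size

    @property
    def is_ht(self) -> bool:
        return self.temperature is None

    @property
    def beta(self) -> float:
        """Inverse temperature 1/(kB T) in (cm^-1)^-1; 0 in the HT limit."""
        if self.is_ht:
            return 0.0
        return 1.0 / (self.kB * self.temperature)


def generate_ou_trajectory(
    bath: BathParams,
    means: np.ndarray,
    n_frames: int,
    dt: float,
    seed: int,
) -> SiteTrajectory:
    """Sample fluctuating site energies with the exact OU discrete update.

    The update ``eps(t+dt) = m + (eps(t)-m) e^{-L dt}
    + sigma sqrt(1 - e^{-2 L dt}) xi`` reproduces the stationary Gaussian
    process with variance ``sigma**2`` and autocorrelation
    ``sigma**2 exp(-L t)`` exactly at any time step.  The initial frame is
    drawn from the stationary distribution.  Each site consumes an
    independent random stream spawned from ``seed``, so a site's trace does
    not depend on how many other sites are present.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    if means.size != bath.n_sites:
        raise ValueError("means length must match bath parameters")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")

    n = bath.n_sites
    out = np.empty((n_frames, n))
    streams = np.random.SeedSequence(seed).spawn(n)
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        sigma = bath.sigma[i]
        lam = 1.0 / bath.lambda_inv[i]
        decay = np.exp(-lam * dt)
        kick = sigma * np.sqrt(1.0 - decay**2)
        xi = rng.standard_normal(n_frames)
        x = np.empty(n_frames)
        x[0] = sigma * xi[0]
        # scipy.signal.lfilter computes the AR(1) recursion in C
        if n_frames > 1:
            from scipy.signal import lfilter

            driven = lfilter([1.0], [1.0, -decay], kick * xi[1:], zi=[decay * x[0]])[0]
            x[1:] = driven
        out[:, i] = means[i] + x
    return SiteTrajectory(energies=out, dt=dt, means=means)


def full_hamiltonian(traj: SiteTrajectory, J: CouplingMatrix, frame_index: int) -> np.ndarray:
    """Instantaneous full-system Hamiltonian at one frame (cm^-1)."""
    if not 0 <= frame_index < traj.n_frames:
        raise ValueError(f"frame {frame_index} out of range")
    H = J.J.copy()
    H[np.diag_indices_from(H)] = traj.energies[frame_index]
    return H


def segment_hamiltonian(
    traj: SiteTrajectory,
    J: CouplingMatrix,
    seg: Segmentation,
    segment_id: int,
    frame_index: int,
) -> np.ndarray:
    """Instantaneous one-exciton Hamiltonian block of one segment (cm^-1).

    The diagonal holds the segment sites' fluctuating energies at the given
    frame; the off-diagonal holds the intra-segment couplings only.
    """
    sites = seg.sites_of(segment_id)
    H = full_hamiltonian(traj, J, frame_index)
    return H[np.ix_(sites, sites)]


def intersegment_coupling(
    J: CouplingMatrix, seg: Segmentation, segment_i: int, segment_j: int
) -> np.ndarray:
    """Static rectangular coupling block between two distinct segments."""
    if segment_i == segment_j:
        raise ValueError("intersegment coupling requires two distinct segments")
    si = seg.sites_of(segment_i)
    sj = seg.sites_of(segment_j)
    return J.J[np.ix_(si, sj)]


def make_dimer_fixture(variant: str = "single_segment") -> SystemModel:
    """Two-site benchmark system.

    Site energies 11500 and 12000 cm^-1, sigma = 198 cm^-1, correlation time
    220 fs, parallel unit transition dipoles along x.  ``single_segment``
    couples the sites at 100 cm^-1 inside one segment; ``double_segment``
    reduces the coupling to 10 cm^-1 and puts each site in its own segment so
    that transfer between them is incoherent.
    """
    if variant == "single_segment":
        coupling, assignment = 100.0, [0, 0]
    elif variant == "double_segment":
        coupling, assignment = 10.0, [0, 1]
    else:
        raise ValueError(f"unknown dimer variant {variant!r}")
    means = np.array([11500.0, 12000.0])
    J = np.array([[0.0, coupling], [coupling, 0.0]])
    return SystemModel(
        means=means,
        bath=BathParams(sigma=[198.0, 198.0], lambda_inv=[220.0, 220.0]),
        J=CouplingMatrix(J),
        dipoles=DipoleSet(np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])),
        segmentation=Segmentation(np.array(assignment)),
        temperature=300.0,
    )


def _ring_positions(n: int, radius: float, z: float, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)])


def _ring_tangents(n: int, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([-np.sin(ang), np.cos(ang), np.zeros(n)])


def _dipole_dipole(pos: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Unit-strength dipole-dipole coupling kernel for unit dipoles."""
    n = pos.shape[0]
    J = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            r = pos[b] - pos[a]
            d = np.linalg.norm(r)
            rh = r / d
            J[a, b] = J[b, a] = (mu[a] @ mu[b] - 3.0 * (mu[a] @ rh) * (mu[b] @ rh)) / d**3
    return J


def make_two_ring_fixture(
    n_inner: int = 9,
    n_outer: int = 18,
    r_inner: float = 28.0,
    r_outer: float = 23.0,
    z_offset: float = 16.0,
    max_outer_coupling: float = 243.0,
    max_inner_coupling: float = 30.0,
    mean_outer: float = 11955.0,
    mean_inner: float = 12465.0,
    sigma_outer: float = 256.0,
    sigma_inner: float = 169.0,
    lambda_inv: float = 150.0,
) -> SystemModel:
    """Geometric two-ring surrogate of an LH2-type antenna.

    A synthetic stand-in for the real antenna Hamiltonian: two concentric
    rings of tangentially oriented unit dipoles (outer ring = strongly
    coupled B850-like band, inner ring = B800-like band).  Couplings are
    point dipole-dipole, rescaled per block so the largest nearest-neighbour
    coupling is ``max_outer_coupling`` within the outer ring and
    ``max_inner_coupling`` within the inner ring (inter-ring couplings use
    the outer-ring scale).  The outer ring is one segment; every inner-ring
    site is its own segment.
    """
    if n_inner < 1 or n_outer < 1:
        raise ValueError("ring site counts must be >= 1")
    if r_inner <= 0 or r_outer <= 0:
        raise ValueError("ring radii must be positive")

    pos = np.vstack(
        [
            _ring_positions(n_outer, r_outer, 0.0),
            _ring_positions(n_inner, r_inner, z_offset, phase=np.pi / max(n_inner, 1)),
        ]
    )
    mu = np.vstack([_ring_tangents(n_outer), _ring_tangents(n_inner, phase=np.pi / max(n_inner, 1))])
    J = _dipole_dipole(pos, mu)

    outer = np.arange(n_outer)
    inner = np.arange(n_outer, n_outer + n_inner)

    def _max_nn(idx: np.ndarray) -> float:
        if idx.size < 2:
            return 0.0
        block = np.abs(J[np.ix_(idx, idx)])
        return block.max()

    outer_scale = max_outer_coupling / _max_nn(outer) if _max_nn(outer) > 0 else 1.0
    inner_scale = max_inner_coupling / _max_nn(inner) if _max_nn(inner) > 0 else 1.0
    Js = np.zeros_like(J)
    Js[np.ix_(outer, outer)] = J[np.ix_(outer, outer)] * outer_scale
    Js[np.ix_(inner, inner)] = J[np.ix_(inner, inner)] * inner_scale
    Js[np.ix_(outer, inner)] = J[np.ix_(outer, inner)] * outer_scale
    Js[np.ix_(inner, outer)] = J[np.ix_(inner, outer)] * outer_scale

    assignment = np.concatenate([np.zeros(n_outer, dtype=int), 1 + np.arange(n_inner)])
    means = np.concatenate([np.full(n_outer, mean_outer), np.full(n_inner, mean_inner)])
    sigma = np.concatenate([np.full(n_outer, sigma_outer), np.full(n_inner, sigma_inner)])
    return SystemModel(
        means=means,
        bath=BathParams(sigma=sigma, lambda_inv=np.full(n_outer + n_inner, lambda_inv)),
        J=CouplingMatrix(Js),
        dipoles=DipoleSet(mu),
        segmentation=Segmentation(assignment),
        temperature=300.0,
    )


def segmentation_report(
    J: CouplingMatrix, seg: Segmentation, flag_fraction: float = 0.5
) -> dict:
    """Summarize intra- versus inter-segment coupling strengths.

    Supports the weak-coupling judgement behind a segmentation choice: for
    every segment pair, reports the largest inter-segment coupling, the
    largest intra-segment coupling of the two partners, and flags pairs
    whose inter-segment coupling exceeds ``flag_fraction`` times the weaker
    partner's intra-segment scale.
    """
    ids = seg.segment_ids
    intra = {}
    for s in ids:
        sites = seg.sites_of(s)
        block = np.abs(J.J[np.ix_(sites, sites)])
        intra[int(s)] = float(block.max()) if sites.size > 1 else 0.0
    pairs = []
    max_inter_overall = 0.0
    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            inter = float(np.abs(intersegment_coupling(J, seg, int(a), int(b))).max())
            max_inter_overall = max(max_inter_overall, inter)
            ref = min(x for x in (intra[int(a)], intra[int(b)]))
            ratio = inter / ref if ref > 0 else np.inf if inter > 0 else 0.0
            pairs.append(
                {
                    "segments": (int(a), int(b)),
                    "max_intersegment": inter,
                    "max_intrasegment": (intra[int(a)], intra[int(b)]),
                    "ratio": ratio,
                    "flagged": bool(inter > flag_fraction * ref) if ref > 0 else inter > 0,
                }
            )
    return {
        "max_intrasegment": intra,
        "max_intersegment": max_inter_overall,
        "pairs": pairs,
    }
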