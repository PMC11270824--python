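"""Numerical propagation of one- and two-exciton wavefunctions.

Time evolution over the fluctuating site energies is a time-ordered product
of per-frame short-time propagators.  Two paths are provided:

* ``dense`` — per-frame eigendecomposition of the instantaneous Hamiltonian
  (exact for each frozen frame); the default and the small-system oracle.
* ``trotter`` — symmetric splitting
  ``exp(-i D dt/2) exp(-i J dt) exp(-i D dt/2)`` where the static-coupling
  exponential ``exp(-i J dt)`` is precomputed once; second-order accurate in
  ``dt`` and cheaper for large segments because only diagonal phases change
  per frame.

All propagators are unitary products of unitaries, so unitarity and the
composition property ``U(a,c) = U(b,c) U(a,b)`` hold to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .model import CouplingMatrix, Segmentation, SiteTrajectory
from .units import TWO_PI_C

__all__ = [
    "OneExcitonPropagator",
    "TwoExcitonBasis",
    "TwoExcitonPropagator",
    "propagate_one",
    "build_two_exciton_basis",
    "two_exciton_hamiltonian",
    "two_exciton_coupling",
    "propagate_two",
    "transition_dipole_ef",
    "step_unitaries",
    "cumulative_propagators",
]


@dataclass
class OneExcitonPropagator:
    """One-exciton time-evolution matrix between two trajectory frames."""

    U: np.ndarray
    frame_start: int
    frame_end: int
    dt: float


@dataclass
class TwoExcitonBasis:
    """Ordered site-pair basis of the doubly excited manifold.

    ``strict`` mode excludes same-site double excitation (hard-core two-level
    chromophores), dimension N(N-1)/2.  ``bosonic`` mode includes (m, m) states
    shifted by the anharmonicity ``delta`` and carrying sqrt(2) dipole and
    coupling factors, dimension N(N+1)/2.
    """

    n_sites: int
    mode: str = "strict"
    delta: float = 0.0
    pairs: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.mode not in ("strict", "bosonic"):
            raise ValueError(f"unknown two-exciton mode {self.mode!r}")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        # a single two-level site has no doubly excited state in strict mode:
        # the basis is then empty and the EA signal vanishes downstream
        pairs = []
        for m in range(self.n_sites):
            start = m + 1 if self.mode == "strict" else m
            for n in range(start, self.n_sites):
                pairs.append((m, n))
        self.pairs = np.array(pairs, dtype=int).reshape(-1, 2)

    @property
    def dimension(self) -> int:
        return self.pairs.shape[0]


@dataclass
class TwoExcitonPropagator:
    """Two-exciton time-evolution matrix over a :class:`TwoExcitonBasis`."""

    U: np.ndarray
    basis: TwoExcitonBasis
    frame_start: int
    frame_end: int
    dt: float


def step_unitaries(
    eps_steps: np.ndarray, J_block: np.ndarray, dt: float, method: str = "dense"
) -> np.ndarray:
    """Per-frame short-time propagators ``exp(-i 2 pi c H_k dt)``.

    Parameters
    ----------
    eps_steps : (..., n_steps, D) array
        Diagonal (fluctuating) energies for each step, cm^-1.
    J_block : (D, D) array
        Static off-diagonal coupling block, cm^-1 (zero diagonal).
    """
    eps_steps = np.asarray(eps_steps, dtype=float)
    D = eps_steps.shape[-1]
    if J_block.shape != (D, D):
        raise ValueError("coupling block does not match energy dimension")
    if D == 1:
        return np.exp(-1j * TWO_PI_C * dt * eps_steps)[..., None]
    if method == "dense":
        H = np.zeros(eps_steps.shape + (D,), dtype=float)
        H[...] = J_block
        idx = np.arange(D)
        H[..., idx, idx] = eps_steps
        w, V = np.linalg.eigh(H)
        phase = np.exp(-1j * TWO_PI_C * dt * w)
        return np.einsum("...ik,...k,...jk->...ij", V, phase, V.conj())
    if method == "trotter":
        Vj = expm(-1j * TWO_PI_C * dt * J_block)
        half = np.exp(-1j * TWO_PI_C * (dt / 2.0) * eps_steps)
        return half[..., :, None] * Vj * half[..., None, :]
    raise ValueError(f"unknown propagation method {method!r}")


def cumulative_propagators(steps: np.ndarray) -> np.ndarray:
    """Left-ordered cumulative products ``U(0 -> k)`` for k = 0..n_steps.

    ``steps`` has shape (..., n_steps, D, D); the result has shape
    (..., n_steps + 1, D, D) with the identity in slot 0 and
    ``U_k-1 ... U_0`` in slot k.
    """
    lead = steps.shape[:-3]
    n_steps, D = steps.shape[-3], steps.shape[-1]
    out = np.empty(lead + (n_steps + 1, D, D), dtype=complex)
    out[..., 0, :, :] = np.eye(D)
    acc = np.broadcast_to(np.eye(D, dtype=complex), lead + (D, D)).copy()
    for k in range(n_steps):
        acc = steps[..., k, :, :] @ acc
        out[..., k + 1, :, :] = acc
    return out


def _segment_steps(
    traj: SiteTrajectory,
    J: CouplingMatrix,
    seg: Segmentation,
    segment_id: int,
    frame_start: int,
    frame_end: int,
):
    if not (0 <= frame_start <= frame_end < traj.n_frames):
        raise ValueError(
            f"frame range [{frame_start}, {frame_end}] outside trajectory "
            f"of {traj.n_frames} frames"
        )
    sites = seg.sites_of(segment_id)
    eps = traj.energies[frame_start:frame_end, :][:, sites]
    Jb = J.J[np.ix_(sites, sites)]
    return eps, Jb


def propagate_one(
    traj: SiteTrajectory,
    J: CouplingMatrix,
    seg: Segmentation,
    segment_id: int,
    frame_start: int,
    frame_end: int,
    method: str = "dense",
) -> OneExcitonPropagator:
    """One-exciton propagator of a segment from ``frame_start`` to ``frame_end``.

    Uses a left-point rule: the Hamiltonian of frame ``k`` propagates the
    interval ``[k, k+1)``; ``frame_end == frame_start`` yields the identity.
    """
    eps, Jb = _segment_steps(traj, J, seg, segment_id, frame_start, frame_end)
    steps = step_unitaries(eps, Jb, traj.dt, method=method)
    U = cumulative_propagators(steps)[-1]
    return OneExcitonPropagator(U=U, frame_start=frame_start, frame_end=frame_end, dt=traj.dt)


def build_two_exciton_basis(
    n_sites: int, mode: str = "strict", anharmonicity: float = 0.0
) -> TwoExcitonBasis:
    """Construct the ordered two-exciton site-pair basis."""
    return TwoExcitonBasis(n_sites=n_sites, mode=mode, delta=anharmonicity)


def two_exciton_coupling(J_block: np.ndarray, basis: TwoExcitonBasis) -> np.ndarray:
    """Static coupling part of the two-exciton Hamiltonian.

    ``<(m,n)|H|(m,k)> = J[n,k]`` for pairs sharing exactly one site index;
    in ``bosonic`` mode elements touching a same-site pair (m, m) pick up a
    factor sqrt(2) from bosonic normalization of the doubly occupied state.
    """
    nf = basis.dimension
    pairs = basis.pairs
    H = np.zeros((nf, nf))
    index = {tuple(p): i for i, p in enumerate(pairs)}
    for a, (m, n) in enumerate(pairs):
        for b, (p, q) in enumerate(pairs):
            if b <= a:
                continue
            shared = {m, n} & {p, q}
            if (m, n) == (p, q) or len(shared) != 1:
                continue
            if m == n or p == q:
                # coupling into/out of a doubly occupied site state
                s = shared.pop()
                others = ({m, n} - {s}).union({p, q} - {s})
                if len(others) != 1:
                    continue
                o = others.pop()
                H[a, b] = H[b, a] = np.sqrt(2.0) * J_block[s, o]
            else:
                s = shared.pop()
                a_other = (set((m, n)) - {s}).pop()
                b_other = (set((p, q)) - {s}).pop()
                H[a, b] = H[b, a] = J_block[a_other, b_other]
    return H


def two_exciton_energies(eps: np.ndarray, basis: TwoExcitonBasis) -> np.ndarray:
    """Diagonal pair energies ``eps_m + eps_n (+ delta if m == n)``.

    ``eps`` may carry leading batch axes; the pair axis is appended.
    """
    m, n = basis.pairs[:, 0], basis.pairs[:, 1]
    E = eps[..., m] + eps[..., n]
    if basis.mode == "bosonic":
        E = E + np.where(m == n, basis.delta, 0.0)
    return E


def two_exciton_hamiltonian(
    eps: np.ndarray, J_block: np.ndarray, basis: TwoExcitonBasis
) -> np.ndarray:
    """Instantaneous two-exciton Hamiltonian (cm^-1) for one frame."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape[-1] != basis.n_sites or J_block.shape[0] != basis.n_sites:
        raise ValueError("energies/couplings do not match the basis site count")
    H = two_exciton_coupling(J_block, basis).astype(float)
    H = H + np.diag(two_exciton_energies(eps, basis))
    return H


def two_exciton_step_unitaries(
    eps_steps: np.ndarray, J_block: np.ndarray, basis: TwoExcitonBasis,
    dt: float, method: str = "dense",
) -> np.ndarray:
    """Per-frame two-exciton propagators; see :func:`step_unitaries`."""
    E2 = two_exciton_energies(np.asarray(eps_steps, dtype=float), basis)
    J2 = two_exciton_coupling(J_block, basis)
    return step_unitaries(E2, J2, dt, method=method)


def propagate_two(
    traj: SiteTrajectory,
    J: CouplingMatrix,
    seg: Segmentation,
    segment_id: int,
    basis: TwoExcitonBasis,
    frame_start: int,
    frame_end: int,
    method: str = "dense",
) -> TwoExcitonPropagator:
    """Two-exciton propagator of a segment between two frames."""
    eps, Jb = _segment_steps(traj, J, seg, segment_id, frame_start, frame_end)
    if basis.n_sites != eps.shape[-1]:
        raise ValueError("basis site count does not match segment size")
    steps = two_exciton_step_unitaries(eps, Jb, basis, traj.dt, method=method)
    U = cumulative_propagators(steps)[-1]
    return TwoExcitonPropagator(
        U=U, basis=basis, frame_start=frame_start, frame_end=frame_end, dt=traj.dt
    )


def transition_dipole_ef(dipoles: np.ndarray, basis: TwoExcitonBasis) -> np.ndarray:
    """Transition dipoles between the one- and two-exciton manifolds.

    Returns an array ``mu_ef`` of shape (n_f, n_e, 3) with
    ``<(m,n)| mu |k> = mu_m delta_nk + mu_n delta_mk`` for m != n and
    ``sqrt(2) mu_m`` for the (m, m) states of ``bosonic`` mode.
    """
    dipoles = np.asarray(dipoles, dtype=float)
    if dipoles.shape != (basis.n_sites, 3):
        raise ValueError("dipoles must be (n_sites, 3) matching the basis")
    nf, ne = basis.dimension, basis.n_sites
    out = np.zeros((nf, ne, 3))
    for f, (m, n) in enumerate(basis.pairs):
        if m == n:
            out[f, m] = np.sqrt(2.0) * dipoles[m]
        else:
            out[f, n] += dipoles[m]
            out[f, m] += dipoles[n]
    return out
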