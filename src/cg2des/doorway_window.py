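"""Per-segment doorway and window functions of the coherence times.

The third-order response is factorized into a *doorway* part (preparation of
the excited-state density during the first coherence time t1), an
inter-segment *transfer* part (waiting time t2, handled by
:mod:`cg2des.kinetics`), and a *window* part (detection during t3).  All
three diagram classes share one doorway per pathway:

``D_{i,ab}(t1) = < mu_b^T U_i^ee(t1) mu_a >``            (nonrephasing)

with the rephasing doorway its complex conjugate.  The windows are
pathway-independent:

``W^GB_{j,gd}(t3) = < mu_d^T U_j^ee(t3) mu_g >``
``W^SE_{j,gd}(t3) = < mu_d^T U_j^ee(t3) rho_j^eq mu_g >``
``W^EA_{j,gd}(t3) = - < Tr[ U_j^ee(t3)^H  mu_d^ef^H  U_j^ff(t3)
                            mu_g^ef  rho_j^eq ] >``

Here ``mu_a`` is the vector of site-dipole a-components within segment i,
``rho^eq`` the segment equilibrium density matrix, and ``< >`` the average
over realizations taken as equidistant starting points along one long bath
trajectory.  The EA window carries the overall minus sign of the
excited-state-absorption contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CouplingMatrix,
    Segmentation,
    SiteTrajectory,
    SystemModel,
    generate_ou_trajectory,
)
from .propagation import (
    TwoExcitonBasis,
    cumulative_propagators,
    step_unitaries,
    transition_dipole_ef,
    two_exciton_step_unitaries,
)
from .units import KB_CM

__all__ = [
    "EquilibriumDensity",
    "SegmentEnergy",
    "DoorwayTable",
    "WindowTable",
    "equilibrium_density",
    "segment_energy",
    "doorway",
    "window_gb",
    "window_se",
    "window_ea",
    "time_grid",
    "ensemble_propagators",
]


@dataclass
class EquilibriumDensity:
    """Segment equilibrium density matrix and its temperature mode."""

    rho: np.ndarray
    mode: str  # "HT" or "finite"
    segment_id: int


@dataclass
class SegmentEnergy:
    """Trajectory-averaged thermal expectation energy of a segment (cm^-1)."""

    value: float
    segment_id: int


@dataclass
class DoorwayTable:
    """Doorway function ``values[t, a, b]`` on a uniform t1 grid."""

    values: np.ndarray
    dt: float
    segment_id: int
    pathway: str  # "nonrephasing" or "rephasing"


@dataclass
class WindowTable:
    """Window function ``values[t, g, d]`` on a uniform t3 grid."""

    values: np.ndarray
    dt: float
    segment_id: int
    diagram: str  # "GB", "SE" or "EA"


def time_grid(n: int, dt: float) -> np.ndarray:
    """Uniform coherence-time grid 0, dt, ..., (n-1) dt."""
    return np.arange(n) * float(dt)


def _check_grid(grid: np.ndarray, name: str) -> tuple[int, float]:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError(f"{name} must be a 1-D grid with >= 2 points")
    if abs(grid[0]) > 1e-12:
        raise ValueError(f"{name} must start at 0")
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError(f"{name} must be uniform")
    return grid.size, float(steps[0])


def _boltzmann_frames(
    traj: SiteTrajectory,
    J: CouplingMatrix,
    seg: Segmentation,
    segment_id: int,
):
    """Eigen-decompositions of every frame's segment Hamiltonian."""
    sites = seg.sites_of(segment_id)
    eps = traj.energies[:, sites]
    Jb = J.J[np.ix_(sites, sites)]
    D = sites.size
    H = np.zeros((traj.n_frames, D, D))
    H[:] = Jb
    idx = np.arange(D)
    H[:, idx, idx] = eps
    w, V = np.linalg.eigh(H)
    return w, V


def equilibrium_density(
    traj: SiteTrajectory,
    J: CouplingMatrix,
    seg: Segmentation,
    segment_id: int,
    temperature: float | None,
    frame: int | None = None,
    normalization: str = "ensemble",
    kB: float = KB_CM,
) -> EquilibriumDensity:
    """Segment equilibrium density matrix.

    HT limit (``temperature is None``): exactly ``I / D`` — equal population
    of all sites, zero coherence.  Finite temperature: the Boltzmann
    operator ``exp(-beta H(t))`` of the instantaneous segment Hamiltonian.
    With ``frame=None`` the operator is averaged over all frames and
    normalized by the averaged trace (unit trace by construction).  With an
    explicit ``frame``, ``normalization`` selects division by the
    ensemble-averaged trace (``"ensemble"``, the default — per-frame traces
    then deviate from 1) or by the frame's own trace (``"frame"``).
    """
    sites = seg.sites_of(segment_id)
    D = sites.size
    if temperature is None:
        return EquilibriumDensity(rho=np.eye(D) / D, mode="HT", segment_id=segment_id)
    if temperature <= 0:
        raise ValueError("temperature must be positive (or None for the HT limit)")
    beta = 1.0 / (kB * temperature)
    w, V = _boltzmann_frames(traj, J, seg, segment_id)
    w0 = w.min()  # common offset; cancels in the trace normalization
    weights = np.exp(-beta * (w - w0))
    B = np.einsum("fik,fk,fjk->fij", V, weights, V.conj())
    mean_trace = weights.sum(axis=1).mean()
    if frame is None:
        rho = B.mean(axis=0) / mean_trace
    else:
        if not 0 <= frame < traj.n_frames:
            raise ValueError(f"frame {frame} out of range")
        if normalization == "ensemble":
            rho = B[frame] / mean_trace
        elif normalization == "frame":
            rho = B[frame] / weights[frame].sum()
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
    return EquilibriumDensity(rho=rho, mode="finite", segment_id=segment_id)


def segment_energy(
    traj: SiteTrajectory,
    J: CouplingMatrix,
    seg: Segmentation,
    segment_id: int,
    temperature: float | None,
    kB: float = KB_CM,
) -> SegmentEnergy:
    """Ensemble-averaged thermal expectation energy of a segment (cm^-1).

    Per frame the thermal expectation of the instantaneous exciton
    eigenvalues is taken (equal weights in the HT limit), then averaged over
    the full trajectory.
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory is empty")
    beta = 0.0 if temperature is None else 1.0 / (kB * temperature)
    if temperature is not None and temperature <= 0:
        raise ValueError("temperature must be positive (or None for the HT limit)")
    w, _ = _boltzmann_frames(traj, J, seg, segment_id)
    if beta == 0.0:
        e_frames = w.mean(axis=1)
    else:
        w0 = w.min(axis=1, keepdims=True)
        p = np.exp(-beta * (w - w0))
        p /= p.sum(axis=1, keepdims=True)
        e_frames = (p * w).sum(axis=1)
    return SegmentEnergy(value=float(e_frames.mean()), segment_id=segment_id)


def ensemble_propagators(
    system: SystemModel,
    segment_id: int,
    n_t: int,
    dt: float,
    realizations: int,
    seed: int,
    spacing: int | None = None,
    method: str = "dense",
    traj: SiteTrajectory | None = None,
    starts: np.ndarray | None = None,
    manifold: str = "one",
    basis: TwoExcitonBasis | None = None,
) -> tuple[np.ndarray, SiteTrajectory, np.ndarray]:
    """Batched segment propagators ``U(start -> start + k)`` for one segment.

    Returns ``(U, traj, starts)`` with ``U`` of shape
    ``(realizations, n_t, D, D)``.  If ``traj``/``starts`` are not supplied,
    one long trajectory is generated from ``seed`` with starting points
    spaced ``spacing`` frames apart (default: the coherence-window length),
    following the equidistant-starting-point averaging scheme.
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    sites = system.segmentation.sites_of(segment_id)
    if spacing is None:
        spacing = n_t - 1
    if traj is None:
        n_frames = spacing * (realizations - 1) + n_t
        traj = generate_ou_trajectory(system.bath, system.means, n_frames, dt, seed)
    elif abs(traj.dt - dt) > 1e-12:
        raise ValueError("grid spacing does not match the trajectory time step")
    if starts is None:
        starts = np.arange(realizations, dtype=int) * spacing
    starts = np.asarray(starts, dtype=int)
    if starts.max() + n_t > traj.n_frames + 1 or starts.min() < 0:
        raise ValueError("starting points exceed the trajectory length")

    idx = starts[:, None] + np.arange(n_t - 1)[None, :]
    eps = traj.energies[:, sites][idx]  # (S, n_t-1, D)
    Jb = system.J.J[np.ix_(sites, sites)]
    if manifold == "one":
        steps = step_unitaries(eps, Jb, dt, method=method)
    elif manifold == "two":
        if basis is None:
            raise ValueError("two-exciton propagation requires a basis")
        steps = two_exciton_step_unitaries(eps, Jb, basis, dt, method=method)
    else:
        raise ValueError(f"unknown manifold {manifold!r}")
    U = cumulative_propagators(steps)
    return U, traj, starts


def _segment_dipoles(system: SystemModel, segment_id: int) -> np.ndarray:
    sites = system.segmentation.sites_of(segment_id)
    return system.dipoles.mu_ge[sites]


def doorway(
    system: SystemModel,
    segment_id: int,
    t1_grid: np.ndarray,
    realizations: int,
    seed: int,
    pathway: str = "nonrephasing",
    spacing: int | None = None,
    method: str = "dense",
    traj: SiteTrajectory | None = None,
    starts: np.ndarray | None = None,
) -> DoorwayTable:
    """Ensemble-averaged doorway function of a segment on a t1 grid.

    At t1 = 0 the value is the static dipole contraction
    ``sum_n mu_{n,a} mu_{n,b}``.
    """
    if pathway not in ("nonrephasing", "rephasing"):
        raise ValueError(f"unknown pathway {pathway!r}")
    n_t, dt = _check_grid(t1_grid, "t1_grid")
    U, _, _ = ensemble_propagators(
        system, segment_id, n_t, dt, realizations, seed,
        spacing=spacing, method=method, traj=traj, starts=starts,
    )
    mu = _segment_dipoles(system, segment_id)
    vals = np.einsum("stij,ib,ja->tab", U, mu, mu) / U.shape[0]
    if pathway == "rephasing":
        vals = vals.conj()
    return DoorwayTable(values=vals, dt=dt, segment_id=segment_id, pathway=pathway)


def window_gb(
    system: SystemModel,
    segment_id: int,
    t3_grid: np.ndarray,
    realizations: int,
    seed: int,
    spacing: int | None = None,
    method: str = "dense",
    traj: SiteTrajectory | None = None,
    starts: np.ndarray | None = None,
) -> WindowTable:
    """Ground-state-bleach window; independent of the equilibrium density."""
    n_t, dt = _check_grid(t3_grid, "t3_grid")
    U, _, _ = ensemble_propagators(
        system, segment_id, n_t, dt, realizations, seed,
        spacing=spacing, method=method, traj=traj, starts=starts,
    )
    mu = _segment_dipoles(system, segment_id)
    vals = np.einsum("stij,id,jg->tgd", U, mu, mu) / U.shape[0]
    return WindowTable(values=vals, dt=dt, segment_id=segment_id, diagram="GB")


def _check_rho(rho: EquilibriumDensity | np.ndarray, D: int) -> np.ndarray:
    rho = rho.rho if isinstance(rho, EquilibriumDensity) else np.asarray(rho)
    if rho.shape != (D, D):
        raise ValueError("equilibrium density does not match the segment size")
    if abs(np.trace(rho) - 1.0) > 1e-8:
        raise ValueError("equilibrium density must have unit trace")
    return rho


def window_se(
    system: SystemModel,
    segment_id: int,
    rho_eq: EquilibriumDensity | np.ndarray,
    t3_grid: np.ndarray,
    realizations: int,
    seed: int,
    spacing: int | None = None,
    method: str = "dense",
    traj: SiteTrajectory | None = None,
    starts: np.ndarray | None = None,
) -> WindowTable:
    """Stimulated-emission window, starting from the segment equilibrium."""
    n_t, dt = _check_grid(t3_grid, "t3_grid")
    mu = _segment_dipoles(system, segment_id)
    rho = _check_rho(rho_eq, mu.shape[0])
    U, _, _ = ensemble_propagators(
        system, segment_id, n_t, dt, realizations, seed,
        spacing=spacing, method=method, traj=traj, starts=starts,
    )
    vals = np.einsum("stij,id,jk,kg->tgd", U, mu, rho, mu) / U.shape[0]
    return WindowTable(values=vals, dt=dt, segment_id=segment_id, diagram="SE")


def window_ea(
    system: SystemModel,
    segment_id: int,
    rho_eq: EquilibriumDensity | np.ndarray,
    basis: TwoExcitonBasis,
    t3_grid: np.ndarray,
    realizations: int,
    seed: int,
    spacing: int | None = None,
    method: str = "dense",
    traj: SiteTrajectory | None = None,
    starts: np.ndarray | None = None,
) -> WindowTable:
    """Excited-state-absorption window (carries the overall minus sign).

    For a single two-level site in strict mode the two-exciton manifold is
    empty and the window vanishes identically.
    """
    n_t, dt = _check_grid(t3_grid, "t3_grid")
    mu = _segment_dipoles(system, segment_id)
    D = mu.shape[0]
    rho = _check_rho(rho_eq, D)
    if basis.n_sites != D:
        raise ValueError("two-exciton basis does not match the segment size")
    if basis.dimension == 0:
        vals = np.zeros((n_t, 3, 3), dtype=complex)
        return WindowTable(values=vals, dt=dt, segment_id=segment_id, diagram="EA")
    U1, traj, starts = ensemble_propagators(
        system, segment_id, n_t, dt, realizations, seed,
        spacing=spacing, method=method, traj=traj, starts=starts,
    )
    U2, _, _ = ensemble_propagators(
        system, segment_id, n_t, dt, realizations, seed,
        spacing=spacing, method=method, traj=traj, starts=starts,
        manifold="two", basis=basis,
    )
    A = transition_dipole_ef(mu, basis)  # (nf, ne, 3)
    vals = np.zeros((n_t, 3, 3), dtype=complex)
    for g in range(3):
        Ag = A[:, :, g]
        if not Ag.any():
            continue
        T1 = Ag @ rho  # (nf, ne)
        X = np.einsum("stfh,he->stfe", U2, T1)
        for d in range(3):
            Ad = A[:, :, d]
            if not Ad.any():
                continue
            vals[:, g, d] = -np.einsum(
                "stab,fa,stfb->t", U1.conj(), Ad, X
            ) / U1.shape[0]
    return WindowTable(values=vals, dt=dt, segment_id=segment_id, diagram="EA")
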