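"""Brute-force third-order response of the full (unsegmented) system.

Validation oracle for the coarse-grained path on small aggregates
(N <= 4 sites): every one of the six double-sided diagrams (GB/SE/EA x
rephasing/nonrephasing) is evaluated by explicit wavefunction propagation
through all three time intervals, with no segmentation and no equilibration
assumption.  The formalism propagates classical bath trajectories, i.e. it
describes high-temperature-limit dynamics.

For one noise realization starting at frame s, with ``P(k)`` the cumulative
one-exciton propagator over k steps from s (``P2`` its two-exciton
counterpart), ``v_x`` the site-dipole x-component vector and ``A_x`` the
one-to-two-exciton dipole matrix, the diagrams read (K3 = k1 + n2,
K4 = k1 + n2 + k3, n2 the number of waiting-time steps):

``GB_NR = < [v_b' P(k1) v_a]         [v_d' P(K4) P(K3)^H v_g] >``
``GB_R  = < [v_b' P(k1) v_a]^*       [v_d' P(K4) P(K3)^H v_g] >``
``SE_NR = < [v_g' P(K3) P(k1)^H v_b]^* [v_d' P(K4) v_a] >``
``SE_R  = < [v_g' P(K3) v_a]^*       [v_d' P(K4) P(k1)^H v_b] >``
``EA_NR = -< v_b' P(k1) P(K4)^H A_d' P2(K4) P2(K3)^H A_g P(K3) v_a >``
``EA_R  = -< v_a' P(K4)^H A_d' P2(K4) P2(K3)^H A_g P(K3) P(k1)^H v_b >``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SiteTrajectory, SystemModel, generate_ou_trajectory
from .propagation import (
    build_two_exciton_basis,
    step_unitaries,
    transition_dipole_ef,
    two_exciton_step_unitaries,
)
from .spectra import PolarizationWeights, ResponseGrid

__all__ = ["FullResponseGrid", "full_2des_small", "MAX_ORACLE_SITES"]

MAX_ORACLE_SITES = 4

_DIAGRAM_KEYS = (
    ("GB", "nonrephasing"), ("GB", "rephasing"),
    ("SE", "nonrephasing"), ("SE", "rephasing"),
    ("EA", "nonrephasing"), ("EA", "rephasing"),
)


@dataclass
class FullResponseGrid:
    """Molecular-frame response components R(t1, t3) at fixed t2.

    ``components[(diagram, pathway)][(a, b, g, d)]`` is the (nt1, nt3)
    complex response for one Cartesian pulse-polarization combination.
    """

    components: dict
    dt1: float
    dt3: float
    t2: float  # ps
    meta: dict = field(default_factory=dict)

    def lab_response(self, weights: PolarizationWeights, pathway: str) -> ResponseGrid:
        """Contract with orientational weights into a lab-frame response."""
        diagrams = {}
        for d in ("GB", "SE", "EA"):
            combos = self.components[(d, pathway)]
            R = None
            for (a, b, g, dd), arr in combos.items():
                w = weights.A[a, b, g, dd]
                if w == 0.0:
                    continue
                R = w * arr if R is None else R + w * arr
            if R is None:
                nt1 = next(iter(next(iter(self.components.values())).values())).shape
                R = np.zeros(nt1, dtype=complex)
            diagrams[d] = R
        return ResponseGrid(
            diagrams=diagrams, pathway=pathway, dt1=self.dt1, dt3=self.dt3,
            t2=self.t2, scheme=weights.scheme,
        )


class _PropStore:
    """Cumulative propagators kept only at the frame offsets that are used."""

    def __init__(self, needed: np.ndarray, n_real: int, dim: int):
        self.needed = needed
        self.pos = {int(k): i for i, k in enumerate(needed)}
        self.P = np.empty((n_real, needed.size, dim, dim), dtype=complex)

    def get(self, k: int) -> np.ndarray:
        return self.P[:, self.pos[int(k)]]

    def gather(self, idx: np.ndarray) -> np.ndarray:
        slots = np.searchsorted(self.needed, idx)
        return self.P[:, slots]


def _accumulate(steps_all: np.ndarray, starts: np.ndarray, total_steps: int,
                store: _PropStore) -> None:
    n_real, dim = starts.size, steps_all.shape[-1]
    acc = np.broadcast_to(np.eye(dim, dtype=complex), (n_real, dim, dim)).copy()
    needed = set(store.pos)
    if 0 in needed:
        store.P[:, store.pos[0]] = acc
    for j in range(total_steps):
        acc = steps_all[starts + j] @ acc
        if (j + 1) in needed:
            store.P[:, store.pos[j + 1]] = acc


def full_2des_small(
    system: SystemModel,
    t1_grid: np.ndarray,
    t2: float,
    t3_grid: np.ndarray,
    realizations: int,
    seed: int,
    spacing: int | None = None,
    basis_mode: str = "strict",
    anharmonicity: float = 0.0,
    traj: SiteTrajectory | None = None,
    starts: np.ndarray | None = None,
    chunk: int = 200,
) -> FullResponseGrid:
    """Direct evaluation of all six diagrams for a small full system.

    ``t2`` is the waiting time in femtoseconds and is rounded to the
    trajectory frame grid.  Realizations are equidistant starting points
    along one long trajectory (``spacing`` frames apart, default one
    coherence window).  Refuses systems with more than four sites — use the
    coarse-grained path there.
    """
    from .doorway_window import _check_grid

    N = system.n_sites
    if N > MAX_ORACLE_SITES:
        raise ValueError(
            f"full propagation oracle is limited to {MAX_ORACLE_SITES} sites "
            f"(got {N}); use the coarse-grained path for larger systems"
        )
    nt1, dt = _check_grid(t1_grid, "t1_grid")
    nt3, dt3 = _check_grid(t3_grid, "t3_grid")
    if abs(dt - dt3) > 1e-12:
        raise ValueError("t1 and t3 grids must share one time step")
    if t2 < 0:
        raise ValueError("waiting time must be >= 0")
    n2 = int(round(t2 / dt))
    total_steps = (nt1 - 1) + n2 + (nt3 - 1)
    if spacing is None:
        spacing = nt1 - 1
    if traj is None:
        n_frames = spacing * (realizations - 1) + total_steps + 1
        traj = generate_ou_trajectory(system.bath, system.means, n_frames, dt, seed)
    elif abs(traj.dt - dt) > 1e-12:
        raise ValueError("grid spacing does not match the trajectory time step")
    if starts is None:
        starts = np.arange(realizations, dtype=int) * spacing
    starts = np.asarray(starts, dtype=int)
    if starts.max() + total_steps + 1 > traj.n_frames:
        raise ValueError("starting points exceed the trajectory length")

    basis = build_two_exciton_basis(N, mode=basis_mode, anharmonicity=anharmonicity)
    mu = system.dipoles.mu_ge
    A_ef = transition_dipole_ef(mu, basis)  # (nf, ne, 3)
    nf = basis.dimension

    # per-frame short-time propagators along the whole trajectory
    eps_steps = traj.energies[:-1] if traj.n_frames > 1 else traj.energies[:0]
    steps1 = step_unitaries(eps_steps, system.J.J, dt, method="dense")
    steps2 = two_exciton_step_unitaries(eps_steps, system.J.J, basis, dt, method="dense")

    needed = np.unique(np.concatenate(
        [np.arange(nt1), n2 + np.arange(nt1 + nt3 - 1)]
    ))
    K3_idx = np.arange(nt1) + n2
    K4_idx = K3_idx[:, None] + np.arange(nt3)[None, :]

    # Cartesian combinations with nonzero dipole components, restricted to
    # the 21-component support of the isotropic average
    active_axes = [x for x in range(3) if np.any(mu[:, x])]
    combos = []
    for a in active_axes:
        for b in active_axes:
            for g in active_axes:
                for d in active_axes:
                    if (a == b and g == d) or (a == g and b == d) or (a == d and b == g):
                        combos.append((a, b, g, d))

    sums = {key: {c: np.zeros((nt1, nt3), dtype=complex) for c in combos}
            for key in _DIAGRAM_KEYS}

    for lo in range(0, starts.size, chunk):
        sub = starts[lo : lo + chunk]
        R = sub.size
        P1 = _PropStore(needed, R, N)
        _accumulate(steps1, sub, total_steps, P1)
        P2 = _PropStore(needed, R, nf)
        _accumulate(steps2, sub, total_steps, P2)

        Pk1 = P1.P[:, :nt1] if np.array_equal(needed[:nt1], np.arange(nt1)) else P1.gather(np.arange(nt1))
        PK3 = P1.gather(K3_idx)  # (R, nt1, N, N)
        PK4 = P1.gather(K4_idx.ravel()).reshape(R, nt1, nt3, N, N)
        P2K3 = P2.gather(K3_idx)
        P2K4 = P2.gather(K4_idx.ravel()).reshape(R, nt1, nt3, nf, nf)

        for (a, b, g, d) in combos:
            va, vb, vg, vd = mu[:, a], mu[:, b], mu[:, g], mu[:, d]
            Ag, Ad = A_ef[:, :, g], A_ef[:, :, d]

            d_ba = np.einsum("i,rtij,j->rt", vb, Pk1, va)  # v_b' P(k1) v_a
            win = np.einsum("i,rtsij,rtkj,k->rts", vd, PK4, PK3.conj(), vg)
            sums[("GB", "nonrephasing")][(a, b, g, d)] += np.einsum("rt,rts->ts", d_ba, win)
            sums[("GB", "rephasing")][(a, b, g, d)] += np.einsum("rt,rts->ts", d_ba.conj(), win)

            # SE nonrephasing: bra [v_g' P(K3) P(k1)^H v_b]^*, ket v_d' P(K4) v_a
            bra_nr = np.einsum("i,rtij,rtkj,k->rt", vg, PK3, Pk1.conj(), vb)
            ket_nr = np.einsum("i,rtsij,j->rts", vd, PK4, va)
            sums[("SE", "nonrephasing")][(a, b, g, d)] += np.einsum(
                "rt,rts->ts", bra_nr.conj(), ket_nr)
            # SE rephasing: bra [v_g' P(K3) v_a]^*, ket v_d' P(K4) P(k1)^H v_b
            bra_r = np.einsum("i,rtij,j->rt", vg, PK3, va)
            ket_r = np.einsum("i,rtsij,rtkj,k->rts", vd, PK4, Pk1.conj(), vb)
            sums[("SE", "rephasing")][(a, b, g, d)] += np.einsum(
                "rt,rts->ts", bra_r.conj(), ket_r)

            if nf == 0:
                continue
            ea_nr = sums[("EA", "nonrephasing")][(a, b, g, d)]
            ea_r = sums[("EA", "rephasing")][(a, b, g, d)]
            for t in range(nt1):
                # right chains at fixed k1 = t
                y_nr = np.einsum("fe,rej,j->rf", Ag, PK3[:, t], va)
                z_nr = np.einsum("rfF,rf->rF", P2K3[:, t].conj(), y_nr)
                q = np.einsum("rkj,k->rj", Pk1[:, t].conj(), vb)  # P(k1)^H v_b
                y_r = np.einsum("fe,rej,rj->rf", Ag, PK3[:, t], q)
                z_r = np.einsum("rfF,rf->rF", P2K3[:, t].conj(), y_r)
                x_nr = np.einsum("rsfF,rF->rsf", P2K4[:, t], z_nr)  # P2(K4) z
                x_r = np.einsum("rsfF,rF->rsf", P2K4[:, t], z_r)
                r_row = np.einsum("j,rji->ri", vb, Pk1[:, t])  # v_b' P(k1)
                left_nr = np.einsum("ri,rsei->rse", r_row, PK4[:, t].conj())
                left_r = np.einsum("i,rsei->rse", va, PK4[:, t].conj())
                ea_nr[t] -= np.einsum("rse,fe,rsf->s", left_nr, Ad, x_nr)
                ea_r[t] -= np.einsum("rse,fe,rsf->s", left_r, Ad, x_r)

    n_real = starts.size
    components = {
        key: {c: arr / n_real for c, arr in combos_d.items()}
        for key, combos_d in sums.items()
    }
    return FullResponseGrid(
        components=components, dt1=dt, dt3=dt, t2=n2 * dt / 1000.0,
        meta={"realizations": n_real, "n2": n2, "basis_mode": basis_mode},
    )
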