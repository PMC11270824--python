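"""Segment-level excitation-transfer kinetics.

The rate matrix ``K`` (ps^-1) acts on column vectors of segment populations,
``dp/dt = K p``: off-diagonal ``K[j, i] >= 0`` is the rate from segment i
into segment j and every column sums to zero (the diagonal is the negative
sum of the off-diagonal elements in its column).  The transfer map
``T(t2) = exp(K t2)`` gives the probability of finding the excitation on
segment j at waiting time t2 given that it started on segment i.

Detailed balance is imposed on a raw (e.g. high-temperature) rate matrix by
a pairwise, sum-preserving thermal correction: for every segment pair the
sum of the forward and backward rates is kept fixed while their ratio is
set to the Boltzmann factor of the (adjusted) segment-energy gap.  The
adjustment ``dE_S = kB T ln(N P_S / D_S)`` shifts segment energies so that
target equilibrium populations P are reproduced without changing the
effective rates; it vanishes when the rates were obtained in the
high-temperature limit (P_S = D_S / N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .units import KB_CM

__all__ = [
    "RateMatrix",
    "ThermoAdjustment",
    "TransferMap",
    "validate_rate_matrix",
    "thermal_correction",
    "delta_e",
    "transfer_map",
    "stationary_distribution",
    "stationary_components",
    "relaxation_eigenvalues",
    "interring_mode",
    "build_lh2_rate_fixture",
    "build_dimer_rate_fixture",
]


@dataclass
class RateMatrix:
    """Segment transfer-rate matrix (ps^-1), column-sum-zero convention."""

    K: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if not self.labels:
            self.labels = [f"S{i}" for i in range(self.K.shape[0])]
        if len(self.labels) != self.K.shape[0]:
            raise ValueError("label count must match matrix dimension")

    @property
    def n_segments(self) -> int:
        return self.K.shape[0]


@dataclass
class ThermoAdjustment:
    """Segment energies and optional target populations for the correction.

    ``energies`` are thermal segment energies E_S (cm^-1); ``counts`` the
    per-segment site numbers D_S.  If target equilibrium ``populations`` P
    are given, the energies are shifted by ``dE_S = kB T ln(N P_S / D_S)``
    before the Boltzmann factors are formed.  ``temperature=None`` selects
    the HT limit (no correction: uphill and downhill equally probable).
    """

    energies: np.ndarray
    counts: np.ndarray
    temperature: float | None
    populations: np.ndarray | None = None
    kB: float = KB_CM

    def __post_init__(self):
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        self.counts = np.atleast_1d(np.asarray(self.counts, dtype=int))
        if self.counts.shape != self.energies.shape:
            raise ValueError("counts and energies must align")
        if np.any(self.counts < 1):
            raise ValueError("segment site counts must be >= 1")
        if self.populations is not None:
            self.populations = np.atleast_1d(np.asarray(self.populations, dtype=float))
            if self.populations.shape != self.energies.shape:
                raise ValueError("populations and energies must align")
            if np.any(self.populations <= 0):
                raise ValueError("target populations must be positive")
            self.populations = self.populations / self.populations.sum()

    @property
    def adjusted_energies(self) -> np.ndarray:
        dE = delta_e(
            self.populations, self.counts, int(self.counts.sum()),
            self.temperature, kB=self.kB,
        ) if self.populations is not None else np.zeros_like(self.energies)
        return self.energies + dE


@dataclass
class TransferMap:
    """Column-stochastic segment occupation map ``T(t2) = exp(K t2)``."""

    T: np.ndarray
    t2: float  # ps
    labels: list[str] = field(default_factory=list)


def validate_rate_matrix(K, labels: list[str] | None = None) -> RateMatrix:
    """Normalize a rate matrix: reject negative off-diagonals, fix diagonal.

    The diagonal is recomputed as the negative sum of the off-diagonal
    elements in each column, enforcing population conservation.
    """
    K = np.array(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("rate matrix must be square")
    off = K - np.diag(np.diag(K))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be non-negative")
    off[off < 0] = 0.0
    Kn = off - np.diag(off.sum(axis=0))
    return RateMatrix(K=Kn, labels=labels or [])


def delta_e(
    populations,
    counts,
    n_total: int,
    temperature: float | None,
    kB: float = KB_CM,
) -> np.ndarray:
    """Segment-energy adjustments ``dE_S = kB T ln(N P_S / D_S)`` (cm^-1).

    Zero in the HT limit, and zero whenever P_S = D_S / N (the HT
    equilibrium populations).
    """
    counts = np.atleast_1d(np.asarray(counts, dtype=float))
    if temperature is None:
        return np.zeros_like(counts)
    P = np.atleast_1d(np.asarray(populations, dtype=float))
    if np.any(P <= 0):
        raise ValueError("populations must be positive")
    if np.any(counts < 1):
        raise ValueError("segment site counts must be >= 1")
    return kB * temperature * np.log(n_total * P / counts)


def thermal_correction(K_raw: RateMatrix, adjustment: ThermoAdjustment) -> RateMatrix:
    """Detailed-balance correction preserving every pairwise rate sum.

    For each pair (i, j) the corrected rates keep the raw sum
    ``s = k_raw(i->j) + k_raw(j->i)`` while their ratio is set to the
    Boltzmann factor of the degeneracy-weighted free-energy gap,

    ``k(i->j) / k(j->i) = (D_j / D_i) exp(-beta (E_j - E_i))``

    with ``E`` the (dE-adjusted) segment energies and ``D`` the segment
    site counts.  Segments of equal size and equal energy keep their raw
    rates; in the HT limit (beta = 0) uphill and downhill transfer between
    equal-size segments become equally probable, ``s / 2`` each, while the
    size factor ``D_j / D_i`` — the multichromophoric degeneracy of the
    acceptor — is retained, so a high-temperature rate matrix passes
    through the correction unchanged.
    """
    K = validate_rate_matrix(K_raw.K, labels=K_raw.labels).K
    n = K.shape[0]
    E = adjustment.adjusted_energies
    if E.size != n:
        raise ValueError("adjustment energies do not match the rate matrix")
    D = adjustment.counts
    beta = 0.0 if adjustment.temperature is None else 1.0 / (
        adjustment.kB * adjustment.temperature
    )
    out = np.zeros_like(K)
    for i in range(n):
        for j in range(i + 1, n):
            s = K[j, i] + K[i, j]
            if s == 0.0:
                continue
            g = E[j] - E[i]
            q = (D[i] / D[j]) * np.exp(beta * g)
            fwd = s / (1.0 + q)  # i -> j
            out[j, i] = fwd
            out[i, j] = s - fwd
    return validate_rate_matrix(out, labels=K_raw.labels)


def transfer_map(K: RateMatrix, t2: float) -> TransferMap:
    """Matrix exponential ``T(t2) = exp(K t2)``, t2 in ps.

    Computed by eigendecomposition, falling back to scaling-and-squaring
    (``scipy.linalg.expm``) when the eigenbasis is ill-conditioned.
    """
    if t2 < 0:
        raise ValueError("waiting time t2 must be >= 0")
    A = K.K * float(t2)
    w, V = np.linalg.eig(A)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        T = (V * np.exp(w)) @ np.linalg.inv(V)
    else:
        T = scipy.linalg.expm(A)
    T = np.real_if_close(T, tol=1e6)
    T = np.asarray(T, dtype=float)
    np.clip(T, 0.0, 1.0, out=T)
    T /= T.sum(axis=0, keepdims=True)
    return TransferMap(T=T, t2=float(t2), labels=K.labels)


def _components(K: np.ndarray) -> list[np.ndarray]:
    from scipy.sparse.csgraph import connected_components

    adj = (np.abs(K - np.diag(np.diag(K))) > 0).astype(int)
    n_comp, label = connected_components(adj, directed=False)
    return [np.flatnonzero(label == c) for c in range(n_comp)]


def stationary_components(K: RateMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per connected component: (segment indices, stationary distribution)."""
    out = []
    for idx in _components(K.K):
        sub = RateMatrix(K.K[np.ix_(idx, idx)], labels=[K.labels[i] for i in idx])
        out.append((idx, stationary_distribution(sub)))
    return out


def stationary_distribution(K: RateMatrix) -> np.ndarray:
    """Non-negative null vector of K normalized to unit sum.

    Requires an irreducible rate matrix (one connected component); use
    :func:`stationary_components` otherwise.
    """
    comps = _components(K.K)
    if len(comps) > 1:
        raise ValueError(
            "rate matrix is reducible; use stationary_components for "
            "per-component distributions"
        )
    w, V = np.linalg.eig(K.K)
    i = int(np.argmin(np.abs(w)))
    p = np.real(V[:, i])
    if p.sum() < 0:
        p = -p
    p[np.abs(p) < 1e-14] = 0.0
    if np.any(p < -1e-10):
        raise ValueError("null vector is not sign-definite; invalid rate matrix")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def relaxation_eigenvalues(K: RateMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Sorted decay constants (ps^-1) and matching eigenvector columns.

    The decay constants are the negated eigenvalues of K, sorted ascending;
    an irreducible K has exactly one zero mode (population conservation).
    """
    w, V = np.linalg.eig(K.K)
    decays = -np.real(w)
    order = np.argsort(decays)
    decays = decays[order]
    V = np.real(V[:, order])
    decays[np.abs(decays) < 1e-12] = 0.0
    return decays, V


def interring_mode(
    K: RateMatrix, group: np.ndarray, tol: float = 1e-9
) -> tuple[float, np.ndarray]:
    """Decay constant of the collective mode separating ``group`` vs rest.

    Identified as the eigenvector whose components have a uniform sign on
    all segments outside ``group`` and the opposite sign on ``group``
    (e.g. all B800 segments against the B850 segment).
    """
    group = np.asarray(group, dtype=int)
    rest = np.setdiff1d(np.arange(K.n_segments), group)
    decays, V = relaxation_eigenvalues(K)
    for k in range(K.n_segments):
        v = V[:, k]
        a, b = v[group], v[rest]
        if np.all(a > tol) and np.all(b < -tol):
            return float(decays[k]), v
        if np.all(a < -tol) and np.all(b > tol):
            return float(decays[k]), v
    raise ValueError("no eigenvector with the requested sign structure found")


def build_lh2_rate_fixture(regime: str = "HT") -> RateMatrix:
    """Ten-segment LH2 rate matrix from the reported elementary rates.

    Segment 0 is the B850 ring; segments 1..9 are the nine B800
    chromophores arranged on a ring with nearest-neighbour exchange at
    1.83 ps^-1 in each direction.  Each B800 transfers to B850 at
    0.775 ps^-1 (HT) or 1.48 ps^-1 (RT); the back transfer per B800 is
    0.0431 ps^-1 (HT) or 1.29e-3 ps^-1 (RT).
    """
    if regime == "HT":
        fwd, bwd = 0.775, 0.0431
    elif regime == "RT":
        fwd, bwd = 1.48, 1.29e-3
    else:
        raise ValueError(f"unknown regime {regime!r}")
    nn = 1.83
    n = 10
    K = np.zeros((n, n))
    for b in range(1, 10):
        K[0, b] = fwd          # B800_b -> B850
        K[b, 0] = bwd          # B850 -> B800_b
        left = 1 + (b - 1 - 1) % 9
        right = 1 + (b - 1 + 1) % 9
        K[left, b] = nn
        K[right, b] = nn
    labels = ["B850"] + [f"B800_{i}" for i in range(1, 10)]
    return validate_rate_matrix(K, labels=labels)


def build_dimer_rate_fixture(
    regime: str = "HT",
    total_rate: float = 0.1,
    gap: float = 500.0,
    temperature: float = 300.0,
) -> RateMatrix:
    """Synthetic 2x2 rate matrix for the double-segment dimer.

    Phenomenological stand-in rates (the benchmark's own transfer rates are
    not tabulated): the forward+backward sum is ``total_rate`` (ps^-1).  In
    the HT regime both directions are equal; in the RT regime the pair is
    thermally corrected for the segment-energy ``gap`` (cm^-1) at
    ``temperature``, making downhill transfer more than ten times faster
    than uphill.  Segment 0 is the low-energy site.
    """
    half = total_rate / 2.0
    K = validate_rate_matrix([[0.0, half], [half, 0.0]], labels=["low", "high"])
    if regime == "HT":
        return K
    if regime != "RT":
        raise ValueError(f"unknown regime {regime!r}")
    adj = ThermoAdjustment(
        energies=np.array([0.0, gap]), counts=np.array([1, 1]),
        temperature=temperature,
    )
    return thermal_correction(K, adj)
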