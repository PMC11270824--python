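"""Assembly of coarse-grained 2D spectra from doorway/window tables.

The response for one pathway (rephasing or nonrephasing) and polarization
scheme is the segment- and Cartesian-contracted doorway-transfer-window
product

``R(t1, t3; t2) = sum_d sum_ij sum_abgd A_abgd W^d_{j,gd}(t3) T_ji(t2)
D_{i,ab}(t1)``

where ``A`` is the isotropic four-point orientational average connecting the
molecular frame to the lab polarization sequence (21 of the 81 Cartesian
components are nonzero), and ``T`` the waiting-time transfer map.  Double
Fourier transforms over the coherence times (with the rephasing w1 sign
flipped so both pathways share a positive frequency axis) give the
absorptive spectrum as the real part of the pathway sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .kinetics import TransferMap
from .units import C_CM_FS

__all__ = [
    "PolarizationWeights",
    "ResponseGrid",
    "Spectrum2D",
    "orientational_weights",
    "orientational_weights_quadrature",
    "orientational_weights_sampled",
    "isotropic_contraction",
    "assemble_response",
    "spectrum_2d",
    "integrate_box",
    "cross_peak_kinetics",
    "CrossPeakFit",
    "anisotropy",
]

DIAGRAMS = ("GB", "SE", "EA")

_LAB_SEQUENCES = {
    # pulse polarizations e1, e2 (pump pair) and e3, e4 (probe pair)
    "parallel": (2, 2, 2, 2),  # ZZZZ
    "perpendicular": (2, 2, 0, 0),  # ZZXX
}


@dataclass
class PolarizationWeights:
    """Isotropic-average weight tensor ``A[a, b, g, d]`` for one scheme."""

    A: np.ndarray
    scheme: str

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(np.abs(self.A) > 1e-15))


def orientational_weights(scheme: str) -> PolarizationWeights:
    """Closed-form isotropic four-point orientational average.

    ``parallel`` is the all-parallel lab sequence (ZZZZ), ``perpendicular``
    the crossed pump/probe sequence (ZZXX).  Both schemes have exactly 21
    nonzero Cartesian components.
    """
    if scheme not in _LAB_SEQUENCES:
        raise ValueError(f"unknown polarization scheme {scheme!r}")
    d = np.eye(3)
    dd1 = np.einsum("ab,gd->abgd", d, d)  # delta_ab delta_gd
    dd2 = np.einsum("ag,bd->abgd", d, d)
    dd3 = np.einsum("ad,bg->abgd", d, d)
    e = [np.eye(3)[i] for i in _LAB_SEQUENCES[scheme]]
    c12, c13, c14 = e[0] @ e[1], e[0] @ e[2], e[0] @ e[3]
    c34, c24, c23 = e[2] @ e[3], e[1] @ e[3], e[1] @ e[2]
    A = (
        c12 * c34 * (4 * dd1 - dd2 - dd3)
        + c13 * c24 * (4 * dd2 - dd1 - dd3)
        + c14 * c23 * (4 * dd3 - dd1 - dd2)
    ) / 30.0
    return PolarizationWeights(A=A, scheme=scheme)


def _lab_vectors(scheme: str) -> list[np.ndarray]:
    return [np.eye(3)[i] for i in _LAB_SEQUENCES[scheme]]


def orientational_weights_quadrature(
    scheme: str, n_theta: int = 8, n_angle: int = 8
) -> PolarizationWeights:
    """Exact SO(3) average of the weight tensor by numerical quadrature.

    Averages the product of the four lab polarization vectors rotated into
    the molecular frame over the rotation group, using Gauss-Legendre nodes
    in cos(theta) and trapezoid nodes in the two periodic Euler angles.
    Degree-4 polynomials are integrated exactly for ``n_theta >= 3`` and
    ``n_angle >= 5``; the result is an independent check of
    :func:`orientational_weights`.
    """
    if scheme not in _LAB_SEQUENCES:
        raise ValueError(f"unknown polarization scheme {scheme!r}")
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = 2 * np.pi * np.arange(n_angle) / n_angle
    psi = 2 * np.pi * np.arange(n_angle) / n_angle

    th, ph, ps = np.meshgrid(theta, phi, psi, indexing="ij")
    wt = np.einsum("i,j,k->ijk", wx, np.ones(n_angle), np.ones(n_angle))
    wt = (wt / wt.sum()).ravel()
    ct, st = np.cos(th).ravel(), np.sin(th).ravel()
    cph, sph = np.cos(ph).ravel(), np.sin(ph).ravel()
    cps, sps = np.cos(ps).ravel(), np.sin(ps).ravel()
    # z-y-z Euler rotation matrices, shape (M, 3, 3)
    M = np.empty((ct.size, 3, 3))
    M[:, 0, 0] = cph * ct * cps - sph * sps
    M[:, 0, 1] = -cph * ct * sps - sph * cps
    M[:, 0, 2] = cph * st
    M[:, 1, 0] = sph * ct * cps + cph * sps
    M[:, 1, 1] = -sph * ct * sps + cph * cps
    M[:, 1, 2] = sph * st
    M[:, 2, 0] = -st * cps
    M[:, 2, 1] = st * sps
    M[:, 2, 2] = ct
    vecs = [np.einsum("mja,j->ma", M, e) for e in _lab_vectors(scheme)]
    A = np.einsum("m,ma,mb,mg,md->abgd", wt, *vecs)
    A[np.abs(A) < 1e-14] = 0.0
    return PolarizationWeights(A=A, scheme=scheme)


def orientational_weights_sampled(
    scheme: str, n_samples: int = 200_000, seed: int = 0
) -> PolarizationWeights:
    """Monte-Carlo random-rotation estimate of the weight tensor.

    Convergence is ~1/sqrt(n_samples); useful as a statistical sanity check
    against the closed form at moderate precision.
    """
    from scipy.spatial.transform import Rotation

    if scheme not in _LAB_SEQUENCES:
        raise ValueError(f"unknown polarization scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    M = Rotation.random(n_samples, random_state=rng).as_matrix()
    vecs = [np.einsum("mja,j->ma", M, e) for e in _lab_vectors(scheme)]
    A = np.einsum("ma,mb,mg,md->abgd", *vecs) / n_samples
    return PolarizationWeights(A=A, scheme=scheme)


def isotropic_contraction(weights: PolarizationWeights, mus: list[np.ndarray]) -> float:
    """Contract the weight tensor with four molecular-frame dipoles."""
    m1, m2, m3, m4 = mus
    return float(np.einsum("abgd,a,b,g,d->", weights.A, m1, m2, m3, m4))


@dataclass
class ResponseGrid:
    """Complex response R(t1, t3) per diagram for one pathway at fixed t2."""

    diagrams: dict
    pathway: str
    dt1: float
    dt3: float
    t2: float  # ps
    scheme: str

    def total(self, diagrams: tuple = DIAGRAMS) -> np.ndarray:
        return sum(self.diagrams[d] for d in diagrams if d in self.diagrams)


def assemble_response(
    doorways: dict,
    windows: dict,
    transfer: TransferMap,
    weights: PolarizationWeights,
    pathway: str = "nonrephasing",
    gb_kernel: str = "transfer",
) -> ResponseGrid:
    """Contract doorway, transfer and window tables into R(t1, t3).

    ``doorways`` maps segment id -> :class:`DoorwayTable` (of the requested
    pathway); ``windows`` maps diagram -> {segment id -> WindowTable}.
    ``gb_kernel`` selects whether the GB diagram propagates population with
    the transfer map (``"transfer"``, the literal summation) or keeps the
    identity kernel (``"identity"``, reflecting that the ground state does
    not transfer).
    """
    if gb_kernel not in ("transfer", "identity"):
        raise ValueError(f"unknown gb_kernel {gb_kernel!r}")
    seg_ids = sorted(doorways)
    n_seg = len(seg_ids)
    if transfer.T.shape != (n_seg, n_seg):
        raise ValueError("transfer map dimension does not match segment count")
    d0 = doorways[seg_ids[0]]
    if any(doorways[s].pathway != pathway for s in seg_ids):
        raise ValueError(f"doorway tables are not all {pathway!r}")
    nt1 = d0.values.shape[0]
    out = {}
    ident = np.eye(n_seg)
    for diag, wtabs in windows.items():
        if sorted(wtabs) != seg_ids:
            raise ValueError(f"window segment ids for {diag} do not match doorways")
        nt3 = wtabs[seg_ids[0]].values.shape[0]
        T = ident if (diag == "GB" and gb_kernel == "identity") else transfer.T
        R = np.zeros((nt1, nt3), dtype=complex)
        for i, si in enumerate(seg_ids):
            D = doorways[si].values
            if D.shape[0] != nt1 or abs(doorways[si].dt - d0.dt) > 1e-12:
                raise ValueError("doorway grids differ between segments")
            for j, sj in enumerate(seg_ids):
                W = wtabs[sj].values
                if W.shape[0] != nt3:
                    raise ValueError("window grids differ between segments")
                if T[j, i] == 0.0:
                    continue
                R += T[j, i] * np.einsum("abgd,tab,sgd->ts", weights.A, D, W)
        out[diag] = R
    dt3 = windows[next(iter(windows))][seg_ids[0]].dt
    return ResponseGrid(
        diagrams=out, pathway=pathway, dt1=d0.dt, dt3=dt3,
        t2=float(transfer.t2), scheme=weights.scheme,
    )


@dataclass
class Spectrum2D:
    """Absorptive 2D spectrum over (w1, w3), both in cm^-1."""

    absorptive: np.ndarray  # real, shape (n_w1, n_w3)
    w1: np.ndarray
    w3: np.ndarray
    components: dict = field(default_factory=dict)  # pathway -> complex array
    meta: dict = field(default_factory=dict)

    def normalized(self) -> "Spectrum2D":
        """Copy scaled to a unit maximum absolute amplitude."""
        peak = np.max(np.abs(self.absorptive))
        scale = 1.0 / peak if peak > 0 else 1.0
        return Spectrum2D(
            absorptive=self.absorptive * scale,
            w1=self.w1,
            w3=self.w3,
            components={k: v * scale for k, v in self.components.items()},
            meta={**self.meta, "normalization": peak},
        )


def _apodization(n: int, kind: str) -> np.ndarray:
    if kind == "cos2":
        t = np.arange(n)
        return np.cos(np.pi * t / (2.0 * (n - 1))) ** 2 if n > 1 else np.ones(1)
    if kind in ("none", None):
        return np.ones(n)
    raise ValueError(f"unknown apodization {kind!r}")


def _transform(R: np.ndarray, n_pad1: int, n_pad3: int, sign1: int) -> np.ndarray:
    """2D DFT with e^{+i w3 t3} along t3 and e^{sign1 * i w1 t1} along t1."""
    if sign1 > 0:
        F = np.fft.ifft(R, n=n_pad1, axis=0) * n_pad1
    else:
        F = np.fft.fft(R, n=n_pad1, axis=0)
    F = np.fft.ifft(F, n=n_pad3, axis=1) * n_pad3
    return np.fft.fftshift(F, axes=(0, 1))


def spectrum_2d(
    nonrephasing: ResponseGrid,
    rephasing: ResponseGrid,
    apodization: str = "cos2",
    zero_pad: int = 4,
    diagrams: tuple = DIAGRAMS,
    rotating_frame: float = 0.0,
) -> Spectrum2D:
    """Double Fourier transform of the two pathways to the (w1, w3) plane.

    The rephasing pathway is transformed with the opposite w1 sign so both
    pathways appear at positive excitation frequency; the absorptive
    spectrum is the real part of their sum.  First time points are
    half-weighted and a squared-cosine taper is applied before zero padding.

    ``rotating_frame`` (cm^-1) demodulates the response at a carrier
    frequency before transforming and offsets the frequency axes
    accordingly; electronic transitions above the sampling Nyquist
    frequency 1/(2 c dt) alias unless a nearby carrier is chosen.
    """
    if abs(nonrephasing.dt1 - rephasing.dt1) > 1e-12 or abs(
        nonrephasing.dt3 - rephasing.dt3
    ) > 1e-12:
        raise ValueError("pathway grids differ")
    R_nr = nonrephasing.total(diagrams)
    R_r = rephasing.total(diagrams)
    if R_nr.shape != R_r.shape:
        raise ValueError("pathway grids differ in shape")
    nt1, nt3 = R_nr.shape
    a1 = _apodization(nt1, apodization).copy()
    a3 = _apodization(nt3, apodization).copy()
    a1[0] *= 0.5
    a3[0] *= 0.5
    taper = a1[:, None] * a3[None, :]
    if rotating_frame != 0.0:
        from .units import TWO_PI_C

        t1 = np.arange(nt1) * nonrephasing.dt1
        t3 = np.arange(nt3) * nonrephasing.dt3
        mod3 = np.exp(1j * TWO_PI_C * rotating_frame * t3)[None, :]
        mod1 = np.exp(1j * TWO_PI_C * rotating_frame * t1)[:, None]
        R_nr = R_nr * mod1 * mod3
        R_r = R_r * mod1.conj() * mod3
    n1, n3 = zero_pad * nt1, zero_pad * nt3
    S_nr = _transform(R_nr * taper, n1, n3, sign1=+1)
    S_r = _transform(R_r * taper, n1, n3, sign1=-1)
    w1 = rotating_frame + np.fft.fftshift(np.fft.fftfreq(n1, d=nonrephasing.dt1)) / C_CM_FS
    w3 = rotating_frame + np.fft.fftshift(np.fft.fftfreq(n3, d=nonrephasing.dt3)) / C_CM_FS
    return Spectrum2D(
        absorptive=np.real(S_nr + S_r),
        w1=w1,
        w3=w3,
        components={"nonrephasing": S_nr, "rephasing": S_r},
        meta={
            "apodization": apodization,
            "zero_pad": zero_pad,
            "t2": nonrephasing.t2,
            "scheme": nonrephasing.scheme,
            "diagrams": tuple(diagrams),
            "rotating_frame": rotating_frame,
        },
    )


def integrate_box(
    spectrum: Spectrum2D, w1_range: tuple, w3_range: tuple
) -> float:
    """Mean absorptive amplitude inside a rectangular (w1, w3) box."""
    m1 = (spectrum.w1 >= w1_range[0]) & (spectrum.w1 <= w1_range[1])
    m3 = (spectrum.w3 >= w3_range[0]) & (spectrum.w3 <= w3_range[1])
    if not (m1.any() and m3.any()):
        raise ValueError("integration box does not overlap the frequency grid")
    return float(spectrum.absorptive[np.ix_(m1, m3)].mean())


@dataclass
class CrossPeakFit:
    """Single-exponential rise fit ``A (1 - exp(-k t2)) + C`` of a peak."""

    t2: np.ndarray
    intensity: np.ndarray
    rate: float  # ps^-1
    amplitude: float
    offset: float
    rms_residual: float
    degenerate: bool = False


def cross_peak_kinetics(
    t2_values: np.ndarray,
    spectra: list,
    w1_range: tuple,
    w3_range: tuple,
) -> CrossPeakFit:
    """Box-integrated cross-peak intensity versus waiting time, with fit.

    Requires at least three waiting times.  A constant series is reported
    as degenerate with zero amplitude and rate.
    """
    t2 = np.asarray(t2_values, dtype=float)
    if t2.size < 3 or len(spectra) != t2.size:
        raise ValueError("need >= 3 waiting times with matching spectra")
    I = np.array([integrate_box(s, w1_range, w3_range) for s in spectra])
    scale = max(np.max(np.abs(I)), 1e-300)
    if np.ptp(I) < 1e-10 * scale:
        return CrossPeakFit(
            t2=t2, intensity=I, rate=0.0, amplitude=0.0,
            offset=float(I.mean()), rms_residual=float(I.std()), degenerate=True,
        )

    def rise(t, A, k, C):
        return A * (1.0 - np.exp(-k * t)) + C

    span = max(t2.max() - t2.min(), 1e-12)
    p0 = [I[-1] - I[0], 2.0 / span, I[0]]
    popt, _ = curve_fit(rise, t2, I, p0=p0, maxfev=20000)
    resid = I - rise(t2, *popt)
    return CrossPeakFit(
        t2=t2, intensity=I, rate=float(abs(popt[1])), amplitude=float(popt[0]),
        offset=float(popt[2]), rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def anisotropy(
    I_parallel: np.ndarray, I_perpendicular: np.ndarray, rel_tol: float = 1e-12
) -> np.ndarray:
    """Polarization anisotropy ``r = (Ipar - Iperp) / (Ipar + 2 Iperp)``.

    Points where the denominator vanishes (relative to the series scale)
    are flagged as NaN.
    """
    Ipar = np.asarray(I_parallel, dtype=float)
    Iperp = np.asarray(I_perpendicular, dtype=float)
    if Ipar.shape != Iperp.shape:
        raise ValueError("intensity series must share one t2 grid")
    den = Ipar + 2.0 * Iperp
    scale = max(np.max(np.abs(Ipar)), np.max(np.abs(Iperp)), 1e-300)
    out = np.full(Ipar.shape, np.nan)
    ok = np.abs(den) > rel_tol * scale
    out[ok] = (Ipar[ok] - Iperp[ok]) / den[ok]
    return out
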