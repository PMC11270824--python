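"""Plain-text file formats for system models and rate matrices.

The model file is a commented key/value header followed by one ``site`` line
per chromophore (mean energy, fluctuation magnitude, correlation time,
dipole components, segment id) and a full coupling-matrix block.  Units are
annotated in the header: energies/couplings in cm^-1, times in fs, rates in
ps^-1.  Rate-matrix files are whitespace-delimited square matrices with a
segment-label header row, column-sum-zero convention validated on load.
"""

from __future__ import annotations

import numpy as np

from .kinetics import RateMatrix, validate_rate_matrix
from .model import (
    BathParams,
    CouplingMatrix,
    DipoleSet,
    Segmentation,
    SystemModel,
)

__all__ = ["save_model", "load_model", "save_rate_matrix", "load_rate_matrix"]


class ModelFileError(ValueError):
    """Malformed model or rate file, with the offending line number."""


def save_model(system: SystemModel, path: str) -> None:
    """Write a system model to the structured text format."""
    lines = [
        "# cg2des model file v1",
        "# units: energies/couplings cm-1, correlation times fs, dipoles arbitrary",
        f"temperature {'HT' if system.is_ht else system.temperature}",
        f"nsites {system.n_sites}",
        "# site <index> <mean> <sigma> <lambda_inv> <mux> <muy> <muz> <segment>",
    ]
    for n in range(system.n_sites):
        mu = system.dipoles.mu_ge[n]
        lines.append(
            f"site {n} {system.means[n]:.10g} {system.bath.sigma[n]:.10g} "
            f"{system.bath.lambda_inv[n]:.10g} {mu[0]:.10g} {mu[1]:.10g} "
            f"{mu[2]:.10g} {system.segmentation.assignment[n]}"
        )
    lines.append("couplings")
    for row in system.J.J:
        lines.append(" ".join(f"{x:.10g}" for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path: str) -> SystemModel:
    """Parse a model file; errors name the offending line and field."""
    with open(path) as fh:
        raw = fh.readlines()

    temperature: float | None = 300.0
    nsites = None
    site_rows: dict[int, tuple] = {}
    coupling_rows: list[list[float]] = []
    in_couplings = False
    for lineno, line in enumerate(raw, start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        tokens = text.split()
        if in_couplings:
            try:
                coupling_rows.append([float(x) for x in tokens])
            except ValueError as exc:
                raise ModelFileError(f"line {lineno}: bad coupling value ({exc})")
            continue
        key = tokens[0].lower()
        if key == "temperature":
            if len(tokens) != 2:
                raise ModelFileError(f"line {lineno}: temperature needs one value")
            temperature = None if tokens[1].upper() == "HT" else _num(tokens[1], lineno)
        elif key == "nsites":
            nsites = int(_num(tokens[1], lineno))
        elif key == "site":
            if len(tokens) != 9:
                raise ModelFileError(
                    f"line {lineno}: site lines need 8 fields "
                    "(index mean sigma lambda_inv mux muy muz segment)"
                )
            idx = int(_num(tokens[1], lineno))
            vals = [_num(t, lineno) for t in tokens[2:8]]
            site_rows[idx] = (*vals, int(_num(tokens[8], lineno)))
        elif key == "couplings":
            in_couplings = True
        else:
            raise ModelFileError(f"line {lineno}: unknown directive {tokens[0]!r}")

    if nsites is None:
        nsites = len(site_rows)
    missing = [n for n in range(nsites) if n not in site_rows]
    if missing:
        raise ModelFileError(f"missing site definitions for sites {missing}")
    if len(site_rows) != nsites:
        raise ModelFileError(
            f"expected {nsites} sites, found {len(site_rows)}"
        )
    means = np.array([site_rows[n][0] for n in range(nsites)])
    sigma = np.array([site_rows[n][1] for n in range(nsites)])
    lam = np.array([site_rows[n][2] for n in range(nsites)])
    mu = np.array([site_rows[n][3:6] for n in range(nsites)])
    assignment = np.array([site_rows[n][6] for n in range(nsites)], dtype=int)
    J = np.array(coupling_rows, dtype=float)
    if J.shape != (nsites, nsites):
        raise ModelFileError(
            f"coupling block has shape {J.shape}, expected ({nsites}, {nsites})"
        )
    return SystemModel(
        means=means,
        bath=BathParams(sigma=sigma, lambda_inv=lam),
        J=CouplingMatrix(J),
        dipoles=DipoleSet(mu),
        segmentation=Segmentation(assignment),
        temperature=temperature,
    )


def _num(token: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ModelFileError(f"line {lineno}: expected a number, got {token!r}")


def save_rate_matrix(K: RateMatrix, path: str) -> None:
    """Write a rate matrix with a label header (ps^-1, column-sum zero)."""
    lines = [
        "# cg2des segment rate matrix, units ps^-1",
        "# K[j, i] is the rate from segment i into segment j; columns sum to 0",
        "labels " + " ".join(K.labels),
    ]
    for row in K.K:
        lines.append(" ".join(f"{x:.10g}" for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_rate_matrix(path: str) -> RateMatrix:
    """Load and validate a rate-matrix file (column-sum convention)."""
    labels = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            tokens = text.split()
            if tokens[0].lower() == "labels":
                labels = tokens[1:]
                continue
            try:
                rows.append([float(x) for x in tokens])
            except ValueError as exc:
                raise ModelFileError(f"line {lineno}: bad rate value ({exc})")
    K = np.array(rows, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ModelFileError(f"rate matrix must be square, got shape {K.shape}")
    diag_check = -np.sum(K - np.diag(np.diag(K)), axis=0)
    if not np.allclose(np.diag(K), diag_check, atol=1e-6 * max(1.0, np.abs(K).max())):
        raise ModelFileError(
            "diagonal is not the negative column sum of the off-diagonal rates"
        )
    return validate_rate_matrix(K, labels=labels)
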