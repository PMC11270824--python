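"""End-to-end run configuration, table caching and pipeline driver.

The expensive stage — doorway and window tables — depends only on the
system, the coherence grids and the realization settings, not on the
waiting time.  Tables are therefore cached on disk under a configuration
hash, and additional waiting times reuse them: assembling a spectrum for a
new t2 is a cheap contraction with a fresh transfer map.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .doorway_window import (
    DoorwayTable,
    WindowTable,
    doorway,
    equilibrium_density,
    segment_energy,
    time_grid,
    window_ea,
    window_gb,
    window_se,
)
from .kinetics import RateMatrix, build_dimer_rate_fixture, build_lh2_rate_fixture, transfer_map, TransferMap
from .model import SystemModel, generate_ou_trajectory, make_dimer_fixture, make_two_ring_fixture
from .modelio import load_model, load_rate_matrix
from .propagation import build_two_exciton_basis
from .spectra import (
    Spectrum2D,
    assemble_response,
    cross_peak_kinetics,
    orientational_weights,
    spectrum_2d,
)

logger = logging.getLogger("cg2des")

__all__ = [
    "RunConfig",
    "Tables",
    "compute_tables",
    "save_tables",
    "load_tables",
    "spectrum_for_t2",
    "run_pipeline",
    "resolve_model",
    "resolve_rates",
]


@dataclass
class RunConfig:
    """All knobs of one coarse-grained 2DES run.

    ``model`` / ``rates`` are either file paths or fixture specs
    (``dimer:single_segment``, ``dimer:double_segment``, ``two_ring``;
    ``lh2:HT``, ``lh2:RT``, ``dimer:HT``, ``dimer:RT``).  ``temperature``
    is ``"model"`` (use the model file), ``"HT"`` or a value in kelvin.
    """

    model: str = "dimer:single_segment"
    rates: str | None = None
    outdir: str = "cg2des_out"
    nt1: int = 128
    nt3: int = 128
    dt: float = 2.0
    t2_list: list = field(default_factory=lambda: [0.0])
    temperature: object = "model"
    realizations: int = 200
    spacing: int | None = None
    seed: int = 1
    apodization: str = "cos2"
    zero_pad: int = 4
    gb_kernel: str = "transfer"
    basis_mode: str = "strict"
    anharmonicity: float = 0.0
    schemes: list = field(default_factory=lambda: ["parallel"])
    kinetics_box: list | None = None  # [w1min, w1max, w3min, w3max]
    anisotropy_box: list | None = None
    spectrum_window: list | None = None  # [wmin, wmax] crop for text output

    def __post_init__(self):
        if self.nt1 < 2 or self.nt3 < 2:
            raise ValueError("coherence grids need at least 2 points")
        if any(t2 < 0 for t2 in self.t2_list):
            raise ValueError("waiting times must be >= 0")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def table_hash(self) -> str:
        """Hash over every field the doorway/window tables depend on."""
        keys = (
            "model", "nt1", "nt3", "dt", "temperature", "realizations",
            "spacing", "seed", "basis_mode", "anharmonicity",
        )
        payload = json.dumps({k: getattr(self, k) for k in keys}, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


def resolve_model(spec: str, temperature) -> SystemModel:
    """Build a system from a fixture spec or load it from a file."""
    if spec.startswith("dimer:"):
        system = make_dimer_fixture(spec.split(":", 1)[1])
    elif spec == "two_ring":
        system = make_two_ring_fixture()
    else:
        system = load_model(spec)
    if temperature == "HT":
        system.temperature = None
    elif temperature != "model":
        system.temperature = float(temperature)
    return system


def resolve_rates(spec: str | None, n_segments: int) -> RateMatrix | None:
    """Build a rate matrix from a fixture spec or load it from a file."""
    if spec is None:
        return None
    if spec.startswith("lh2:"):
        K = build_lh2_rate_fixture(spec.split(":", 1)[1])
    elif spec.startswith("dimer:"):
        K = build_dimer_rate_fixture(spec.split(":", 1)[1])
    else:
        K = load_rate_matrix(spec)
    if K.n_segments != n_segments:
        raise ValueError(
            f"rate matrix has {K.n_segments} segments, model has {n_segments}"
        )
    return K


@dataclass
class Tables:
    """Cached per-segment doorway/window tables plus segment metadata."""

    doorways: dict  # pathway -> {segment id -> DoorwayTable}
    windows: dict  # diagram -> {segment id -> WindowTable}
    energies: dict  # segment id -> cm^-1
    config_hash: str
    dt: float

    @property
    def segment_ids(self) -> list:
        return sorted(self.doorways["nonrephasing"])


def compute_tables(system: SystemModel, config: RunConfig) -> Tables:
    """Compute all doorway and window tables for one run configuration.

    Doorway and window ensembles use statistically independent trajectory
    stretches (separate seeds spawned from the master seed), reflecting the
    assumption that the waiting time is long compared to the bath memory.
    """
    ss = np.random.SeedSequence(config.seed)
    seed_d, seed_w, seed_rho = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(3)]
    t1 = time_grid(config.nt1, config.dt)
    t3 = time_grid(config.nt3, config.dt)
    seg_ids = [int(s) for s in system.segmentation.segment_ids]

    # one moderate trajectory for equilibrium densities and segment energies
    rho_traj = generate_ou_trajectory(
        system.bath, system.means, n_frames=4096, dt=config.dt, seed=seed_rho
    )
    # shared doorway and window trajectories (generated once, reused by
    # every segment and diagram so the contractions stay mutually consistent)
    spacing_d = config.spacing if config.spacing is not None else config.nt1 - 1
    spacing_w = config.spacing if config.spacing is not None else config.nt3 - 1
    traj_d = generate_ou_trajectory(
        system.bath, system.means,
        spacing_d * (config.realizations - 1) + config.nt1, config.dt, seed_d,
    )
    traj_w = generate_ou_trajectory(
        system.bath, system.means,
        spacing_w * (config.realizations - 1) + config.nt3, config.dt, seed_w,
    )

    doorways = {"nonrephasing": {}, "rephasing": {}}
    windows = {"GB": {}, "SE": {}, "EA": {}}
    energies = {}
    for sid in seg_ids:
        t0 = time.perf_counter()
        dtab = doorway(
            system, sid, t1, config.realizations, seed_d,
            spacing=config.spacing, traj=traj_d,
        )
        doorways["nonrephasing"][sid] = dtab
        doorways["rephasing"][sid] = DoorwayTable(
            values=dtab.values.conj(), dt=dtab.dt, segment_id=sid,
            pathway="rephasing",
        )
        rho = equilibrium_density(
            rho_traj, system.J, system.segmentation, sid, system.temperature
        )
        energies[sid] = segment_energy(
            rho_traj, system.J, system.segmentation, sid, system.temperature
        ).value
        # one shared trajectory per segment for the three window diagrams
        windows["GB"][sid] = window_gb(
            system, sid, t3, config.realizations, seed_w,
            spacing=config.spacing, traj=traj_w,
        )
        windows["SE"][sid] = window_se(
            system, sid, rho, t3, config.realizations, seed_w,
            spacing=config.spacing, traj=traj_w,
        )
        d_seg = system.segmentation.sites_of(sid).size
        basis = build_two_exciton_basis(
            d_seg, mode=config.basis_mode, anharmonicity=config.anharmonicity
        )
        windows["EA"][sid] = window_ea(
            system, sid, rho, basis, t3, config.realizations, seed_w,
            spacing=config.spacing, traj=traj_w,
        )
        logger.info(
            "segment %s tables done in %.1f s", sid, time.perf_counter() - t0
        )
    return Tables(
        doorways=doorways, windows=windows, energies=energies,
        config_hash=config.table_hash(), dt=config.dt,
    )


def save_tables(tables: Tables, path: str) -> None:
    """Persist tables in a compressed array container with metadata."""
    arrays = {}
    for pathway, tabs in tables.doorways.items():
        for sid, tab in tabs.items():
            arrays[f"D_{pathway}_{sid}"] = tab.values
    for diagram, tabs in tables.windows.items():
        for sid, tab in tabs.items():
            arrays[f"W_{diagram}_{sid}"] = tab.values
    meta = {
        "config_hash": tables.config_hash,
        "dt": tables.dt,
        "energies": {str(k): v for k, v in tables.energies.items()},
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez_compressed(path, **arrays)


def load_tables(path: str) -> Tables:
    """Load tables written by :func:`save_tables`."""
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta_json"]))
    doorways: dict = {"nonrephasing": {}, "rephasing": {}}
    windows: dict = {"GB": {}, "SE": {}, "EA": {}}
    for key in data.files:
        if key.startswith("D_"):
            _, pathway, sid = key.split("_", 2)
            doorways[pathway][int(sid)] = DoorwayTable(
                values=data[key], dt=meta["dt"], segment_id=int(sid),
                pathway=pathway,
            )
        elif key.startswith("W_"):
            _, diagram, sid = key.split("_", 2)
            windows[diagram][int(sid)] = WindowTable(
                values=data[key], dt=meta["dt"], segment_id=int(sid),
                diagram=diagram,
            )
    return Tables(
        doorways=doorways, windows=windows,
        energies={int(k): v for k, v in meta["energies"].items()},
        config_hash=meta["config_hash"], dt=meta["dt"],
    )


def spectrum_for_t2(
    tables: Tables,
    K: RateMatrix | None,
    t2: float,
    scheme: str,
    config: RunConfig,
    rotating_frame: float = 0.0,
) -> Spectrum2D:
    """Assemble the absorptive spectrum at one waiting time (t2 in ps)."""
    n_seg = len(tables.segment_ids)
    if K is None:
        T = TransferMap(T=np.eye(n_seg), t2=float(t2))
    else:
        T = transfer_map(K, t2)
    weights = orientational_weights(scheme)
    grids = {}
    for pathway in ("nonrephasing", "rephasing"):
        grids[pathway] = assemble_response(
            tables.doorways[pathway], tables.windows, T, weights,
            pathway=pathway, gb_kernel=config.gb_kernel,
        )
    return spectrum_2d(
        grids["nonrephasing"], grids["rephasing"],
        apodization=config.apodization, zero_pad=config.zero_pad,
        rotating_frame=rotating_frame,
    )


def _write_spectrum_text(spec: Spectrum2D, path: Path, window) -> None:
    m1 = np.ones(spec.w1.size, dtype=bool)
    m3 = np.ones(spec.w3.size, dtype=bool)
    if window is not None:
        m1 = (spec.w1 >= window[0]) & (spec.w1 <= window[1])
        m3 = (spec.w3 >= window[0]) & (spec.w3 <= window[1])
    w1, w3 = spec.w1[m1], spec.w3[m3]
    block = spec.absorptive[np.ix_(m1, m3)]
    with open(path, "w") as fh:
        fh.write("# w1[cm-1] w3[cm-1] absorptive\n")
        for i, a in enumerate(w1):
            for j, b in enumerate(w3):
                fh.write(f"{a:.3f} {b:.3f} {block[i, j]:.8e}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run fixture/tables/transfer/spectra/kinetics stages; return artifacts.

    Deterministic given the config seed; doorway/window tables are cached in
    the output directory under the configuration hash and reused when only
    the waiting-time list changes.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict = {"log": str(log_path)}
    try:
        stage = "model"
        system = resolve_model(config.model, config.temperature)
        stage = "rates"
        K = resolve_rates(config.rates, system.segmentation.n_segments)
        stage = "tables"
        chash = config.table_hash()
        tables_path = out / f"tables_{chash}.npz"
        if tables_path.exists():
            tables = load_tables(tables_path)
            logger.info("reusing cached tables %s", tables_path.name)
            artifacts["tables_cached"] = True
        else:
            tables = compute_tables(system, config)
            save_tables(tables, tables_path)
            logger.info("computed tables -> %s", tables_path.name)
            artifacts["tables_cached"] = False
        artifacts["tables"] = str(tables_path)

        stage = "spectra"
        if config.spectrum_window is None:
            lo = float(system.means.min() - 1500.0)
            hi = float(system.means.max() + 1500.0)
            window = (lo, hi)
        else:
            window = tuple(config.spectrum_window)
        w_ref = float(system.means.mean())
        spectra: dict = {}
        for scheme in config.schemes:
            for t2 in config.t2_list:
                spec = spectrum_for_t2(
                    tables, K, t2, scheme, config, rotating_frame=w_ref
                )
                spectra[(scheme, t2)] = spec
                name = f"spectrum_{scheme}_t2_{t2:g}ps"
                _write_spectrum_text(spec.normalized(), out / f"{name}.txt", window)
                np.savez_compressed(
                    out / f"{name}.npz", absorptive=spec.absorptive,
                    w1=spec.w1, w3=spec.w3,
                    config_hash=np.array(chash),
                )
                artifacts.setdefault("spectra", []).append(str(out / f"{name}.txt"))

        stage = "kinetics"
        if config.kinetics_box is not None and len(config.t2_list) >= 3:
            b = config.kinetics_box
            scheme = config.schemes[0]
            fit = cross_peak_kinetics(
                np.array(config.t2_list),
                [spectra[(scheme, t2)] for t2 in config.t2_list],
                (b[0], b[1]), (b[2], b[3]),
            )
            fit_out = {
                "t2_ps": list(map(float, fit.t2)),
                "intensity": list(map(float, fit.intensity)),
                "rate_ps_inv": fit.rate,
                "amplitude": fit.amplitude,
                "offset": fit.offset,
                "rms_residual": fit.rms_residual,
                "degenerate": fit.degenerate,
                "config_hash": chash,
            }
            with open(out / "kinetics.json", "w") as fh:
                json.dump(fit_out, fh, indent=2)
            artifacts["kinetics"] = str(out / "kinetics.json")

        stage = "anisotropy"
        if (
            config.anisotropy_box is not None
            and "parallel" in config.schemes
            and "perpendicular" in config.schemes
        ):
            from .spectra import anisotropy, integrate_box

            b = config.anisotropy_box
            Ipar = np.array([
                integrate_box(spectra[("parallel", t2)], (b[0], b[1]), (b[2], b[3]))
                for t2 in config.t2_list
            ])
            Iperp = np.array([
                integrate_box(spectra[("perpendicular", t2)], (b[0], b[1]), (b[2], b[3]))
                for t2 in config.t2_list
            ])
            r = anisotropy(Ipar, Iperp)
            with open(out / "anisotropy.json", "w") as fh:
                json.dump(
                    {
                        "t2_ps": list(map(float, config.t2_list)),
                        "r": [None if np.isnan(x) else float(x) for x in r],
                        "config_hash": chash,
                    },
                    fh, indent=2,
                )
            artifacts["anisotropy"] = str(out / "anisotropy.json")

        stage = "manifest"
        with open(out / "run.json", "w") as fh:
            json.dump(
                {
                    "config": config.to_dict(),
                    "config_hash": chash,
                    "version": __version__,
                    "artifacts": artifacts,
                },
                fh, indent=2, default=str,
            )
        artifacts["manifest"] = str(out / "run.json")
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts
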