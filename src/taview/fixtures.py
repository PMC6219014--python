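"""Self-contained synthetic experiments: geometry, lead field, ground truth, ECG.

`make_experiment` produces everything a full inversion study needs with zero
downloads: a two-lobe heart in an ellipsoidal torso, the 8-channel lead
field and its coarse source reduction, a ground-truth TMP movie with an
atrium-first activation sequence (sinus-like: atrial stimulus at t=0,
ventricular stimulus after an AV delay), a clean 8-channel ECG generated
through a perturbed transfer matrix L + DeltaL*, and a noisy ECG at a stated
per-channel SNR.  Every random stage derives its seed from the bundle seed,
and the manifest records all of them, so a bundle is reproducible from its
manifest alone.

The ground-truth dynamics run directly on the coarse (reduced) source model
— the same resolution the inversion uses — so parameter-recovery studies are
well-posed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from . import io as ecg_io
from .forward import ECGRecord, project_to_electrodes
from .leadfield import (
    SourceReduction,
    TransferMatrix,
    TransferUncertainty,
    compute_transfer_matrix,
    reduce_sources,
    sample_transfer_perturbation,
)
from .mesh import (
    ATRIAL,
    VENTRICULAR,
    ElectrodeSet,
    TriSurfaceMesh,
    build_synthetic_heart,
    build_synthetic_torso,
    place_standard_electrodes,
    write_mesh,
)
from .rd import RDParams, StimulusSpec, TMPMovie, build_laplacian, coarsen_laplacian, simulate


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions of a synthetic experiment (defaults = the small preset)."""

    n_atrial_fine: int = 64
    n_ventricular_fine: int = 60
    n_torso: int = 200
    heart_scale_mm: float = 60.0
    torso_scale_mm: float = 300.0
    n_coarse: int = 20
    k: float = 8.0
    a: float = 0.15
    e: float = 0.01
    D_atrial: float = 50.0  # mm^2/ms, effective coarse-model conduction
    D_ventricular: float = 50.0
    dt_ms: float = 0.1
    t_end_ms: float = 600.0
    av_delay_ms: float = 120.0
    stim_duration_ms: float = 1.0
    stim_amplitude: float = 0.4
    obs_every: int = 20  # observation grid = every `obs_every` simulation steps
    process_noise_sd: float = 0.0  # optional model-error realization, per sqrt(ms)
    snr_db: float | None = 20.0  # None = noise off
    deltaL_rel_sd: float = 0.05  # DeltaL* sd relative to RMS |L| entry
    gain_mv: float = 1.0


@dataclasses.dataclass
class ExperimentBundle:
    """All artifacts of one synthetic experiment plus a reproducibility manifest."""

    config: ExperimentConfig
    seed: int
    heart: TriSurfaceMesh
    torso: TriSurfaceMesh
    electrodes: ElectrodeSet
    L_fine: TransferMatrix
    L_coarse: TransferMatrix
    reduction: SourceReduction
    laplacian_coarse: np.ndarray
    params: RDParams
    stimuli: tuple[StimulusSpec, ...]
    movie: TMPMovie  # full-rate ground truth on coarse nodes
    movie_obs: TMPMovie  # ground truth on the observation grid
    ecg_clean: ECGRecord  # 8 channels, observation grid, through L + DeltaL*
    ecg_noisy: ECGRecord
    deltaL_true: np.ndarray
    noise_var: np.ndarray  # per-channel measurement-noise variance
    manifest: dict

    @property
    def fs(self) -> float:
        return self.ecg_clean.fs

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "meshes").mkdir(parents=True, exist_ok=True)
        (out / "ecg").mkdir(exist_ok=True)
        write_mesh(out / "meshes" / "heart.off", self.heart)
        write_mesh(out / "meshes" / "torso.off", self.torso)
        self.L_coarse.save_h5(out / "leadfield.h5")
        self.movie.save_h5(out / "tmp.h5")
        ecg_io.write_ecg(out / "ecg" / "clean.csv", self.ecg_clean)
        ecg_io.write_ecg(out / "ecg" / "noisy.csv", self.ecg_noisy)
        _write_flat_toml(out / "manifest.toml", self.manifest)


def _write_flat_toml(path: Path, data: dict) -> None:
    """Minimal flat TOML emitter (scalars only); readable by stdlib tomllib."""
    with open(path, "w") as fh:
        for key, val in data.items():
            if isinstance(val, bool):
                fh.write(f"{key} = {'true' if val else 'false'}\n")
            elif isinstance(val, (int, float)):
                fh.write(f"{key} = {val}\n")
            else:
                fh.write(f'{key} = "{val}"\n')


def make_experiment(config: ExperimentConfig, seed: int = 7) -> ExperimentBundle:
    """Build a complete, reproducible synthetic inversion experiment."""
    cfg = config
    heart = build_synthetic_heart(
        cfg.n_atrial_fine, cfg.n_ventricular_fine, cfg.heart_scale_mm
    )
    torso = build_synthetic_torso(cfg.n_torso, cfg.torso_scale_mm)
    electrodes = place_standard_electrodes(torso)
    L_fine = compute_transfer_matrix(heart, torso, electrodes)
    L_coarse, red = reduce_sources(L_fine, heart, cfg.n_coarse)

    params = RDParams(
        k=cfg.k,
        a=cfg.a,
        e=cfg.e,
        D={ATRIAL: cfg.D_atrial, VENTRICULAR: cfg.D_ventricular},
        dt=cfg.dt_ms,
    )
    lap_fine = build_laplacian(heart, params)
    lap_coarse = coarsen_laplacian(lap_fine, red.membership)

    # sinus-like protocol: stimulate the most cranial atrial coarse node at
    # t = 0, the most basal ventricular coarse node after the AV delay
    atr = np.where(red.coarse_labels == ATRIAL)[0]
    ven = np.where(red.coarse_labels == VENTRICULAR)[0]
    sa_node = int(atr[np.argmax(red.coarse_positions[atr, 2])])
    av_node = int(ven[np.argmax(red.coarse_positions[ven, 2])])
    stimuli = (
        StimulusSpec((sa_node,), 0.0, cfg.stim_duration_ms, cfg.stim_amplitude),
        StimulusSpec((av_node,), cfg.av_delay_ms, cfg.stim_duration_ms, cfg.stim_amplitude),
    )
    movie = simulate(
        params,
        stimuli,
        cfg.t_end_ms,
        laplacian=lap_coarse,
        labels=red.coarse_labels,
        seed=seed,
        process_noise_sd=cfg.process_noise_sd or None,
    )
    obs_idx = np.arange(0, len(movie.times), cfg.obs_every)
    movie_obs = TMPMovie(
        times=movie.times[obs_idx],
        u=movie.u[obs_idx],
        v=movie.v[obs_idx],
        labels=movie.labels,
    )

    unc = TransferUncertainty(
        shape=L_coarse.entries.shape,
        entry_sd=cfg.deltaL_rel_sd * float(np.sqrt(np.mean(L_coarse.entries**2))),
    )
    deltaL_true = sample_transfer_perturbation(unc, seed + 1)
    L_pert = dataclasses.replace(L_coarse, entries=L_coarse.entries + deltaL_true)
    ecg_clean = project_to_electrodes(movie_obs, L_pert, gain_mv=cfg.gain_mv)

    n_ch = len(ecg_clean.lead_names)
    if cfg.snr_db is None:
        noise_var = np.zeros(n_ch)
        ecg_noisy = ecg_clean
    else:
        rms2 = np.mean(ecg_clean.samples**2, axis=1)
        if np.any(rms2 <= 0):
            raise InvalidArgumentError("a clean channel is identically zero; cannot set SNR")
        noise_var = rms2 / 10.0 ** (cfg.snr_db / 10.0)
        rng = np.random.default_rng(seed + 2)
        raw = rng.standard_normal(ecg_clean.samples.shape)
        # normalize each channel's realization to the exact target power so the
        # stated SNR is met sample-for-sample
        raw = raw - raw.mean(axis=1, keepdims=True)
        raw /= np.sqrt(np.mean(raw**2, axis=1, keepdims=True))
        noise = raw * np.sqrt(noise_var)[:, None]
        ecg_noisy = ECGRecord(
            fs=ecg_clean.fs,
            lead_names=ecg_clean.lead_names,
            samples=ecg_clean.samples + noise,
        )

    manifest = {
        "seed": seed,
        "seed_deltaL": seed + 1,
        "seed_noise": seed + 2,
        **{f"config_{k}": ("" if v is None else v) for k, v in dataclasses.asdict(cfg).items()},
        "fs_hz": float(ecg_clean.fs),
        "n_coarse_actual": int(red.n_coarse),
        "sa_node": sa_node,
        "av_node": av_node,
    }
    return ExperimentBundle(
        config=cfg,
        seed=seed,
        heart=heart,
        torso=torso,
        electrodes=electrodes,
        L_fine=L_fine,
        L_coarse=L_coarse,
        reduction=red,
        laplacian_coarse=lap_coarse,
        params=params,
        stimuli=stimuli,
        movie=movie,
        movie_obs=movie_obs,
        ecg_clean=ecg_clean,
        ecg_noisy=ecg_noisy,
        deltaL_true=deltaL_true,
        noise_var=noise_var,
        manifest=manifest,
    )


def default_small(seed: int = 7) -> ExperimentBundle:
    """The small working preset: 20 source nodes, 8 channels, one ~600 ms beat.

    Sized so a full Gibbs inversion finishes in minutes on one CPU.
    """
    return make_experiment(ExperimentConfig(), seed=seed)
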