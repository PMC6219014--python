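"""Forward projection of TMP movies to surface ECG and 12-lead derivation.

phi(t) = L u(t): only the transmembrane potential u is observed through the
lead field; the recovery variable v does not reach the body surface (the
observation operator is [L ; 0] on the state x = (u, v)).  The 8 independent
channels are {I, II, V1..V6}; III and the augmented leads are algebraic
combinations derived afterwards.  Amplitudes are in mV after a single global
gain (default 1), since the normalized source model carries no absolute
scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InvalidArgumentError
from .leadfield import TransferMatrix
from .rd import TMPMovie

CHANNEL_ORDER_8 = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
LEAD_ORDER_12 = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")
DEFAULT_GAIN_MV = 1.0


@dataclasses.dataclass(frozen=True)
class ECGRecord:
    """Multichannel surface ECG: samples (n_leads, n_samples) in mV."""

    fs: float
    lead_names: tuple[str, ...]
    samples: np.ndarray
    annotations: dict | None = None

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be > 0")
        if s.shape[0] != len(self.lead_names):
            raise InvalidArgumentError(
                f"{len(self.lead_names)} lead names but {s.shape[0]} signal rows"
            )
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "lead_names", tuple(self.lead_names))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.samples[self.lead_names.index(name)]


def project_to_electrodes(
    movie: TMPMovie, L: TransferMatrix, gain_mv: float = DEFAULT_GAIN_MV
) -> ECGRecord:
    """phi_k = L u_k per time step; v is not observed."""
    if movie.u.shape[1] != L.n_sources:
        raise InvalidArgumentError(
            f"movie has {movie.u.shape[1]} nodes but L has {L.n_sources} source columns"
        )
    dt_ms = float(np.median(np.diff(movie.times))) if len(movie.times) > 1 else 1.0
    fs = 1000.0 / dt_ms
    samples = gain_mv * (L.entries @ movie.u.T)
    return ECGRecord(fs=fs, lead_names=tuple(L.row_ids), samples=samples)


def derive_12_leads(channels8: ECGRecord) -> ECGRecord:
    """Standard 12 leads from the 8 independent channels (I, II, V1..V6)."""
    if channels8.lead_names != CHANNEL_ORDER_8:
        raise InvalidArgumentError(
            f"expected channels {CHANNEL_ORDER_8}, got {channels8.lead_names}"
        )
    I = channels8.lead("I")
    II = channels8.lead("II")
    III = II - I
    aVR = -(I + II) / 2.0
    aVL = I - II / 2.0
    aVF = II - I / 2.0
    chest = [channels8.lead(n) for n in CHANNEL_ORDER_8[2:]]
    samples = np.vstack([I, II, III, aVR, aVL, aVF] + chest)
    return ECGRecord(
        fs=channels8.fs,
        lead_names=LEAD_ORDER_12,
        samples=samples,
        annotations=channels8.annotations,
    )


def add_measurement_noise(
    record: ECGRecord, covariance: float | np.ndarray, seed: int
) -> ECGRecord:
    """Add i.i.d. zero-mean Gaussian noise with the given cross-channel covariance.

    `covariance` may be a scalar variance (shared by all channels), a vector
    of per-channel variances, or a full PSD matrix.
    """
    n_leads = len(record.lead_names)
    cov = np.asarray(covariance, dtype=float)
    rng = np.random.default_rng(seed)
    if cov.ndim == 0:
        if cov < 0:
            raise InvalidArgumentError("variance must be >= 0")
        noise = np.sqrt(cov) * rng.standard_normal(record.samples.shape)
    elif cov.ndim == 1:
        if len(cov) != n_leads or np.any(cov < 0):
            raise InvalidArgumentError("per-channel variances invalid")
        noise = np.sqrt(cov)[:, None] * rng.standard_normal(record.samples.shape)
    else:
        if cov.shape != (n_leads, n_leads):
            raise InvalidArgumentError("covariance shape mismatch")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10 * max(eig.max(), 1.0):
            raise InvalidArgumentError("covariance is not positive semidefinite")
        Lc = np.linalg.cholesky(cov + 1e-15 * np.eye(n_leads) * max(eig.max(), 1.0))
        noise = Lc @ rng.standard_normal(record.samples.shape)
    return ECGRecord(
        fs=record.fs,
        lead_names=record.lead_names,
        samples=record.samples + noise,
        annotations=record.annotations,
    )
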