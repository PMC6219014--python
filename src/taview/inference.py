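"""Hierarchical Bayesian state-space inversion of surface ECG to TMPs.

The data model couples the reaction-diffusion dynamics with the lead field:

    x_{k+1} = F_theta(x_k) + w_k,        w_k ~ N(0, xi_w I)
    phi_k   = (L + DeltaL) u_k + z_k,    z_k ~ N(0, xi_z I)

with state x = (u, v), observation touching only the u-block, and the joint
posterior factorized hierarchically as

    P(x, DeltaL, theta, xi_w, xi_z | phi)
      propto P(phi | x, DeltaL, xi_z) P(x | theta, xi_w)
             P(DeltaL) P(xi_z) p(theta) P(xi_w).

Sampling is blocked Gibbs.  The trajectory block realizes the
Chapman-Kolmogorov forecast / Bayes update recursion in one of three forms:
exact forward-filter backward-sampling on a time-varying linearization of
the paced dynamics along the previous smoothed mean (default), a stochastic
ensemble Kalman filter with perturbed observations plus a backward ensemble
smoother, or exact FFBS on the rest-point linearized augmented propagator.
theta = (k, a, e) enters the dynamics nonlinearly and is updated by
univariate slice sampling; DeltaL rows and the two noise variances have
exact Gaussian / inverse-gamma conjugate updates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
from scipy import stats

from .errors import DegeneracyError, InvalidArgumentError, NumericalError
from .forward import ECGRecord
from .leadfield import TransferMatrix
from .rd import RDParams, TMPState, linearize_and_augment

_ENSEMBLE_SPREAD_TOL = 1e-13
_SLICE_MAX_STEPOUT = 64
#: numerical projection guard for ensemble members: the explicit cubic
#: reaction diverges far outside the physiological range [0, 1], so stray
#: members are clamped to a generous envelope around it
_STATE_CLIP = (-0.5, 1.8)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StateSpaceModel:
    """Dynamics + observation + noise for one observation grid.

    `params.dt` is the inner integration substep (ms); one observation
    interval spans `n_substeps` explicit-Euler substeps.  The observation
    operator is H = [(L + DeltaL) * gain ; 0]: the recovery variable and any
    dummy co-states are unobserved.
    """

    laplacian: np.ndarray
    labels: np.ndarray
    params: RDParams
    L: TransferMatrix
    deltaL: np.ndarray | None = None
    xi_w: float = 1e-4
    xi_z: float = 1e-4
    n_substeps: int = 4
    gain_mv: float = 1.0
    augmentation_factor: int = 10
    #: known exogenous pacing input per integration substep, (n_substeps_total, n);
    #: None = unpaced dynamics (rest is then the only attractor from rest)
    stim_current: np.ndarray | None = None
    #: projection guard envelope for filtering/sampling; None disables it
    state_clip: tuple[float, float] | None = _STATE_CLIP

    def __post_init__(self) -> None:
        if self.deltaL is None:
            self.deltaL = np.zeros_like(self.L.entries)
        if self.xi_w < 0 or self.xi_z < 0:
            raise InvalidArgumentError("noise variances must be >= 0")

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]

    @property
    def dt_obs(self) -> float:
        return self.params.dt * self.n_substeps

    def obs_matrix(self) -> np.ndarray:
        """(n_channels, n_nodes) map from the u-block to the electrodes."""
        return self.gain_mv * (self.L.entries + self.deltaL)

    def transition(
        self,
        x: np.ndarray,
        theta: tuple[float, float, float] | None = None,
        start_step: int | np.ndarray = 0,
        clip: bool = False,
    ) -> np.ndarray:
        """Deterministic one-observation-step propagation F(x); x is (..., 2n).

        `start_step` is the absolute substep index at the start of the
        interval (scalar, or one index per leading row of `x`), used to look
        up the known pacing input.  `clip=True` projects every substep onto
        the physiological envelope (used by the ensemble filter, where stray
        members would otherwise diverge through the explicit cubic).
        """
        p = self.params if theta is None else self.params.with_theta(*theta)
        n = self.n_nodes
        u = x[..., :n]
        v = x[..., n:]
        dt = p.dt
        stim = self.stim_current
        for j in range(self.n_substeps):
            du = u @ self.laplacian.T + p.k * u * (u - p.a) * (1.0 - u) - u * v
            if stim is not None:
                idx = np.minimum(start_step + j, len(stim) - 1)
                cur = stim[idx]
                du = du + (cur if np.ndim(idx) else cur[None] if u.ndim > 1 else cur)
            dv = -p.e * (v + p.k * u * (u - p.a - 1.0))
            u = u + dt * du
            v = v + dt * dv
            if clip and self.state_clip is not None:
                u = np.clip(u, *self.state_clip)
                v = np.clip(v, *self.state_clip)
        return np.concatenate([u, v], axis=-1)


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Priors of the hierarchy: Gaussian theta and DeltaL, inverse-gamma variances."""

    theta_mean: dict[str, float]
    theta_sd: dict[str, float]
    deltaL_sd: float = 0.05
    xi_w_shape: float = 2.0
    xi_w_scale: float = 1e-4
    xi_z_shape: float = 2.0
    xi_z_scale: float = 1e-4

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.theta_sd.values()):
            raise InvalidArgumentError("theta prior sds must be > 0")
        if self.deltaL_sd < 0:
            raise InvalidArgumentError("deltaL_sd must be >= 0")
        if min(self.xi_w_shape, self.xi_w_scale, self.xi_z_shape, self.xi_z_scale) <= 0:
            raise InvalidArgumentError("inverse-gamma hyperparameters must be > 0")


@dataclasses.dataclass
class InferenceConfig:
    n_iter: int = 2000
    n_burn: int = 500
    seed: int = 0
    method: str = "ffbs_reference"
    n_ensemble: int = 48
    n_substeps: int = 4
    traj_thin: int = 5
    slice_width_frac: float = 0.25  # initial slice width as fraction of prior sd
    init_state_sd: float = 0.02


@dataclasses.dataclass
class PosteriorChain:
    """Post-burn-in draws of all unknowns plus convergence diagnostics."""

    theta: dict[str, np.ndarray]  # each (n_draws,)
    xi_w: np.ndarray
    xi_z: np.ndarray
    deltaL: np.ndarray  # (n_draws, n_ch, n_src)
    u_draws: np.ndarray  # (n_kept, T, n) thinned u-trajectory draws
    u_mean: np.ndarray  # (T, n) running posterior mean of u
    n_burn: int
    seed: int
    diagnostics: dict[str, dict[str, float]]
    labels: np.ndarray | None = None

    def theta_mean(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.theta.items()}

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            g = fh.create_group("theta")
            for k, v in self.theta.items():
                g.create_dataset(k, data=v)
            fh.create_dataset("xi_w", data=self.xi_w)
            fh.create_dataset("xi_z", data=self.xi_z)
            fh.create_dataset("deltaL", data=self.deltaL)
            fh.create_dataset("u_draws", data=self.u_draws)
            fh.create_dataset("u_mean", data=self.u_mean)
            if self.labels is not None:
                fh.create_dataset("labels", data=self.labels)
            fh.attrs["n_burn"] = self.n_burn
            fh.attrs["seed"] = self.seed
            d = fh.create_group("diagnostics")
            for name, dd in self.diagnostics.items():
                sub = d.create_group(name)
                for k, v in dd.items():
                    sub.attrs[k] = v


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------


def _gaussian_loglik(resid: np.ndarray, variance: float) -> float:
    if variance <= 0 or not np.all(np.isfinite(resid)):
        return -np.inf
    return float(
        -0.5 * resid.size * np.log(2.0 * np.pi * variance)
        - 0.5 * np.sum(resid**2) / variance
    )


def build_stimulus_currents(
    stimuli, dt: float, n_steps: int, n_nodes: int
) -> np.ndarray:
    """Per-substep exogenous current array (n_steps, n_nodes) for known pacing."""
    out = np.zeros((n_steps, n_nodes))
    times = np.arange(n_steps) * dt
    for s in stimuli:
        mask = (times >= s.onset_ms) & (times < s.onset_ms + s.duration_ms)
        out[np.ix_(mask, list(s.site_nodes))] += s.amplitude
    return out


def transition_loglik(
    x_traj: np.ndarray,
    model: StateSpaceModel,
    theta: tuple[float, float, float],
    xi_w: float,
) -> float:
    """log P(x | theta, xi_w): Gaussian one-step transition densities."""
    offsets = np.arange(len(x_traj) - 1) * model.n_substeps
    pred = model.transition(x_traj[:-1], theta, start_step=offsets, clip=True)
    return _gaussian_loglik(x_traj[1:] - pred, xi_w)


def observation_loglik(
    x_traj: np.ndarray,
    model: StateSpaceModel,
    deltaL: np.ndarray,
    xi_z: float,
    phi: np.ndarray,
) -> float:
    """log P(phi | x, DeltaL, xi_z); phi is (n_channels, T)."""
    n = model.n_nodes
    H = model.gain_mv * (model.L.entries + deltaL)
    resid = phi - H @ x_traj[:, :n].T
    return _gaussian_loglik(resid, xi_z)


def log_posterior(
    x_traj: np.ndarray,
    theta: tuple[float, float, float],
    deltaL: np.ndarray,
    xi_w: float,
    xi_z: float,
    ecg: ECGRecord,
    priors: PriorSpec,
    model: StateSpaceModel,
) -> float:
    """Joint log-density of the full hierarchy (up to an additive constant)."""
    if not np.all(np.isfinite(x_traj)):
        raise InvalidArgumentError("trajectory contains non-finite values")
    if xi_w <= 0 or xi_z <= 0:
        raise InvalidArgumentError("variances must be > 0")
    k, a, e = theta
    if k <= 0 or not 0 < a < 1 or e <= 0:
        return -np.inf
    lp = observation_loglik(x_traj, model, deltaL, xi_z, ecg.samples)
    lp += transition_loglik(x_traj, model, theta, xi_w)
    for name, val in zip(("k", "a", "e"), theta):
        lp += float(
            stats.norm.logpdf(val, priors.theta_mean[name], priors.theta_sd[name])
        )
    if priors.deltaL_sd > 0:
        lp += float(np.sum(stats.norm.logpdf(deltaL, 0.0, priors.deltaL_sd)))
    lp += float(stats.invgamma.logpdf(xi_w, priors.xi_w_shape, scale=priors.xi_w_scale))
    lp += float(stats.invgamma.logpdf(xi_z, priors.xi_z_shape, scale=priors.xi_z_scale))
    return lp


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def slice_sample_scalar(
    logdensity: Callable[[float], float],
    x0: float,
    width: float,
    seed: int | np.random.Generator = 0,
) -> float:
    """One univariate slice-sampling draw (stepping-out then shrinkage)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f0 = logdensity(x0)
    if not np.isfinite(f0):
        raise InvalidArgumentError("logdensity must be finite at the current point")
    log_y = f0 + np.log(rng.uniform())
    lo = x0 - width * rng.uniform()
    hi = lo + width
    j = int(np.floor(_SLICE_MAX_STEPOUT * rng.uniform()))
    kk = _SLICE_MAX_STEPOUT - 1 - j
    while j > 0 and logdensity(lo) > log_y:
        lo -= width
        j -= 1
    while kk > 0 and logdensity(hi) > log_y:
        hi += width
        kk -= 1
    while True:
        x1 = rng.uniform(lo, hi)
        if logdensity(x1) > log_y:
            return float(x1)
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def gibbs_update_variances(
    process_resid: np.ndarray,
    obs_resid: np.ndarray,
    priors: PriorSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Conjugate inverse-gamma draws of (xi_w, xi_z) given residual series."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for resid, shape, scale in (
        (process_resid, priors.xi_w_shape, priors.xi_w_scale),
        (obs_resid, priors.xi_z_shape, priors.xi_z_scale),
    ):
        resid = np.asarray(resid, dtype=float)
        if not np.all(np.isfinite(resid)):
            raise InvalidArgumentError("residuals must be finite")
        post_shape = shape + resid.size / 2.0
        post_scale = scale + float(np.sum(resid**2)) / 2.0
        out.append(float(stats.invgamma.rvs(post_shape, scale=post_scale, random_state=rng)))
    return out[0], out[1]


def gibbs_update_deltaL(
    u_traj: np.ndarray,
    ecg: ECGRecord,
    L: TransferMatrix,
    xi_z: float,
    priors: PriorSpec,
    seed: int | np.random.Generator = 0,
    gain_mv: float = 1.0,
) -> np.ndarray:
    """Exact Gaussian conditional draw of DeltaL, row by row.

    Each electrode row solves a ridge regression of the observation residual
    on the u trajectory: posterior precision A = U^T U / xi_z + I / sd^2,
    mean A^{-1} U^T r / xi_z.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if priors.deltaL_sd == 0:
        return np.zeros_like(L.entries)
    U = gain_mv * u_traj  # (T, n)
    resid = ecg.samples - gain_mv * (L.entries @ u_traj.T)  # (n_ch, T)
    n = U.shape[1]
    A = U.T @ U / xi_z + np.eye(n) / priors.deltaL_sd**2
    try:
        chol = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular normal equations in DeltaL update") from exc
    rhs = U.T @ resid.T / xi_z  # (n, n_ch)
    mean = np.linalg.solve(A, rhs)  # (n, n_ch)
    noise = np.linalg.solve(chol.T, rng.standard_normal((n, resid.shape[0])))
    return (mean + noise).T


# --- linear-Gaussian machinery (exact Kalman filter / FFBS) -----------------


def kalman_filter(
    A: np.ndarray,
    H: np.ndarray,
    Q: np.ndarray,
    R: np.ndarray,
    ys: np.ndarray,
    m0: np.ndarray,
    P0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standard Kalman recursion; ys is (T, p).  Returns (m_f, P_f, m_p, P_p).

    The predictive step is the Chapman-Kolmogorov integral of the Gaussian
    transition kernel; the update step is the Bayes rule — both exact here.
    """
    T = ys.shape[0]
    dim = len(m0)
    m_f = np.zeros((T, dim))
    P_f = np.zeros((T, dim, dim))
    m_p = np.zeros((T, dim))
    P_p = np.zeros((T, dim, dim))
    m, P = m0, P0
    for k in range(T):
        if k > 0:
            m = A @ m
            P = A @ P @ A.T + Q
        m_p[k], P_p[k] = m, P
        S = H @ P @ H.T + R
        K = np.linalg.solve(S, H @ P).T
        m = m + K @ (ys[k] - H @ m)
        P = P - K @ S @ K.T
        P = 0.5 * (P + P.T)
        m_f[k], P_f[k] = m, P
    return m_f, P_f, m_p, P_p


def kalman_smoother(
    A: np.ndarray, m_f: np.ndarray, P_f: np.ndarray, m_p: np.ndarray, P_p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rauch-Tung-Striebel pass on Kalman filter output."""
    T, dim = m_f.shape
    m_s = m_f.copy()
    P_s = P_f.copy()
    for k in range(T - 2, -1, -1):
        G = np.linalg.solve(P_p[k + 1], A @ P_f[k]).T
        m_s[k] = m_f[k] + G @ (m_s[k + 1] - m_p[k + 1])
        P_s[k] = P_f[k] + G @ (P_s[k + 1] - P_p[k + 1]) @ G.T
    return m_s, P_s


def ffbs_sample(
    A: np.ndarray,
    H: np.ndarray,
    Q: np.ndarray,
    R: np.ndarray,
    ys: np.ndarray,
    m0: np.ndarray,
    P0: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Exact trajectory draw from a linear-Gaussian smoothing posterior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_f, P_f, _, _ = kalman_filter(A, H, Q, R, ys, m0, P0)
    T, dim = m_f.shape
    x = np.zeros((T, dim))
    x[T - 1] = rng.multivariate_normal(m_f[T - 1], P_f[T - 1], method="svd")
    for k in range(T - 2, -1, -1):
        Pp = A @ P_f[k] @ A.T + Q
        G = np.linalg.solve(Pp, A @ P_f[k]).T
        m_c = m_f[k] + G @ (x[k + 1] - A @ m_f[k])
        P_c = P_f[k] - G @ A @ P_f[k]
        P_c = 0.5 * (P_c + P_c.T)
        x[k] = rng.multivariate_normal(m_c, P_c, method="svd")
    return x


# --- FFBS on the reference-trajectory linearization -------------------------


def _rollout(model: StateSpaceModel, T: int) -> np.ndarray:
    """Deterministic paced rollout from rest, (T, 2n)."""
    refs = np.zeros((T, 2 * model.n_nodes))
    for k in range(T - 1):
        refs[k + 1] = model.transition(
            refs[k], start_step=k * model.n_substeps, clip=True
        )
    return refs


def _linearized_interval_maps(
    model: StateSpaceModel, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent-linear maps of the paced dynamics along a reference trajectory.

    For every observation interval k the product of substep Jacobians is
    accumulated, so that  x_{k+1} ~= A_k x_k + c_k  near the reference, with
    c_k = F(ref_k) - A_k ref_k.  Returns (A (T-1, 2n, 2n), c (T-1, 2n)).
    """
    p = model.params
    n = model.n_nodes
    lap = model.laplacian
    dt = p.dt
    T = len(reference)
    u = reference[:-1, :n].copy()
    v = reference[:-1, n:].copy()
    A = np.broadcast_to(np.eye(2 * n), (T - 1, 2 * n, 2 * n)).copy()
    stim = model.stim_current
    base_idx = np.arange(T - 1) * model.n_substeps
    for j in range(model.n_substeps):
        d1 = p.k * (-3.0 * u**2 + 2.0 * (1.0 + p.a) * u - p.a) - v
        d2 = -u
        d3 = -p.e * p.k * (2.0 * u - p.a - 1.0)
        Au = A[:, :n, :]
        Av = A[:, n:, :]
        JAu = lap @ Au + d1[:, :, None] * Au + d2[:, :, None] * Av
        JAv = d3[:, :, None] * Au - p.e * Av
        A = A + dt * np.concatenate([JAu, JAv], axis=1)
        du = u @ lap.T + p.k * u * (u - p.a) * (1.0 - u) - u * v
        if stim is not None:
            idx = np.minimum(base_idx + j, len(stim) - 1)
            du = du + stim[idx]
        dv = -p.e * (v + p.k * u * (u - p.a - 1.0))
        u = u + dt * du
        v = v + dt * dv
        if model.state_clip is not None:
            u = np.clip(u, *model.state_clip)
            v = np.clip(v, *model.state_clip)
    pred = np.concatenate([u, v], axis=-1)
    c = pred - np.einsum("tij,tj->ti", A, reference[:-1])
    return A, c


def _ffbs_reference(
    model: StateSpaceModel,
    phi: np.ndarray,
    rng: np.random.Generator,
    init_sd: float,
    reference: np.ndarray | None = None,
    return_smoothed_mean: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Exact FFBS draw from the reference-linearized time-varying model."""
    T = phi.shape[1]
    n = model.n_nodes
    dim = 2 * n
    if reference is None:
        reference = _rollout(model, T)
    As, cs = _linearized_interval_maps(model, reference)
    Hu = model.obs_matrix()
    n_ch = Hu.shape[0]
    H = np.zeros((n_ch, dim))
    H[:, :n] = Hu
    Q = model.xi_w * np.eye(dim)
    R = model.xi_z * np.eye(n_ch)
    m = np.zeros(dim)
    P = init_sd**2 * np.eye(dim)
    m_f = np.zeros((T, dim))
    P_f = np.zeros((T, dim, dim))
    for k in range(T):
        if k > 0:
            m = As[k - 1] @ m + cs[k - 1]
            P = As[k - 1] @ P @ As[k - 1].T + Q
        S = H @ P @ H.T + R
        K = np.linalg.solve(S, H @ P).T
        m = m + K @ (phi[:, k] - H @ m)
        P = P - K @ S @ K.T
        P = 0.5 * (P + P.T)
        m_f[k], P_f[k] = m, P
    x = np.zeros((T, dim))
    x[T - 1] = _mvn_draw(m_f[T - 1], P_f[T - 1], rng)
    for k in range(T - 2, -1, -1):
        A = As[k]
        Pp = A @ P_f[k] @ A.T + Q
        G = np.linalg.solve(Pp, A @ P_f[k]).T
        m_c = m_f[k] + G @ (x[k + 1] - (A @ m_f[k] + cs[k]))
        P_c = P_f[k] - G @ A @ P_f[k]
        P_c = 0.5 * (P_c + P_c.T)
        x[k] = _mvn_draw(m_c, P_c, rng)
    if model.state_clip is not None:
        np.clip(x, *model.state_clip, out=x)
    if return_smoothed_mean:
        ms = m_f.copy()
        for k in range(T - 2, -1, -1):
            A = As[k]
            Pp = A @ P_f[k] @ A.T + Q
            G = np.linalg.solve(Pp, A @ P_f[k]).T
            ms[k] = m_f[k] + G @ (ms[k + 1] - (A @ m_f[k] + cs[k]))
        if model.state_clip is not None:
            np.clip(ms, *model.state_clip, out=ms)
        return x, ms
    return x


def _mvn_draw(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian draw via eigen square root (robust to tiny negative eigenvalues)."""
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return mean + (V * np.sqrt(w)) @ rng.standard_normal(len(mean))


# --- ensemble Kalman filter-smoother ----------------------------------------


def _enkf_forward(
    model: StateSpaceModel,
    phi: np.ndarray,
    rng: np.random.Generator,
    n_ensemble: int,
    init_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic EnKF with perturbed observations; returns (forecast, analysis)
    ensembles of shape (T, N, 2n)."""
    n = model.n_nodes
    dim = 2 * n
    T = phi.shape[1]
    H = model.obs_matrix()
    n_ch = H.shape[0]
    R = model.xi_z * np.eye(n_ch)
    ens = init_sd * rng.standard_normal((n_ensemble, dim))
    Xf = np.zeros((T, n_ensemble, dim))
    Xa = np.zeros((T, n_ensemble, dim))
    sw = np.sqrt(model.xi_w)
    for k in range(T):
        if k > 0:
            ens = model.transition(ens, start_step=(k - 1) * model.n_substeps, clip=True)
            ens += sw * rng.standard_normal(ens.shape)
            if model.state_clip is not None:
                np.clip(ens, *model.state_clip, out=ens)
        Xf[k] = ens
        anom = ens - ens.mean(axis=0)
        spread = np.sqrt(np.mean(anom**2))
        if spread < _ENSEMBLE_SPREAD_TOL:
            raise DegeneracyError(
                f"ensemble collapse at step {k} (spread {spread:.2e}); "
                "consider covariance inflation or more members"
            )
        Hy = ens[:, :n] @ H.T  # (N, n_ch)
        Hy_anom = Hy - Hy.mean(axis=0)
        S = Hy_anom.T @ Hy_anom / (n_ensemble - 1) + R
        y_pert = phi[:, k] + np.sqrt(model.xi_z) * rng.standard_normal((n_ensemble, n_ch))
        innov = y_pert - Hy
        sol = np.linalg.solve(S, innov.T)  # (n_ch, N)
        Cxy = anom.T @ Hy_anom / (n_ensemble - 1)  # (dim, n_ch)
        ens = ens + (Cxy @ sol).T
        if model.state_clip is not None:
            np.clip(ens, *model.state_clip, out=ens)
        Xa[k] = ens
    return Xf, Xa


def _ensemble_rts_smoother(
    Xf: np.ndarray, Xa: np.ndarray, state_clip: tuple[float, float] | None = None
) -> np.ndarray:
    """Backward ensemble smoother (RTS form with ensemble-estimated gains)."""
    T, N, dim = Xa.shape
    Xs = Xa[T - 1].copy()
    out = np.zeros_like(Xa)
    out[T - 1] = Xs
    for k in range(T - 2, -1, -1):
        Aa = Xa[k] - Xa[k].mean(axis=0)
        Af = Xf[k + 1] - Xf[k + 1].mean(axis=0)
        G = Aa.T @ np.linalg.pinv(Af.T, rcond=1e-10)  # (dim, dim) ensemble gain
        Xs = Xa[k] + (Xs - Xf[k + 1]) @ G.T
        if state_clip is not None:
            np.clip(Xs, *state_clip, out=Xs)
        out[k] = Xs
    return out


def sample_state_trajectory(
    model: StateSpaceModel,
    ecg: ECGRecord,
    method: str = "ensemble_kalman_smoother",
    n_ensemble: int = 48,
    seed: int | np.random.Generator = 0,
    init_sd: float = 0.02,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """One (approximate) draw of the state trajectory given all parameters.

    Returns an array (T, 2n).  `ffbs_reference` (the default inside
    `run_inference`) draws exactly from the model linearized along its own
    deterministic paced rollout; `ensemble_kalman_smoother` runs a stochastic
    EnKF forward pass and a backward ensemble smoother and returns one
    smoothed member; `ffbs_linearized` runs the exact forward-filter
    backward-sampler on the rest-point linearized augmented propagator and
    returns the (u, v) blocks of the augmented draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = ecg.samples
    if method == "ffbs_reference":
        return _ffbs_reference(model, phi, rng, init_sd, reference=reference)
    if method == "ensemble_kalman_smoother":
        Xf, Xa = _enkf_forward(model, phi, rng, n_ensemble, init_sd)
        Xs = _ensemble_rts_smoother(Xf, Xa, model.state_clip)
        return Xs[:, 0, :]
    if method == "ffbs_linearized":
        n = model.n_nodes
        rest = TMPState(np.zeros(n), np.zeros(n))
        A = linearize_and_augment(
            model.params, rest, model.laplacian, model.augmentation_factor
        )
        # one observation interval = n_substeps substeps of the linear map
        A = np.linalg.matrix_power(A, model.n_substeps)
        dim = A.shape[0]
        Hu = model.obs_matrix()
        H = np.zeros((Hu.shape[0], dim))
        H[:, :n] = Hu
        Q = model.xi_w * np.eye(dim)
        R = model.xi_z * np.eye(Hu.shape[0])
        m0 = np.zeros(dim)
        P0 = init_sd**2 * np.eye(dim)
        x = ffbs_sample(A, H, Q, R, phi.T, m0, P0, rng)
        return x[:, : 2 * n]
    raise InvalidArgumentError(f"unknown trajectory method {method!r}")


# ---------------------------------------------------------------------------
# full Gibbs cycle
# ---------------------------------------------------------------------------


def run_inference(
    ecg: ECGRecord,
    L: TransferMatrix,
    laplacian: np.ndarray,
    priors: PriorSpec,
    config: InferenceConfig | None = None,
    params: RDParams | None = None,
    stimuli=(),
    gain_mv: float = 1.0,
) -> PosteriorChain:
    """Blocked Gibbs sampler over (x, theta, DeltaL, xi_w, xi_z).

    `params` fixes the substep dt and diffusion (not sampled); theta = (k, a,
    e) is initialized at the prior means; `stimuli` is the known pacing
    protocol entering the dynamics as an exogenous input.  Fully reproducible
    under `config.seed`.
    """
    config = config or InferenceConfig()
    base = params or RDParams()
    rng = np.random.default_rng(config.seed)
    theta = np.array([priors.theta_mean[n] for n in ("k", "a", "e")])
    n_src = L.n_sources
    stim = (
        build_stimulus_currents(
            stimuli, base.dt, ecg.n_samples * config.n_substeps, n_src
        )
        if stimuli
        else None
    )
    model = StateSpaceModel(
        laplacian=laplacian,
        labels=L.col_labels,
        params=base.with_theta(*theta),
        L=L,
        xi_w=priors.xi_w_scale / max(priors.xi_w_shape - 1.0, 0.5),
        xi_z=priors.xi_z_scale / max(priors.xi_z_shape - 1.0, 0.5),
        n_substeps=config.n_substeps,
        gain_mv=gain_mv,
        stim_current=stim,
    )
    n = model.n_nodes
    phi = ecg.samples
    T = phi.shape[1]
    n_draws = config.n_iter - config.n_burn
    if n_draws <= 0:
        raise InvalidArgumentError("n_iter must exceed n_burn")

    theta_draws = {name: np.zeros(n_draws) for name in ("k", "a", "e")}
    xi_w_draws = np.zeros(n_draws)
    xi_z_draws = np.zeros(n_draws)
    deltaL_draws = np.zeros((n_draws, *model.L.entries.shape))
    kept_u = []
    u_sum = np.zeros((T, n))

    names = ("k", "a", "e")
    bounds = {"k": (0.0, np.inf), "a": (0.0, 1.0), "e": (0.0, np.inf)}

    # linearization reference: the smoothed mean of the previous iteration
    # (noise-free, so re-linearization does not accumulate draw noise)
    x_ref: np.ndarray | None = None
    for it in range(config.n_iter):
        # --- trajectory | theta, DeltaL, variances
        if config.method == "ffbs_reference":
            x_traj, x_ref = _ffbs_reference(
                model, phi, rng, config.init_state_sd,
                reference=x_ref, return_smoothed_mean=True,
            )
        else:
            x_traj = sample_state_trajectory(
                model,
                ecg,
                method=config.method,
                n_ensemble=config.n_ensemble,
                seed=rng,
                init_sd=config.init_state_sd,
            )

        # --- theta | trajectory (slice sampling per component)
        for j, name in enumerate(names):
            lo, hi = bounds[name]

            def logdens(val: float, j=j, name=name, lo=lo, hi=hi) -> float:
                if not lo < val < hi:
                    return -np.inf
                th = theta.copy()
                th[j] = val
                ll = transition_loglik(x_traj, model, tuple(th), model.xi_w)
                lp = -0.5 * ((val - priors.theta_mean[name]) / priors.theta_sd[name]) ** 2
                return ll + lp

            width = max(config.slice_width_frac * priors.theta_sd[name], 1e-12)
            theta[j] = slice_sample_scalar(logdens, float(theta[j]), width, rng)
        model.params = base.with_theta(*theta)

        # --- DeltaL | trajectory, data, xi_z
        model.deltaL = gibbs_update_deltaL(
            x_traj[:, :n], ecg, model.L, model.xi_z, priors, rng, gain_mv=gain_mv
        )

        # --- variances | residuals
        offsets = np.arange(len(x_traj) - 1) * model.n_substeps
        proc_resid = x_traj[1:] - model.transition(
            x_traj[:-1], start_step=offsets, clip=True
        )
        obs_resid = phi - model.obs_matrix() @ x_traj[:, :n].T
        model.xi_w, model.xi_z = gibbs_update_variances(proc_resid, obs_resid, priors, rng)

        if it >= config.n_burn:
            idx = it - config.n_burn
            for j, name in enumerate(names):
                theta_draws[name][idx] = theta[j]
            xi_w_draws[idx] = model.xi_w
            xi_z_draws[idx] = model.xi_z
            deltaL_draws[idx] = model.deltaL
            u_sum += x_traj[:, :n]
            if idx % config.traj_thin == 0:
                kept_u.append(x_traj[:, :n].copy())

    diagnostics = _chain_diagnostics(
        {**theta_draws, "xi_w": xi_w_draws, "xi_z": xi_z_draws}
    )
    return PosteriorChain(
        theta=theta_draws,
        xi_w=xi_w_draws,
        xi_z=xi_z_draws,
        deltaL=deltaL_draws,
        u_draws=np.array(kept_u),
        u_mean=u_sum / n_draws,
        n_burn=config.n_burn,
        seed=config.seed,
        diagnostics=diagnostics,
        labels=model.L.col_labels,
    )


def _chain_diagnostics(scalars: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Effective sample size and split-Rhat (two half-chains) per scalar."""
    import arviz as az

    out = {}
    for name, draws in scalars.items():
        half = len(draws) // 2
        split = np.vstack([draws[:half], draws[half : 2 * half]])
        out[name] = {
            "mean": float(draws.mean()),
            "sd": float(draws.std()),
            "ess": float(az.ess(split)),
            "rhat": float(az.rhat(split)),
        }
    return out
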