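"""Two-variable excitation-recovery reaction-diffusion dynamics on the heart.

The Aliev-Panfilov-type system on the heart surface nodes,

    du/dt = div(D grad u) + k u (u - a) (1 - u) - u v
    dv/dt = -e (v + k u (u - a - 1)),

with u the normalized transmembrane potential (rest 0, peak ~1) and v the
recovery variable, drives both the ground-truth simulator and the dynamic
constraint of the Bayesian inversion.  The diffusion term is discretized with
a cotangent-weighted surface Laplacian (symmetric, negative semidefinite,
zero row sums), with harmonic-mean diffusivity on edges crossing the
atrial/ventricular region boundary.

Parameters k (reaction gain), a (excitation threshold) and e (recovery rate)
are dimensionless; D is mm^2/ms per region; time is in ms.  Defaults follow
the common phenomenological-model literature (k=8, a=0.15, e=0.01).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import GeometryError, IntegrationError, InvalidArgumentError
from .mesh import ATRIAL, VENTRICULAR, TriSurfaceMesh

_DEGENERATE_AREA_MM2 = 1e-9


@dataclasses.dataclass(frozen=True)
class RDParams:
    """Reaction-diffusion parameters; all dimensionless except D (mm^2/ms), dt (ms)."""

    k: float = 8.0
    a: float = 0.15
    e: float = 0.01
    D: dict[int, float] | float = 1.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise InvalidArgumentError("k must be > 0")
        if not 0 < self.a < 1:
            raise InvalidArgumentError("a must lie in (0, 1)")
        if self.e <= 0:
            raise InvalidArgumentError("e must be > 0")
        dvals = self.D.values() if isinstance(self.D, dict) else [self.D]
        if any(d < 0 for d in dvals):
            raise InvalidArgumentError("D must be >= 0")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be > 0")

    def diffusion_for(self, label: int) -> float:
        if isinstance(self.D, dict):
            return float(self.D[label])
        return float(self.D)

    def with_theta(self, k: float, a: float, e: float) -> "RDParams":
        return dataclasses.replace(self, k=k, a=a, e=e)


@dataclasses.dataclass(frozen=True)
class TMPState:
    """State x = (u, v) of all heart source nodes at time t (ms)."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape or u.ndim != 1:
            raise InvalidArgumentError("u and v must be 1-D arrays of equal length")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    """External excitation current applied to du/dt on a node set."""

    site_nodes: tuple[int, ...]
    onset_ms: float
    duration_ms: float = 1.0
    amplitude: float = 0.4

    def __post_init__(self) -> None:
        if len(self.site_nodes) == 0:
            raise InvalidArgumentError("stimulus site must be nonempty")
        if self.onset_ms < 0 or self.duration_ms < 0:
            raise InvalidArgumentError("onset and duration must be >= 0")


@dataclasses.dataclass(frozen=True)
class TMPMovie:
    """Time-resolved (u, v) trajectory on the heart source nodes."""

    times: np.ndarray  # (T,) ms
    u: np.ndarray  # (T, n)
    v: np.ndarray  # (T, n)
    labels: np.ndarray  # (n,) region labels

    @property
    def n_nodes(self) -> int:
        return self.u.shape[1]

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("u", data=self.u)
            fh.create_dataset("v", data=self.v)
            fh.create_dataset("labels", data=self.labels)

    @classmethod
    def load_h5(cls, path: str | Path) -> "TMPMovie":
        with h5py.File(path, "r") as fh:
            return cls(fh["times"][()], fh["u"][()], fh["v"][()], fh["labels"][()])


# ---------------------------------------------------------------------------
# discrete diffusion operator
# ---------------------------------------------------------------------------


def build_laplacian(heart: TriSurfaceMesh, params: RDParams | None = None) -> np.ndarray:
    """Cotangent-weighted diffusion operator approximating div(D grad .).

    Edge weight = D_edge * (cot(alpha) + cot(beta)) / 2 / A_bar, where alpha
    and beta are the angles opposite the edge, D_edge is the harmonic mean of
    the two endpoint regions' diffusivities, and A_bar is the mean barycentric
    vertex area (a single global scale so the operator stays symmetric).
    Result is symmetric, negative semidefinite, zero row sums; units 1/ms.
    """
    params = params or RDParams()
    v = heart.vertices
    tris = heart.triangles
    areas = heart.triangle_areas()
    if np.any(areas < _DEGENERATE_AREA_MM2):
        bad = int(np.argmin(areas))
        raise GeometryError(f"degenerate triangle {bad} (area {areas[bad]:.3g} mm^2)")
    n = heart.n_vertices
    W = np.zeros((n, n))
    Dnode = np.array([params.diffusion_for(int(l)) for l in heart.region_label])
    for c in range(3):
        i = tris[:, c]
        j = tris[:, (c + 1) % 3]
        k = tris[:, (c + 2) % 3]  # vertex opposite edge (i, j)
        e1 = v[i] - v[k]
        e2 = v[j] - v[k]
        cot = np.einsum("ij,ij->i", e1, e2) / (2.0 * areas)
        di, dj = Dnode[i], Dnode[j]
        both = di + dj
        dharm = np.where(both > 0, 2.0 * di * dj / np.where(both > 0, both, 1.0), 0.0)
        w = 0.5 * cot * dharm
        np.add.at(W, (i, j), w)
        np.add.at(W, (j, i), w)
    abar = heart.vertex_areas().mean()
    W /= abar
    np.fill_diagonal(W, 0.0)
    lap = W - np.diag(W.sum(axis=1))
    return lap


def coarsen_laplacian(lap_fine: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Galerkin aggregation of a fine operator onto coarse clusters.

    L_c = S^-1 P^T L_f P with P the 0/1 membership indicator and
    S = diag(cluster sizes) rescaled symmetrically: the returned operator is
    S^-1/2 P^T L_f P S^-1/2, which keeps symmetry and negative
    semidefiniteness; zero row sums hold exactly only for equal cluster
    sizes, so the residual row sum is folded into the diagonal.
    """
    membership = np.asarray(membership, dtype=np.int64)
    nc = membership.max() + 1
    P = np.zeros((len(membership), nc))
    P[np.arange(len(membership)), membership] = 1.0
    sizes = P.sum(axis=0)
    Shalf = np.diag(1.0 / np.sqrt(sizes))
    Lc = Shalf @ (P.T @ lap_fine @ P) @ Shalf
    Lc = 0.5 * (Lc + Lc.T)
    # restore the zero-row-sum (no-flux) property lost to unequal cluster sizes
    np.fill_diagonal(Lc, np.diag(Lc) - Lc.sum(axis=1))
    return Lc


def stable_dt_max(laplacian: np.ndarray, params: RDParams) -> float:
    """Explicit-Euler stability bound dt <= 2 / (lambda_max + k).

    lambda_max of the (positive) diffusion operator -L is bounded by the
    Gershgorin estimate 2 * max_i |L_ii|; the reaction Jacobian magnitude is
    bounded by k over the physiological range of u.
    """
    gersh = 2.0 * np.abs(np.diag(laplacian)).max() if laplacian.size else 0.0
    return 2.0 / (gersh + params.k)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def rd_rhs(
    state: TMPState, params: RDParams, laplacian: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (du/dt, dv/dt); pure function of its inputs."""
    u, v = state.u, state.v
    if laplacian.shape != (len(u), len(u)):
        raise InvalidArgumentError(
            f"laplacian shape {laplacian.shape} does not match state size {len(u)}"
        )
    du = laplacian @ u + params.k * u * (u - params.a) * (1.0 - u) - u * v
    dv = -params.e * (v + params.k * u * (u - params.a - 1.0))
    return du, dv


def _rhs_arrays(
    u: np.ndarray, v: np.ndarray, params: RDParams, laplacian: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """rhs vectorized over leading axes; u, v shaped (..., n)."""
    du = u @ laplacian.T + params.k * u * (u - params.a) * (1.0 - u) - u * v
    dv = -params.e * (v + params.k * u * (u - params.a - 1.0))
    return du, dv


def _stimulus_current(
    stimuli: Sequence[StimulusSpec], t: float, n: int
) -> np.ndarray | None:
    cur = None
    for s in stimuli:
        if s.onset_ms <= t < s.onset_ms + s.duration_ms:
            if cur is None:
                cur = np.zeros(n)
            cur[list(s.site_nodes)] += s.amplitude
    return cur


def simulate(
    params: RDParams,
    stimuli: Sequence[StimulusSpec],
    t_end: float,
    mesh: TriSurfaceMesh | None = None,
    *,
    laplacian: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    seed: int = 0,
    process_noise_sd: float | None = None,
    method: str = "euler",
) -> TMPMovie:
    """Integrate the system from rest; explicit Euler (default) or Heun.

    Process noise, when requested, adds i.i.d. Gaussian increments of
    standard deviation `process_noise_sd * sqrt(dt)` to both u and v at every
    step (the discrete-time realization of an i.i.d. model error process).
    """
    if laplacian is None:
        if mesh is None:
            raise InvalidArgumentError("either mesh or laplacian is required")
        laplacian = build_laplacian(mesh, params)
        labels = mesh.region_label
    if labels is None:
        raise InvalidArgumentError("labels are required when passing a laplacian")
    n = laplacian.shape[0]
    dt = params.dt
    if dt > stable_dt_max(laplacian, params):
        raise InvalidArgumentError(
            f"dt={dt} exceeds the stability bound {stable_dt_max(laplacian, params):.4g} ms"
        )
    for s in stimuli:
        if s.onset_ms > t_end:
            raise InvalidArgumentError("stimulus onset beyond t_end")
        if max(s.site_nodes) >= n:
            raise InvalidArgumentError("stimulus site index out of range")
    if method not in ("euler", "heun"):
        raise InvalidArgumentError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    U = np.zeros((n_steps + 1, n))
    V = np.zeros((n_steps + 1, n))
    u = np.zeros(n)
    v = np.zeros(n)
    for step in range(n_steps):
        t = times[step]
        du, dv = _rhs_arrays(u, v, params, laplacian)
        stim = _stimulus_current(stimuli, t, n)
        if stim is not None:
            du = du + stim
        if method == "euler":
            u_new = u + dt * du
            v_new = v + dt * dv
        else:  # heun
            up = u + dt * du
            vp = v + dt * dv
            du2, dv2 = _rhs_arrays(up, vp, params, laplacian)
            stim2 = _stimulus_current(stimuli, t + dt, n)
            if stim2 is not None:
                du2 = du2 + stim2
            u_new = u + 0.5 * dt * (du + du2)
            v_new = v + 0.5 * dt * (dv + dv2)
        if process_noise_sd:
            sc = process_noise_sd * np.sqrt(dt)
            u_new = u_new + sc * rng.standard_normal(n)
            v_new = v_new + sc * rng.standard_normal(n)
        if np.any(np.abs(u_new) > 10.0):
            raise IntegrationError(
                f"instability at step {step + 1} (t={t + dt:.3g} ms): |u| > 10"
            )
        u, v = u_new, v_new
        U[step + 1] = u
        V[step + 1] = v
    return TMPMovie(times=times, u=U, v=V, labels=np.asarray(labels))


def activation_times(movie: TMPMovie, threshold: float = 0.5) -> np.ndarray:
    """First upward crossing time of u through the threshold, NaN if never."""
    above = movie.u >= threshold
    rising = above & ~np.vstack([np.zeros((1, movie.n_nodes), dtype=bool), above[:-1]])
    out = np.full(movie.n_nodes, np.nan)
    for j in range(movie.n_nodes):
        idx = np.argmax(rising[:, j])
        if rising[idx, j]:
            out[j] = movie.times[idx]
    return out


# ---------------------------------------------------------------------------
# linearization with augmented co-states
# ---------------------------------------------------------------------------


def rd_jacobian(
    u: np.ndarray, v: np.ndarray, params: RDParams, laplacian: np.ndarray
) -> np.ndarray:
    """Jacobian of the (u, v) right-hand side at the given operating point."""
    k, a, e = params.k, params.a, params.e
    duu = laplacian + np.diag(k * (-3.0 * u**2 + 2.0 * (1.0 + a) * u - a) - v)
    duv = np.diag(-u)
    dvu = np.diag(-e * k * (2.0 * u - a - 1.0))
    dvv = -e * np.eye(len(u))
    return np.block([[duu, duv], [dvu, dvv]])


def linearize_and_augment(
    params: RDParams,
    operating_point: TMPState,
    laplacian: np.ndarray,
    augmentation_factor: int = 10,
) -> np.ndarray:
    """Discrete-time propagator I + dt * J on the augmented state.

    The augmented state is (u, v, d_1, ..., d_m) with m = augmentation_factor
    * n dummy co-states arranged in a delay chain behind v: the first block
    relaxes toward v at rate e, each later block toward its predecessor.
    The dummies enrich the effective memory of the linearized dynamics; the
    rest state remains an exact fixed point.
    """
    if augmentation_factor < 0:
        raise InvalidArgumentError("augmentation_factor must be >= 0")
    n = len(operating_point.u)
    J = rd_jacobian(operating_point.u, operating_point.v, params, laplacian)
    m = augmentation_factor * n
    dim = 2 * n + m
    A = np.zeros((dim, dim))
    A[: 2 * n, : 2 * n] = J
    e = params.e
    for blk in range(augmentation_factor):
        rows = slice(2 * n + blk * n, 2 * n + (blk + 1) * n)
        prev = slice(n, 2 * n) if blk == 0 else slice(2 * n + (blk - 1) * n, 2 * n + blk * n)
        A[rows, prev] += e * np.eye(n)
        A[rows, rows] += -e * np.eye(n)
    return np.eye(dim) + params.dt * A
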