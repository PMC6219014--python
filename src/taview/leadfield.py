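"""Lead-field (transfer matrix) construction, coarsening and uncertainty.

The forward map phi = L u relates transmembrane potentials on heart surface
nodes to body-surface electrode potentials.  L is built from the
equivalent-double-layer solution of the quasi-static Poisson equation in a
homogeneous unbounded medium: each source node carries a uniform dipole layer
over its barycentric vertex patch (area = one third of the incident triangle
areas, direction = outward vertex normal), and the potential it induces at a
field point r is, to first order in patch size,

    (1 / 4 pi sigma) * A * n . (r - p) / |r - p|^3.

Rows are sampled at the electrodes' nearest torso vertices and referenced to
the mean over all electrode rows (common-reference removal).  The systematic
error of ignoring the torso boundary is deliberately absorbed downstream into
the transfer-matrix uncertainty DeltaL, which the Bayesian inversion
estimates; full boundary-element correction is an extension point.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
from sklearn.cluster import KMeans

from .errors import GeometryError, InvalidArgumentError
from .mesh import ATRIAL, VENTRICULAR, ElectrodeSet, TriSurfaceMesh

DEFAULT_CONDUCTIVITY_S_PER_M = 0.2  # conventional lumped torso conductivity
DEFAULT_CLUSTER_SEED = 1905  # fixed so reduce_sources is reproducible

#: Minimum field-point-to-source distance, in units of sqrt(patch area).
_MIN_DISTANCE_FACTOR = 0.5


@dataclasses.dataclass(frozen=True)
class TransferMatrix:
    """Discretized lead-field map from source-node TMPs to electrode potentials."""

    entries: np.ndarray  # (n_rows, n_sources)
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    col_labels: np.ndarray  # region label per source column
    conductivity_S_per_m: float

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2:
            raise InvalidArgumentError("entries must be a 2-D matrix")
        if not np.all(np.isfinite(e)):
            raise InvalidArgumentError("transfer matrix entries must be finite")
        if len(self.row_ids) != e.shape[0] or len(self.col_ids) != e.shape[1]:
            raise InvalidArgumentError("row/col id counts must match entries shape")
        object.__setattr__(self, "entries", e)
        object.__setattr__(
            self, "col_labels", np.asarray(self.col_labels, dtype=np.int64)
        )

    @property
    def n_sources(self) -> int:
        return self.entries.shape[1]

    def region_block(self, label: int) -> np.ndarray:
        """Columns of one region, zero elsewhere (same shape as entries)."""
        out = np.zeros_like(self.entries)
        mask = self.col_labels == label
        out[:, mask] = self.entries[:, mask]
        return out

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("entries", data=self.entries)
            fh.create_dataset("row_ids", data=np.array(self.row_ids, dtype="S"))
            fh.create_dataset("col_ids", data=np.array(self.col_ids, dtype="S"))
            fh.create_dataset("col_labels", data=self.col_labels)
            fh.attrs["conductivity_S_per_m"] = self.conductivity_S_per_m

    @classmethod
    def load_h5(cls, path: str | Path) -> "TransferMatrix":
        with h5py.File(path, "r") as fh:
            return cls(
                entries=fh["entries"][()],
                row_ids=tuple(s.decode() for s in fh["row_ids"][()]),
                col_ids=tuple(s.decode() for s in fh["col_ids"][()]),
                col_labels=fh["col_labels"][()],
                conductivity_S_per_m=float(fh.attrs["conductivity_S_per_m"]),
            )

    def save_text(self, path: str | Path) -> None:
        header = "rows: " + " ".join(self.row_ids) + "\ncols: " + " ".join(self.col_ids)
        np.savetxt(path, self.entries, header=header)


@dataclasses.dataclass(frozen=True)
class TransferUncertainty:
    """Gaussian per-entry uncertainty model for DeltaL."""

    shape: tuple[int, int]
    entry_sd: float | np.ndarray = 0.0
    mean_offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        sd = np.asarray(self.entry_sd, dtype=float)
        if np.any(sd < 0):
            raise InvalidArgumentError("entry_sd must be >= 0")
        if self.mean_offset is not None:
            mo = np.asarray(self.mean_offset, dtype=float)
            if mo.shape != tuple(self.shape):
                raise InvalidArgumentError("mean_offset shape mismatch")
            object.__setattr__(self, "mean_offset", mo)


def dipole_potential(
    field_points: np.ndarray,
    source_points: np.ndarray,
    source_normals: np.ndarray,
    source_areas: np.ndarray,
    conductivity: float,
) -> np.ndarray:
    """Point-dipole-layer kernel matrix (field points x sources)."""
    r = field_points[:, None, :] - source_points[None, :, :]  # (F, S, 3)
    dist = np.linalg.norm(r, axis=2)
    min_ok = _MIN_DISTANCE_FACTOR * np.sqrt(np.maximum(source_areas, 1e-300))
    bad = dist < min_ok[None, :]
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise GeometryError(
            f"field point {i} lies within the near field of source patch {j} "
            f"(distance {dist[i, j]:.3g} mm)"
        )
    proj = np.einsum("fsk,sk->fs", r, source_normals)
    return source_areas[None, :] * proj / (4.0 * np.pi * conductivity * dist**3)


def compute_transfer_matrix(
    heart: TriSurfaceMesh,
    torso: TriSurfaceMesh,
    electrodes: ElectrodeSet,
    conductivity: float = DEFAULT_CONDUCTIVITY_S_PER_M,
) -> TransferMatrix:
    """Lead field at the 8 electrodes, common-reference removed.

    Each row corresponds to one electrode channel, referenced to the mean of
    all electrode rows, so adding a constant to all raw electrode potentials
    leaves the output unchanged.
    """
    if conductivity <= 0:
        raise InvalidArgumentError("conductivity must be > 0")
    field = torso.vertices[electrodes.nearest_vertex]
    K = dipole_potential(
        field,
        heart.vertices,
        heart.vertex_normals(),
        heart.vertex_areas(),
        conductivity,
    )
    K = K - K.mean(axis=0, keepdims=True)
    col_ids = tuple(f"src{i}" for i in range(heart.n_vertices))
    return TransferMatrix(
        entries=K,
        row_ids=tuple(electrodes.names),
        col_ids=col_ids,
        col_labels=heart.region_label.copy(),
        conductivity_S_per_m=float(conductivity),
    )


@dataclasses.dataclass(frozen=True)
class SourceReduction:
    """Fine-to-coarse aggregation produced by `reduce_sources`."""

    membership: np.ndarray  # (n_fine,) coarse index per fine node
    coarse_positions: np.ndarray  # (n_coarse, 3) cluster centroids, mm
    coarse_labels: np.ndarray  # (n_coarse,) region label per coarse node

    @property
    def n_coarse(self) -> int:
        return len(self.coarse_labels)

    def aggregate_matrix(self) -> np.ndarray:
        """0/1 membership indicator P, shape (n_fine, n_coarse); P @ 1 = 1."""
        P = np.zeros((len(self.membership), self.n_coarse))
        P[np.arange(len(self.membership)), self.membership] = 1.0
        return P


def reduce_sources(
    L: TransferMatrix,
    heart: TriSurfaceMesh,
    n_coarse: int,
    seed: int = DEFAULT_CLUSTER_SEED,
) -> tuple[TransferMatrix, SourceReduction]:
    """Aggregate fine source columns into n_coarse region-respecting clusters.

    K-means runs separately inside the atrial and ventricular vertex sets
    (fixed seed, deterministic); each coarse column is the *sum* of its member
    fine columns, so a spatially uniform TMP maps identically through the fine
    and coarse operators.  Coarse nodes are split between regions in
    proportion to fine node counts, at least one per region.
    """
    n_fine = L.n_sources
    if n_coarse < 2:
        raise InvalidArgumentError("n_coarse must be >= 2 (one node per region)")
    if n_coarse > n_fine:
        raise InvalidArgumentError(
            f"n_coarse={n_coarse} exceeds fine source count {n_fine}"
        )
    labels = L.col_labels
    n_atr = int(np.sum(labels == ATRIAL))
    n_ven = int(np.sum(labels == VENTRICULAR))
    if n_atr == 0 or n_ven == 0:
        raise InvalidArgumentError("both regions must be present to reduce")
    k_atr = int(round(n_coarse * n_atr / n_fine))
    k_atr = min(max(k_atr, 1), n_coarse - 1)
    k_atr = min(k_atr, n_atr)
    k_ven = min(n_coarse - k_atr, n_ven)
    k_atr = n_coarse - k_ven

    membership = np.empty(n_fine, dtype=np.int64)
    centers = []
    coarse_labels = []
    offset = 0
    for region, k in ((ATRIAL, k_atr), (VENTRICULAR, k_ven)):
        idx = np.where(labels == region)[0]
        pts = heart.vertices[idx]
        if k == len(idx):
            assign = np.arange(len(idx))
            ctr = pts
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            assign = km.fit_predict(pts)
            ctr = km.cluster_centers_
        membership[idx] = offset + assign
        centers.append(ctr)
        coarse_labels.extend([region] * k)
        offset += k

    red = SourceReduction(
        membership=membership,
        coarse_positions=np.vstack(centers),
        coarse_labels=np.array(coarse_labels, dtype=np.int64),
    )
    coarse_entries = L.entries @ red.aggregate_matrix()
    coarse = TransferMatrix(
        entries=coarse_entries,
        row_ids=L.row_ids,
        col_ids=tuple(f"coarse{i}" for i in range(red.n_coarse)),
        col_labels=red.coarse_labels,
        conductivity_S_per_m=L.conductivity_S_per_m,
    )
    return coarse, red


def sample_transfer_perturbation(unc: TransferUncertainty, seed: int) -> np.ndarray:
    """One i.i.d. Gaussian draw of DeltaL; reproducible under seed."""
    rng = np.random.default_rng(seed)
    sd = np.broadcast_to(np.asarray(unc.entry_sd, dtype=float), unc.shape)
    delta = rng.standard_normal(unc.shape) * sd
    if unc.mean_offset is not None:
        delta = delta + unc.mean_offset
    return delta
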