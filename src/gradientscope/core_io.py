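"""Domain types and plain-text readers/writers shared across the pipeline.

All on-disk formats are delimited text: tab-separated matrices without
headers (parcel order defined solely by the partition file), a two-column
partition table, CSV participant tables and YAML/JSON run configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NetworkPartition",
    "ConnectivityMatrix",
    "GradientSet",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "read_participants",
    "write_participants",
    "read_gradients",
    "write_gradients",
    "config_hash",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of each parcel to exactly one named functional network.

    ``parcel_ids`` fixes the row/column order of every matrix in a run;
    ``network_of`` maps each parcel to one of ``K >= 2`` non-empty networks.
    ``network_order`` is the canonical display order (defaults to order of
    first appearance).
    """

    parcel_ids: tuple[str, ...]
    network_of: tuple[str, ...]
    network_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.parcel_ids) != len(self.network_of):
            raise ValueError("parcel_ids and network_of must have equal length")
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("duplicate parcel ids in partition")
        seen: list[str] = []
        for name in self.network_of:
            if name not in seen:
                seen.append(name)
        order = self.network_order or tuple(seen)
        if set(order) != set(seen):
            raise ValueError("network_order must name exactly the networks present")
        object.__setattr__(self, "network_order", tuple(order))
        if self.n_networks < 2:
            raise ValueError("a partition needs at least 2 networks")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def n_networks(self) -> int:
        return len(self.network_order)

    def indices(self, network: str) -> np.ndarray:
        """Positional indices of the parcels belonging to ``network``."""
        if network not in self.network_order:
            raise KeyError(f"unknown network {network!r}")
        labels = np.asarray(self.network_of)
        return np.flatnonzero(labels == network)

    def sizes(self) -> dict[str, int]:
        return {net: int(self.indices(net).size) for net in self.network_order}

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered network pairs in canonical order (K·(K−1)/2)."""
        nets = self.network_order
        return [(nets[i], nets[j]) for i in range(len(nets)) for j in range(i + 1, len(nets))]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric parcel × parcel Pearson correlation matrix.

    Off-diagonal entries lie in [−1, 1]; the diagonal is stored as 1 but is
    excluded from every downstream transform (Fisher z of r = 1 is infinite).
    """

    values: np.ndarray
    parcel_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.isnan(values).any():
            raise ValueError("connectivity matrix contains NaN")
        asym = np.max(np.abs(values - values.T)) if values.size else 0.0
        if asym > 1e-10:
            raise ValueError(f"matrix asymmetry {asym:.3g} exceeds 1e-10")
        off = values[~np.eye(values.shape[0], dtype=bool)]
        if off.size and (off.min() < -1.0 - 1e-12 or off.max() > 1.0 + 1e-12):
            raise ValueError("off-diagonal correlations outside [-1, 1]")
        if not np.allclose(np.diag(values), 1.0, atol=1e-8):
            raise ValueError("diagonal must be 1")
        object.__setattr__(self, "values", values)
        ids = tuple(self.parcel_ids) or tuple(f"p{i}" for i in range(values.shape[0]))
        if len(ids) != values.shape[0]:
            raise ValueError("parcel_ids length does not match matrix size")
        object.__setattr__(self, "parcel_ids", ids)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GradientSet:
    """Parcels × components matrix of gradient scores.

    ``explained_variance`` holds the fraction of total affinity variance each
    component carries. After Procrustes alignment component order is fixed by
    the reference, so the fractions need not be non-increasing.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    aligned: bool = False

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        ev = np.asarray(self.explained_variance, dtype=float)
        if scores.ndim != 2:
            raise ValueError("scores must be 2-D (parcels × components)")
        if ev.ndim != 1 or ev.size != scores.shape[1]:
            raise ValueError("explained_variance must have one entry per component")
        if (ev < -1e-12).any():
            raise ValueError("explained variance fractions must be >= 0")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "explained_variance", ev)

    @property
    def n_parcels(self) -> int:
        return self.scores.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.scores.shape[1]


@dataclass
class RunConfig:
    """Tunable parameters of a full analysis run.

    Defaults reproduce the reference analysis: 0.95 row sparsity, cosine
    affinity kernel, ten gradients, three embedding dimensions for the
    eccentricity/dispersion metrics, 50 histogram bins and α = 0.05.
    """

    sparsity: float = 0.95
    kernel: str = "cosine"
    n_gradients: int = 10
    eccentricity_dims: int = 3
    n_bins: int = 50
    alpha: float = 0.05
    eccentricity_agg: str = "mean"  # or "sum_sq"
    signed_median_distance: bool = False
    gender_coding: dict = field(default_factory=lambda: {"female": 0, "male": 1})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.kernel != "cosine":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.n_gradients < 1:
            raise ValueError("n_gradients must be >= 1")
        if self.eccentricity_dims > self.n_gradients:
            raise ValueError(
                f"eccentricity_dims={self.eccentricity_dims} exceeds "
                f"n_gradients={self.n_gradients}"
            )
        if self.eccentricity_agg not in ("mean", "sum_sq"):
            raise ValueError("eccentricity_agg must be 'mean' or 'sum_sq'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the configuration (hex digest)."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path: str | Path, expected_parcels: int | None = None,
                parcel_ids: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Read a tab-delimited, headerless, square correlation matrix.

    Symmetrization is applied only when the asymmetry is within 1e-8 (text
    round-off); larger asymmetry raises.
    """
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is {values.shape[0]}×{values.shape[1]}, not square")
    if np.isnan(values).any():
        raise ValueError(f"{path}: matrix contains NaN cells")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > _SYM_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.3g} exceeds {_SYM_TOL}")
    values = (values + values.T) / 2.0
    if expected_parcels is not None and values.shape[0] != expected_parcels:
        raise ValueError(
            f"{path}: expected {expected_parcels} parcels, found {values.shape[0]}"
        )
    ids = tuple(parcel_ids) if parcel_ids is not None else ()
    return ConnectivityMatrix(values=values, parcel_ids=ids)


def write_matrix(matrix: ConnectivityMatrix | np.ndarray, path: str | Path) -> None:
    """Write a matrix as tab-delimited text at 12 significant digits."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    np.savetxt(path, values, delimiter="\t", fmt="%.12g")


def read_partition(path: str | Path) -> NetworkPartition:
    """Read a two-column TSV ``parcel_id<TAB>network`` (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["parcel_id", "network"],
                     dtype=str)
    if df["parcel_id"].duplicated().any():
        dups = df.loc[df["parcel_id"].duplicated(), "parcel_id"].tolist()
        raise ValueError(f"{path}: duplicated parcel ids {dups}")
    if df["network"].isna().any() or (df["network"].str.len() == 0).any():
        raise ValueError(f"{path}: empty network labels")
    return NetworkPartition(
        parcel_ids=tuple(df["parcel_id"]), network_of=tuple(df["network"])
    )


def write_partition(partition: NetworkPartition, path: str | Path) -> None:
    lines = [f"{p}\t{n}" for p, n in zip(partition.parcel_ids, partition.network_of)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read the CSV participant table (subject_id index column kept as column)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: participant table needs a subject_id column")
    return df


def write_participants(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_gradients(gset: GradientSet, path: str | Path) -> None:
    """Persist scores as TSV plus a JSON sidecar with variance/alignment."""
    path = Path(path)
    np.savetxt(path, gset.scores, delimiter="\t", fmt="%.12g")
    sidecar = {
        "explained_variance": [float(v) for v in gset.explained_variance],
        "aligned": bool(gset.aligned),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_gradients(path: str | Path) -> GradientSet:
    path = Path(path)
    scores = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return GradientSet(
        scores=scores,
        explained_variance=np.asarray(sidecar["explained_variance"], dtype=float),
        aligned=bool(sidecar["aligned"]),
    )
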