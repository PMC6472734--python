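"""Core data containers and delimited-text I/O.

Connectivity is stored subject-by-edge: one row per scan session, one column
per region pair, values in Fisher-z units (``atanh`` of the Pearson
correlation).  Edges are the strictly lower-triangular part of the symmetric
node-by-node matrix, vectorized column-major — pairs ``(i, j)`` with
``j < i``, ordered by ``j`` then ``i``.  This ordering is a documented
convention: any fixed bijection is statistically equivalent, but external
tools must match it to compare edge vectors element-wise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DIAGNOSES = ("HC", "MDD", "SCZ", "ASD", "OTHER")
DATASET_KINDS = ("multisite", "traveling")

#: metadata columns required for every dataset
META_COLUMNS = (
    "row_id",
    "participant_id",
    "site_id",
    "diagnosis",
    "dataset_kind",
    "session_id",
)


class ValidationError(ValueError):
    """Raised when a dataset, atlas or matrix violates a structural invariant."""


@dataclass(frozen=True)
class AtlasSpec:
    """Node list of a functional brain atlas.

    Node identifiers are 1-based in files and kept as given; coordinates, when
    present, are millimetres in MNI space.
    """

    node_ids: tuple
    node_names: tuple | None = None
    node_coords: np.ndarray | None = None

    def __post_init__(self):
        if len(self.node_ids) < 2:
            raise ValidationError("an atlas needs at least 2 nodes")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("atlas node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class EdgeIndex:
    """Fixed bijection between node pairs and edge-vector slots.

    ``pairs[e] = (i, j)`` with ``j < i`` (0-based); ordering is column-major
    over the lower triangle (sorted by ``j`` then ``i``).
    """

    n_nodes: int
    pairs: np.ndarray = field(repr=False)

    @property
    def n_edges(self) -> int:
        return self.pairs.shape[0]

    def labels(self) -> list[str]:
        """Edge labels ``n<i>_n<j>`` with 1-based node numbers."""
        return [f"n{i + 1}_n{j + 1}" for i, j in self.pairs]


def build_edge_index(n_nodes: int) -> EdgeIndex:
    """All unordered node pairs, exactly once, in the documented order.

    A 268-node atlas yields 268*267/2 = 35,778 edges.
    """
    if n_nodes < 2:
        raise ValidationError(f"need at least 2 nodes, got {n_nodes}")
    cols, rows = np.triu_indices(n_nodes, k=1)  # triu of (j, i) == tril order
    pairs = np.column_stack([rows, cols])
    order = np.lexsort((pairs[:, 0], pairs[:, 1]))  # by j then i
    return EdgeIndex(n_nodes=n_nodes, pairs=pairs[order])


def vectorize_matrix(sym_matrix: np.ndarray, edge_index: EdgeIndex,
                     atol: float = 1e-8) -> np.ndarray:
    """Lower-triangular vectorization of a symmetric matrix (diagonal ignored)."""
    m = np.asarray(sym_matrix, dtype=float)
    k = edge_index.n_nodes
    if m.shape != (k, k):
        raise ValidationError(f"matrix shape {m.shape} != ({k}, {k})")
    if not np.allclose(m, m.T, atol=atol, equal_nan=False):
        raise ValidationError("matrix is not symmetric within tolerance")
    return m[edge_index.pairs[:, 0], edge_index.pairs[:, 1]].copy()


def devectorize(edge_vector: np.ndarray, edge_index: EdgeIndex) -> np.ndarray:
    """Inverse of :func:`vectorize_matrix`; diagonal is set to zero."""
    v = np.asarray(edge_vector, dtype=float)
    if v.shape != (edge_index.n_edges,):
        raise ValidationError("edge vector length mismatch")
    m = np.zeros((edge_index.n_nodes, edge_index.n_nodes))
    i, j = edge_index.pairs[:, 0], edge_index.pairs[:, 1]
    m[i, j] = v
    m[j, i] = v
    return m


@dataclass
class ConnectivityDataset:
    """Subject/session-by-edge Fisher-z connectivity with row metadata.

    ``meta`` is a DataFrame with columns :data:`META_COLUMNS`; ``values`` is a
    float matrix with one row per metadata row, columns following
    ``edge_index``.
    """

    values: np.ndarray
    meta: pd.DataFrame
    edge_index: EdgeIndex

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.meta = self.meta.reset_index(drop=True)
        validate_dataset(self)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def subset(self, mask) -> "ConnectivityDataset":
        """Row subset by boolean mask or integer positions (metadata kept aligned)."""
        mask = np.asarray(mask)
        return ConnectivityDataset(
            values=self.values[mask],
            meta=self.meta.iloc[mask].reset_index(drop=True),
            edge_index=self.edge_index,
        )

    def sites(self) -> list[str]:
        return sorted(self.meta["site_id"].unique())


def validate_dataset(ds: ConnectivityDataset) -> None:
    if ds.values.ndim != 2:
        raise ValidationError("values must be a 2-D matrix")
    if ds.values.shape[0] != len(ds.meta):
        raise ValidationError(
            f"{ds.values.shape[0]} value rows but {len(ds.meta)} metadata rows"
        )
    missing = [c for c in META_COLUMNS if c not in ds.meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if ds.values.shape[1] != ds.edge_index.n_edges:
        raise ValidationError(
            f"{ds.values.shape[1]} columns != {ds.edge_index.n_edges} edges"
        )
    dup = ds.meta["row_id"][ds.meta["row_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate row_id: {sorted(dup.unique())}")
    bad_kind = set(ds.meta["dataset_kind"]) - set(DATASET_KINDS)
    if bad_kind:
        raise ValidationError(f"unknown dataset_kind values: {sorted(bad_kind)}")
    unknown = ~ds.meta["diagnosis"].isin(DIAGNOSES)
    if unknown.any():
        labels = sorted(ds.meta.loc[unknown, "diagnosis"].unique())
        warnings.warn(f"unknown diagnosis labels mapped to OTHER: {labels}")
        ds.meta.loc[unknown, "diagnosis"] = "OTHER"
    trav = ds.meta["dataset_kind"] == "traveling"
    if (ds.meta.loc[trav, "diagnosis"] != "HC").any():
        bad = ds.meta.loc[trav & (ds.meta["diagnosis"] != "HC"), "row_id"]
        raise ValidationError(
            f"traveling rows must be HC; offending rows: {list(bad)}"
        )
    nan_rows = np.flatnonzero(~np.isfinite(ds.values).all(axis=1))
    if len(nan_rows):
        bad = list(ds.meta["row_id"].iloc[nan_rows[:10]])
        raise ValidationError(
            f"{len(nan_rows)} rows contain non-finite values, e.g. {bad}"
        )


# ---------------------------------------------------------------------------
# file formats: TSV values (first column row_id, then edge labels), TSV
# metadata, TSV atlas, decomposition directory of TSV blocks + JSON manifest
# ---------------------------------------------------------------------------

def read_dataset(values_path, metadata_path, edge_index: EdgeIndex | None = None,
                 fisher_z_on_load: bool = False) -> ConnectivityDataset:
    """Load a dataset from a values TSV and a metadata TSV.

    Rows are matched by ``row_id``; set ``fisher_z_on_load`` for files holding
    raw correlation coefficients instead of Fisher-z values.
    """
    vals = pd.read_csv(values_path, sep="\t", dtype={"row_id": str})
    meta = pd.read_csv(
        metadata_path, sep="\t",
        dtype={c: str for c in META_COLUMNS if c != "session_id"},
    )
    if "row_id" not in vals.columns:
        raise ValidationError("values file lacks a row_id column")
    missing = set(vals["row_id"]) - set(meta["row_id"])
    if missing:
        raise ValidationError(
            f"metadata missing row_id(s): {sorted(missing)}"
        )
    extra = set(meta["row_id"]) - set(vals["row_id"])
    if extra:
        raise ValidationError(f"values missing row_id(s): {sorted(extra)}")
    meta = meta.set_index("row_id").loc[vals["row_id"]].reset_index()
    meta["session_id"] = meta["session_id"].astype(str)
    x = vals.drop(columns="row_id").to_numpy(dtype=float)
    if fisher_z_on_load:
        x = np.arctanh(np.clip(x, -1 + 1e-7, 1 - 1e-7))
    if edge_index is None:
        n_edges = x.shape[1]
        n_nodes = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
        if n_nodes * (n_nodes - 1) // 2 != n_edges:
            raise ValidationError(
                f"{n_edges} columns is not a triangular number; pass edge_index"
            )
        edge_index = build_edge_index(n_nodes)
    return ConnectivityDataset(values=x, meta=meta, edge_index=edge_index)


def write_dataset(ds: ConnectivityDataset, values_path, metadata_path) -> None:
    out = pd.DataFrame(ds.values, columns=ds.edge_index.labels())
    out.insert(0, "row_id", ds.meta["row_id"].to_numpy())
    out.to_csv(values_path, sep="\t", index=False, float_format="%.10g")
    ds.meta.to_csv(metadata_path, sep="\t", index=False)


def read_atlas(path) -> AtlasSpec:
    df = pd.read_csv(path, sep="\t")
    if "node_id" not in df.columns:
        raise ValidationError("atlas file lacks a node_id column")
    coords = None
    if {"x", "y", "z"} <= set(df.columns) and df[["x", "y", "z"]].notna().all().all():
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    names = tuple(df["node_name"]) if "node_name" in df.columns else None
    return AtlasSpec(node_ids=tuple(df["node_id"]), node_names=names,
                     node_coords=coords)


@dataclass
class BiasDecomposition:
    """Per-edge estimates of the site-difference decomposition.

    Each block maps a level (site, diagnosis or traveling participant) to an
    edge vector in Fisher-z units.  Measurement biases and each sampling-bias
    class sum to ~0 across sites, participant factors sum to ~0 across
    participants, and the healthy-control disorder factor is identically zero
    (HC is the baseline); these conventions remove the intercept ambiguity.
    """

    measurement_bias: dict[str, np.ndarray]
    sampling_bias_hc: dict[str, np.ndarray]
    sampling_bias_mdd: dict[str, np.ndarray]
    sampling_bias_scz: dict[str, np.ndarray]
    disorder_factor: dict[str, np.ndarray]
    participant_factor: dict[str, np.ndarray]
    intercept: np.ndarray
    residual_variance: np.ndarray
    lam: float

    _SUM_ZERO_BLOCKS = (
        "measurement_bias",
        "sampling_bias_hc",
        "sampling_bias_mdd",
        "sampling_bias_scz",
        "participant_factor",
    )

    def block(self, name: str) -> dict[str, np.ndarray]:
        return getattr(self, name)

    def n_edges(self) -> int:
        return self.intercept.shape[0]

    def constraint_residuals(self) -> dict[str, float]:
        """Max |sum over levels| per constrained block (0 for empty blocks)."""
        out = {}
        for name in self._SUM_ZERO_BLOCKS:
            blk = self.block(name)
            if blk:
                out[name] = float(
                    np.abs(np.sum(list(blk.values()), axis=0)).max()
                )
            else:
                out[name] = 0.0
        return out

    def check_constraints(self, tol: float = 1e-6) -> None:
        bad = {k: v for k, v in self.constraint_residuals().items() if v > tol}
        if bad:
            raise ValidationError(f"constraint residuals above {tol}: {bad}")
        if "HC" in self.disorder_factor and np.any(self.disorder_factor["HC"]):
            raise ValidationError("HC disorder factor must be identically zero")


def _block_frame(block: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame({k: v for k, v in block.items()}).T


def write_decomposition(decomp: BiasDecomposition, out_dir) -> None:
    """Write one TSV per factor block plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = {
        "measurement_bias": decomp.measurement_bias,
        "sampling_bias_hc": decomp.sampling_bias_hc,
        "sampling_bias_mdd": decomp.sampling_bias_mdd,
        "sampling_bias_scz": decomp.sampling_bias_scz,
        "disorder_factor": decomp.disorder_factor,
        "participant_factor": decomp.participant_factor,
    }
    for name, blk in blocks.items():
        df = _block_frame(blk)
        df.index.name = "level"
        df.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.10g")
    scalars = pd.DataFrame(
        {"intercept": decomp.intercept,
         "residual_variance": decomp.residual_variance}
    )
    scalars.to_csv(out / "per_edge.tsv", sep="\t", index=False,
                   float_format="%.10g")
    manifest = {
        "lambda": decomp.lam,
        "n_edges": decomp.n_edges(),
        "constraint_residuals": decomp.constraint_residuals(),
        "blocks": {k: sorted(v) for k, v in blocks.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_decomposition(in_dir) -> BiasDecomposition:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())

    def load(name):
        df = pd.read_csv(src / f"{name}.tsv", sep="\t", index_col="level")
        return {str(k): df.loc[k].to_numpy(dtype=float) for k in df.index}

    per_edge = pd.read_csv(src / "per_edge.tsv", sep="\t")
    return BiasDecomposition(
        measurement_bias=load("measurement_bias"),
        sampling_bias_hc=load("sampling_bias_hc"),
        sampling_bias_mdd=load("sampling_bias_mdd"),
        sampling_bias_scz=load("sampling_bias_scz"),
        disorder_factor=load("disorder_factor"),
        participant_factor=load("participant_factor"),
        intercept=per_edge["intercept"].to_numpy(),
        residual_variance=per_edge["residual_variance"].to_numpy(),
        lam=float(manifest["lambda"]),
    )


def concat_datasets(*datasets: ConnectivityDataset) -> ConnectivityDataset:
    """Row-wise concatenation of datasets sharing an edge index."""
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.edge_index.n_nodes != first.edge_index.n_nodes:
            raise ValidationError("cannot concatenate: edge index mismatch")
    return ConnectivityDataset(
        values=np.vstack([ds.values for ds in datasets]),
        meta=pd.concat([ds.meta for ds in datasets], ignore_index=True),
        edge_index=first.edge_index,
    )
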