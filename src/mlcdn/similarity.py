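"""Single-layer similarity networks over cell lines and drugs.

Cell line layers: copy-number status and mutation status are compared with
the Tanimoto coefficient; pathway-activity profiles with the Pearson
correlation.  Drug layers: structural fingerprints with Tanimoto, target
profiles with Jaccard (identical on binary data, kept as a named alias for
layer bookkeeping) and pan-cancer sensitivity profiles with pairwise-complete
Pearson.  Every network is a complete weighted graph; no sparsification is
applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BINARY, CONTINUOUS, FeatureMatrix, ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityNetwork",
    "pearson_similarity",
    "tanimoto_similarity",
    "jaccard_similarity",
    "build_csn",
    "build_dsn",
    "read_network",
    "write_network",
    "align_networks",
]

_CORRELATION_MEASURES = ("pearson", "tanimoto", "jaccard")


@dataclass
class SimilarityNetwork:
    """Symmetric entity x entity similarity matrix for one layer.

    ``measure`` is one of pearson / tanimoto / jaccard / snf; the first
    three have a unit diagonal, Pearson entries lie in [-1, 1] and
    Tanimoto/Jaccard in [0, 1].  SNF-fused networks are nonnegative but on
    their own (row-stochastic) scale.
    """

    entity_ids: list
    rho: np.ndarray
    layer_label: str
    measure: str

    def __post_init__(self) -> None:
        self.entity_ids = list(self.entity_ids)
        rho = np.asarray(self.rho, dtype=float)
        n = len(self.entity_ids)
        if rho.shape != (n, n):
            raise ValueError(f"rho shape {rho.shape} does not match {n} entities")
        if len(set(self.entity_ids)) != n:
            raise ValueError("duplicate entity ids in similarity network")
        if not np.isfinite(rho).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if np.abs(rho - rho.T).max(initial=0.0) > 1e-12:
            raise ValueError("similarity matrix is not symmetric (tolerance 1e-12)")
        if self.measure in _CORRELATION_MEASURES:
            if np.abs(np.diag(rho) - 1.0).max(initial=0.0) > 1e-9:
                raise ValueError(f"{self.measure} network must have a unit diagonal")
            lo = -1.0 if self.measure == "pearson" else 0.0
            if rho.min() < lo - 1e-9 or rho.max() > 1.0 + 1e-9:
                raise ValueError(f"{self.measure} entries out of [{lo}, 1]")
        elif self.measure == "snf":
            if rho.min() < 0:
                raise ValueError("fused network entries must be nonnegative")
        else:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.rho = rho
        self._index = {e: k for k, e in enumerate(self.entity_ids)}

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.entity_ids, columns=self.entity_ids)

    def aligned_rho(self, ids) -> np.ndarray:
        """Return the similarity submatrix in the order of ``ids``."""
        missing = [e for e in ids if e not in self._index]
        if missing:
            raise ValueError(f"entities missing from {self.layer_label!r} network: {missing}")
        idx = np.fromiter((self._index[e] for e in ids), dtype=int)
        return self.rho[np.ix_(idx, idx)]

    def subnetwork(self, ids) -> "SimilarityNetwork":
        return SimilarityNetwork(list(ids), self.aligned_rho(ids), self.layer_label, self.measure)


# ---------------------------------------------------------------------------
# measures


def pearson_similarity(
    m: FeatureMatrix,
    min_overlap: int = 3,
    layer_label: str = "path",
) -> SimilarityNetwork:
    """Pairwise Pearson correlation of entity profiles.

    Missing values (NaN) are handled pairwise-complete: each pair is
    correlated over its jointly observed features, requiring at least
    ``min_overlap`` of them.
    """
    X = m.values.to_numpy(dtype=float)
    ids = m.entity_ids
    n = X.shape[0]
    obs = np.isfinite(X)
    rho = np.eye(n)
    if obs.all():
        sd = X.std(axis=1, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(f"zero-variance profile for entity {ids[int(flat[0])]!r}")
        rho = np.corrcoef(X)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                joint = obs[i] & obs[j]
                k = int(joint.sum())
                if k < min_overlap:
                    raise ValueError(
                        f"pair ({ids[i]!r}, {ids[j]!r}) has only {k} jointly observed "
                        f"features (< min_overlap={min_overlap})"
                    )
                xi, xj = X[i, joint], X[j, joint]
                xi = xi - xi.mean()
                xj = xj - xj.mean()
                denom = np.sqrt((xi * xi).sum() * (xj * xj).sum())
                if denom == 0:
                    raise ValueError(
                        f"zero variance over the joint features of pair ({ids[i]!r}, {ids[j]!r})"
                    )
                rho[i, j] = rho[j, i] = float((xi * xj).sum() / denom)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return SimilarityNetwork(ids, rho, layer_label, "pearson")


def _binary_overlap_similarity(m: FeatureMatrix, measure: str, layer_label: str) -> SimilarityNetwork:
    if m.dtype_flag != BINARY:
        raise ValueError(f"{measure} similarity requires a binary FeatureMatrix")
    A = m.values.to_numpy(dtype=float)
    inter = A @ A.T
    counts = A.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    empty = union == 0
    if empty.any():
        logger.warning(
            "%d entity pairs share an empty feature union; similarity set to 0",
            int(np.triu(empty, k=1).sum()),
        )
    rho = np.divide(inter, union, out=np.zeros_like(inter), where=~empty)
    rho = np.clip(rho, 0.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return SimilarityNetwork(m.entity_ids, rho, layer_label, measure)


def tanimoto_similarity(m: FeatureMatrix, layer_label: str = "cnv") -> SimilarityNetwork:
    """Tanimoto coefficient |a AND b| / |a OR b| between binary rows.

    Pairs whose union is empty (both rows all-zero) are scored 0 with a
    warning; the diagonal is forced to 1.
    """
    return _binary_overlap_similarity(m, "tanimoto", layer_label)


def jaccard_similarity(m: FeatureMatrix, layer_label: str = "targ") -> SimilarityNetwork:
    """Jaccard index between binary rows; coincides with Tanimoto on binary
    data, kept as a named alias for layer bookkeeping."""
    return _binary_overlap_similarity(m, "jaccard", layer_label)


# ---------------------------------------------------------------------------
# layer dispatch

_CSN_LAYERS = {"cnv": "tanimoto", "mut": "tanimoto", "path": "pearson"}
_DSN_LAYERS = {"stru": "tanimoto", "targ": "jaccard", "sens": "pearson"}


def _check_entity_count(n: int, kind: str) -> None:
    if n < 3:
        raise ValueError(f"need at least 3 {kind}, got {n}")


def build_csn(layer: str, data: FeatureMatrix, min_overlap: int = 3) -> SimilarityNetwork:
    """Build a single-layer cell line similarity network.

    ``layer`` selects the measure: cnv/mut -> Tanimoto on binary status
    matrices, path -> Pearson on pathway-activity profiles.
    """
    if layer not in _CSN_LAYERS:
        raise ValueError(f"unknown cell-line layer {layer!r}; expected one of {sorted(_CSN_LAYERS)}")
    _check_entity_count(len(data.entity_ids), "cell lines")
    if _CSN_LAYERS[layer] == "tanimoto":
        return tanimoto_similarity(data, layer_label=layer)
    return pearson_similarity(data, min_overlap=min_overlap, layer_label=layer)


def build_dsn(
    layer: str,
    data: FeatureMatrix | ResponseMatrix,
    min_overlap: int = 3,
) -> SimilarityNetwork:
    """Build a single-layer drug similarity network.

    ``layer`` selects the measure: stru -> Tanimoto on fingerprints,
    targ -> Jaccard on target profiles, sens -> pairwise-complete Pearson on
    pan-cancer sensitivity profiles (drugs x cell lines; a cell line x drug
    :class:`ResponseMatrix` is transposed automatically).
    """
    if layer not in _DSN_LAYERS:
        raise ValueError(f"unknown drug layer {layer!r}; expected one of {sorted(_DSN_LAYERS)}")
    if layer == "sens":
        if isinstance(data, ResponseMatrix):
            data = FeatureMatrix(data.values.T, CONTINUOUS)
        obs_per_drug = np.isfinite(data.values.to_numpy()).sum(axis=1)
        low = np.flatnonzero(obs_per_drug < min_overlap)
        if low.size:
            raise ValueError(
                f"drug {data.entity_ids[int(low[0])]!r} observed in only "
                f"{int(obs_per_drug[low[0]])} cell lines (< {min_overlap})"
            )
        _check_entity_count(len(data.entity_ids), "drugs")
        return pearson_similarity(data, min_overlap=min_overlap, layer_label=layer)
    _check_entity_count(len(data.entity_ids), "drugs")
    if layer == "stru":
        return tanimoto_similarity(data, layer_label=layer)
    return jaccard_similarity(data, layer_label=layer)


def align_networks(networks: list[SimilarityNetwork]) -> list[SimilarityNetwork]:
    """Restrict networks built on different layers to their common entities
    (order taken from the first network); warns about dropped entities."""
    if not networks:
        raise ValueError("no networks supplied")
    common = [e for e in networks[0].entity_ids if all(e in n._index for n in networks[1:])]
    if not common:
        raise ValueError("networks share no entities")
    dropped = {e for n in networks for e in n.entity_ids} - set(common)
    if dropped:
        logger.warning("dropping %d entities absent from some layer: %s", len(dropped), sorted(dropped))
    return [n.subnetwork(common) for n in networks]


# ---------------------------------------------------------------------------
# serialization: square TSV + JSON metadata sidecar


def write_network(net: SimilarityNetwork, path, metadata: dict | None = None) -> None:
    path = Path(path)
    net.to_frame().to_csv(path, sep="\t")
    meta = {"layer_label": net.layer_label, "measure": net.measure}
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_network(path) -> SimilarityNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValueError("network file must be square with matching row/column ids")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        layer, measure = meta.get("layer_label", "unknown"), meta.get("measure", "snf")
    else:
        logger.warning("no metadata sidecar for %s; assuming an SNF-fused network", path)
        layer, measure = "unknown", "snf"
    return SimilarityNetwork(list(df.index), df.to_numpy(), layer, measure)
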