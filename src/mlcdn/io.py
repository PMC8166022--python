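"""Input/output and preprocessing for drug-response network modelling.

This module houses the three tabular containers the rest of the package is
built on -- :class:`FeatureMatrix` (one data layer: expression, copy-number
status, mutation status, fingerprints, targets, pathway activities),
:class:`ResponseMatrix` (cell line x drug normalized IC50 with an
observed-entry mask) and :class:`PathwayCollection` (GMT gene sets) -- plus
the preprocessing steps applied before any similarity network is built:
global IC50 z-normalization, copy-number binarization, invariant-feature
removal, pathway activity scoring, cross-cohort homogenization and optional
SMILES fingerprinting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
BINARY = "binary"

__all__ = [
    "FeatureMatrix",
    "ResponseMatrix",
    "PathwayCollection",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_response_matrix",
    "write_response_matrix",
    "read_gmt",
    "normalize_ic50",
    "binarize_cnv",
    "drop_invariant_features",
    "pathway_activity",
    "cohort_homogenize",
    "smiles_to_fingerprints",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} labels: {dups}")


class FeatureMatrix:
    """An entities x features table for one data layer.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are entities (cell lines, drugs or samples), columns are
        features (genes, pathways, fingerprint bits, targets).
    dtype_flag : {"continuous", "binary"}
        Binary matrices must contain only 0/1 and no missing values.
        Continuous matrices may contain NaN (e.g. pan-cancer sensitivity
        profiles) but no entity row may be entirely missing.
    """

    def __init__(self, values: pd.DataFrame, dtype_flag: str):
        if dtype_flag not in (CONTINUOUS, BINARY):
            raise ValueError(f"dtype_flag must be 'continuous' or 'binary', got {dtype_flag!r}")
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        _check_unique(values.index, "entity")
        _check_unique(values.columns, "feature")
        vals = values.astype(float)
        arr = vals.to_numpy()
        if dtype_flag == BINARY:
            bad = ~((arr == 0.0) | (arr == 1.0))
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValueError(
                    f"non-binary value {arr[i, j]!r} at entity {vals.index[i]!r}, "
                    f"feature {vals.columns[j]!r}"
                )
        else:
            all_missing = ~np.isfinite(arr)
            if arr.shape[1] and all_missing.all(axis=1).any():
                row = vals.index[int(np.argmax(all_missing.all(axis=1)))]
                raise ValueError(f"entity row entirely missing: {row!r}")
        self.values = vals
        self.dtype_flag = dtype_flag

    @property
    def entity_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.shape
        return f"FeatureMatrix({n} entities x {p} features, {self.dtype_flag})"


class ResponseMatrix:
    """Cell line x drug response matrix with an observed-entry mask.

    Missing responses are stored as NaN; ``observed_mask`` marks the set of
    observed cell line-drug pairs over which all prediction sums run.
    ``normalization_meta`` records the (mean, sd) removed by
    :func:`normalize_ic50`, or ``None`` for raw values.
    """

    def __init__(self, values: pd.DataFrame, normalization_meta: tuple[float, float] | None = None):
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        _check_unique(values.index, "cell line")
        _check_unique(values.columns, "drug")
        self.values = values.astype(float)
        self.normalization_meta = normalization_meta

    @property
    def cell_ids(self) -> list:
        return list(self.values.index)

    @property
    def drug_ids(self) -> list:
        return list(self.values.columns)

    @property
    def observed_mask(self) -> pd.DataFrame:
        return self.values.notna() & np.isfinite(self.values.fillna(np.nan))

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.to_numpy().sum())

    def observed_values(self) -> np.ndarray:
        arr = self.values.to_numpy()
        return arr[np.isfinite(arr)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, d = self.values.shape
        return f"ResponseMatrix({n} cell lines x {d} drugs, {self.n_observed} observed)"


@dataclass
class PathwayCollection:
    """Named gene sets (e.g. MSigDB canonical pathways)."""

    gene_sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __iter__(self):
        return iter(self.gene_sets.items())


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path) -> pd.DataFrame:
    # TSV by default; comma autodetected by the python-engine sniffer
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_feature_matrix(path, dtype_flag: str = CONTINUOUS) -> FeatureMatrix:
    """Read a delimited entities x features table (header row = feature ids,
    first column = entity ids)."""
    return FeatureMatrix(_read_table(path), dtype_flag)


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    m.values.to_csv(path, sep="\t")


def read_response_matrix(path) -> ResponseMatrix:
    """Read a cell line x drug response table; 'NA' or empty cells are missing."""
    return ResponseMatrix(_read_table(path))


def write_response_matrix(r: ResponseMatrix, path) -> None:
    r.values.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path) -> PathwayCollection:
    """Parse a GMT file: one pathway per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    gene_sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if name in gene_sets:
                raise ValueError(f"duplicate pathway id {name!r} at line {lineno}")
            if not genes:
                raise ValueError(f"pathway {name!r} at line {lineno} has no genes")
            gene_sets[name] = genes
            descriptions[name] = desc
    return PathwayCollection(gene_sets, descriptions)


# ---------------------------------------------------------------------------
# preprocessing


def normalize_ic50(raw: ResponseMatrix | pd.DataFrame) -> ResponseMatrix:
    """Z-normalize a response matrix with ONE global (mean, sd).

    The mean and (sample) standard deviation are computed over all observed
    entries of the matrix and removed from every entry, giving all drugs the
    same baseline and range within a dataset.  The observed mask is
    unchanged; (mean, sd) is stored in ``normalization_meta``.
    """
    values = raw.values if isinstance(raw, ResponseMatrix) else pd.DataFrame(raw).astype(float)
    arr = values.to_numpy()
    obs = arr[np.isfinite(arr)]
    if obs.size < 2:
        raise ValueError(f"need at least 2 observed values to normalize, got {obs.size}")
    mean = float(np.mean(obs))
    sd = float(np.std(obs, ddof=1))
    if sd == 0.0:
        raise ValueError("observed responses have zero variance; cannot normalize")
    return ResponseMatrix((values - mean) / sd, normalization_meta=(mean, sd))


def binarize_cnv(copy_number: FeatureMatrix | pd.DataFrame) -> FeatureMatrix:
    """Convert per-gene total copy numbers into amplification/deletion calls.

    A gene is called altered (1) when its total copy number is >= 8
    (amplification) or exactly 0 (deletion); copy numbers strictly between 0
    and 8 are wild type (0).
    """
    values = copy_number.values if isinstance(copy_number, FeatureMatrix) else pd.DataFrame(copy_number)
    values = values.astype(float)
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("copy-number matrix contains missing values")
    bad = (arr < 0) | (arr != np.floor(arr))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"invalid copy number {arr[i, j]!r} at entity {values.index[i]!r}, "
            f"gene {values.columns[j]!r} (must be a nonnegative integer)"
        )
    calls = ((arr >= 8) | (arr == 0)).astype(float)
    return FeatureMatrix(pd.DataFrame(calls, index=values.index, columns=values.columns), BINARY)


def drop_invariant_features(m: FeatureMatrix) -> FeatureMatrix:
    """Remove binary features that are 0 across every entity (column order
    otherwise preserved)."""
    if m.dtype_flag != BINARY:
        raise ValueError("drop_invariant_features expects a binary FeatureMatrix")
    keep = m.values.sum(axis=0) > 0
    if not keep.any():
        raise ValueError("no informative features: every column is all-zero")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d invariant (all-zero) features", dropped)
    return FeatureMatrix(m.values.loc[:, keep], BINARY)


def pathway_activity(
    expr: FeatureMatrix,
    pathways: PathwayCollection,
    min_genes: int = 3,
) -> FeatureMatrix:
    """Score per-sample pathway activity from a gene expression matrix.

    Each gene is z-scored across samples (sample sd); the activity of a
    pathway in a sample is the mean z-score of its member genes present in
    the matrix.  Pathways with fewer than ``min_genes`` matched genes are
    dropped.  A gene with zero variance across samples gets z = 0 (logged)
    so it neither adds nor removes signal.
    """
    vals = expr.values
    arr = vals.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("expression matrix contains missing values; not supported")
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    zero_var = sd == 0
    if zero_var.any():
        logger.info("%d genes with zero variance across samples; z-score set to 0", int(zero_var.sum()))
    safe_sd = np.where(zero_var, 1.0, sd)
    z = (arr - mu) / safe_sd
    z[:, zero_var] = 0.0

    col_pos = {g: k for k, g in enumerate(vals.columns)}
    scores: dict[str, np.ndarray] = {}
    for pid, genes in pathways:
        idx = [col_pos[g] for g in vals.columns if g in genes]
        if len(idx) < min_genes:
            logger.debug("pathway %s dropped: %d < %d matched genes", pid, len(idx), min_genes)
            continue
        scores[pid] = z[:, idx].mean(axis=1)
    if not scores:
        raise ValueError(f"no pathway retained with at least {min_genes} matched genes")
    return FeatureMatrix(pd.DataFrame(scores, index=vals.index), CONTINUOUS)


def cohort_homogenize(cohorts: Sequence[FeatureMatrix]) -> list[FeatureMatrix]:
    """Restrict cohorts to their common genes and standardize each gene
    within each cohort (location-scale adjustment).

    Downstream similarities are correlations of pathway-activity profiles,
    which are invariant to the per-cohort location and scale removed here.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts to homogenize")
    sets = [set(c.feature_ids) for c in cohorts]
    common = [g for g in cohorts[0].feature_ids if all(g in s for s in sets[1:])]
    if not common:
        raise ValueError("empty gene intersection across cohorts")
    out = []
    for c in cohorts:
        sub = c.values.loc[:, common]
        arr = sub.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("cohort contains missing values; not supported")
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
        zero = sd == 0
        if zero.any():
            logger.info("%d constant genes within a cohort set to 0 after centering", int(zero.sum()))
        z = (arr - mu) / np.where(zero, 1.0, sd)
        z[:, zero] = 0.0
        out.append(FeatureMatrix(pd.DataFrame(z, index=sub.index, columns=sub.columns), CONTINUOUS))
    return out


def smiles_to_fingerprints(
    smiles: Iterable[tuple[str, str]],
    n_bits: int = 1024,
    radius: int = 2,
) -> FeatureMatrix:
    """Hash SMILES strings into extended-connectivity (Morgan) fingerprints.

    Unparseable SMILES are excluded with a warning.  Requires the optional
    rdkit backend; without it, supply a precomputed fingerprint matrix via
    :func:`read_feature_matrix` instead.
    """
    try:
        from rdkit import Chem
        from rdkit import RDLogger
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "rdkit is not installed; install the 'chem' extra or supply a "
            "precomputed fingerprint matrix with read_feature_matrix(..., 'binary')"
        ) from exc
    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows, ids = [], []
    for drug_id, smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("unparseable SMILES for %r: %r (excluded)", drug_id, smi)
            continue
        rows.append(np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=float))
        ids.append(drug_id)
    if not rows:
        raise ValueError("no parseable SMILES strings supplied")
    df = pd.DataFrame(np.vstack(rows), index=ids, columns=[f"bit{i}" for i in range(n_bits)])
    return FeatureMatrix(df, BINARY)


def read_smiles_list(path) -> list[tuple[str, str]]:
    """Read a two-column (id, SMILES) tab-separated file with no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "smiles"], dtype=str)
    return list(df.itertuples(index=False, name=None))
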