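"""Containers and I/O for expression atlases, phenotype maps and distance matrices.

The central object is :class:`ExpressionAtlas`, a region x gene matrix of
normalized expression values with optional region centroid coordinates and an
optional two-level region classification (e.g. cortex / non-cortex).  All
readers are id-based: phenotypes and distance matrices are aligned to an atlas
by region identifier, never by row position.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionAtlas",
    "PhenotypeMap",
    "DistanceMatrix",
    "load_expression",
    "write_expression",
    "load_coordinates",
    "load_phenotype",
    "write_phenotype",
    "load_distance_matrix",
    "write_distance_matrix",
    "apply_quality_filter",
    "compute_distance_matrix",
    "write_enrichment_table",
    "read_enrichment_table",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass
class ExpressionAtlas:
    """Region x gene matrix of normalized expression.

    Parameters
    ----------
    expression
        DataFrame indexed by region id with gene ids as columns.  Missing
        measurements are encoded as NaN.
    coordinates
        Optional DataFrame of region centroids (one row per region, columns
        x/y/z in mm).  Required for distance-based features.
    region_class
        Optional Series mapping region id to a class label, used by the
        two-class differential-expression diagnostic.
    """

    expression: pd.DataFrame
    coordinates: pd.DataFrame | None = None
    region_class: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.expression.index, "region")
        _check_unique(self.expression.columns, "gene")
        self.expression = self.expression.astype(float)
        if self.coordinates is not None:
            self.coordinates = self.coordinates.loc[self.expression.index]
            if self.coordinates.shape[0] != self.expression.shape[0]:
                raise ValueError("coordinates must have one row per region")
        if self.region_class is not None:
            self.region_class = self.region_class.loc[self.expression.index]

    @property
    def region_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def values(self) -> np.ndarray:
        return self.expression.to_numpy()

    @property
    def n_regions(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset_genes(self, genes) -> "ExpressionAtlas":
        return ExpressionAtlas(
            self.expression.loc[:, list(genes)],
            coordinates=self.coordinates,
            region_class=self.region_class,
        )


@dataclass
class PhenotypeMap:
    """One real value per region (a spatial brain phenotype, SBP)."""

    values: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "region")
        self.values = self.values.astype(float)

    @property
    def region_ids(self) -> pd.Index:
        return self.values.index

    def align_to(self, atlas: ExpressionAtlas, min_overlap: int = 3) -> pd.Series:
        """Values for regions shared with *atlas*, in atlas order.

        Raises if fewer than *min_overlap* overlapping regions carry finite
        values: a correlation over fewer points is undefined.
        """
        common = atlas.region_ids.intersection(self.values.index)
        vals = self.values.loc[common]
        if int(np.isfinite(vals.to_numpy()).sum()) < min_overlap:
            raise ValueError(
                f"phenotype overlaps atlas in {len(common)} regions; "
                f"need >= {min_overlap} finite values"
            )
        return vals


@dataclass
class DistanceMatrix:
    """Symmetric region x region Euclidean distance matrix (mm)."""

    d: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.d.index, "region")
        if not self.d.index.equals(self.d.columns):
            raise ValueError("distance matrix rows and columns must carry the same ids")
        a = self.d.to_numpy(dtype=float)
        if not np.allclose(a, a.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.nanmin(a) < 0:
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def region_ids(self) -> pd.Index:
        return self.d.index

    def upper_pairs(self):
        """(i_idx, j_idx, distances) over the unordered region pairs."""
        a = self.d.to_numpy(dtype=float)
        iu = np.triu_indices(a.shape[0], k=1)
        return iu[0], iu[1], a[iu]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, index_col=0, **kw)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"failed to parse {path}: {exc}") from exc


def load_expression(path, coordinates_path=None, region_class_path=None) -> ExpressionAtlas:
    """Read a region x gene expression matrix from TSV/CSV.

    First column holds region ids, header row gene ids; empty cells are
    treated as missing.  Optional side files supply coordinates (region, x, y,
    z) and region class labels (region, label).
    """
    df = _read_table(path)
    coords = load_coordinates(coordinates_path) if coordinates_path else None
    rclass = None
    if region_class_path:
        rc = _read_table(region_class_path)
        rclass = rc.iloc[:, 0]
    return ExpressionAtlas(df, coordinates=coords, region_class=rclass)


def write_expression(atlas: ExpressionAtlas, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    atlas.expression.to_csv(path, sep=sep, float_format="%.10g")


def load_coordinates(path) -> pd.DataFrame:
    coords = _read_table(path)
    if coords.shape[1] != 3:
        raise ValueError(f"coordinates file must have 3 value columns, got {coords.shape[1]}")
    return coords.astype(float)


def load_phenotype(path) -> PhenotypeMap:
    df = _read_table(path)
    if df.shape[1] != 1:
        raise ValueError(f"phenotype file must have exactly one value column, got {df.shape[1]}")
    return PhenotypeMap(df.iloc[:, 0])


def write_phenotype(phenotype: PhenotypeMap, path, name: str = "value") -> None:
    phenotype.values.rename(name).to_frame().to_csv(path, sep="\t", float_format="%.10g")


def load_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix(_read_table(path))


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.d.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def apply_quality_filter(
    atlas: ExpressionAtlas,
    gene_threshold: float = 0.5,
    region_threshold: float = 0.5,
) -> ExpressionAtlas:
    """Drop poorly sampled genes, then poorly sampled regions.

    A gene is kept if it is observed in at least ``gene_threshold`` of
    regions; afterwards a region is kept if it retains at least
    ``region_threshold`` of the surviving genes.  The gene pass runs first,
    so a region's completeness is judged against the filtered gene set.
    """
    for name, t in (("gene_threshold", gene_threshold), ("region_threshold", region_threshold)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {t}")
    expr = atlas.expression
    gene_frac = expr.notna().mean(axis=0)
    keep_genes = gene_frac >= gene_threshold
    if not keep_genes.any():
        raise ValueError("quality filter removed every gene")
    expr = expr.loc[:, keep_genes]
    region_frac = expr.notna().mean(axis=1)
    keep_regions = region_frac >= region_threshold
    if not keep_regions.any():
        raise ValueError("quality filter removed every region")
    expr = expr.loc[keep_regions]
    n_g, n_r = (~keep_genes).sum(), (~keep_regions).sum()
    if n_g or n_r:
        logger.info("quality filter removed %d genes and %d regions", n_g, n_r)
    coords = atlas.coordinates.loc[expr.index] if atlas.coordinates is not None else None
    rclass = atlas.region_class.loc[expr.index] if atlas.region_class is not None else None
    return ExpressionAtlas(expr, coordinates=coords, region_class=rclass)


def compute_distance_matrix(atlas: ExpressionAtlas) -> DistanceMatrix:
    """Pairwise Euclidean distances (mm) between region centroids."""
    if atlas.coordinates is None:
        raise ValueError("atlas has no coordinates; cannot compute distances")
    d = squareform(pdist(atlas.coordinates.to_numpy(dtype=float)))
    if np.any(d[np.triu_indices_from(d, k=1)] == 0.0):
        warnings.warn("some regions share identical coordinates (zero distance)")
    ids = atlas.region_ids
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))


RESULT_COLUMNS = ["category_id", "name", "size", "score", "p", "q", "null_kind"]


def write_enrichment_table(results: pd.DataFrame, path, config: dict | None = None) -> None:
    """Write an enrichment result table as TSV sorted by p, plus a JSON sidecar.

    The sidecar records the full run configuration (including seeds) so that a
    run can be reproduced bit-identically from it.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    out = results[RESULT_COLUMNS].sort_values(["p", "category_id"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"config": config or {}}, indent=2, sort_keys=True, default=str))


def read_enrichment_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
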