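"""Null-phenotype ensembles: i.i.d. random maps and spatial-lag surrogates.

Two kinds of randomized spatial brain phenotype (SBP) are generated:

* SBP-random: independent standard-normal values per region;
* SBP-spatial: spatially autocorrelated maps from the spatial-lag (SAR)
  model u = (I - rho W)^-1 eps, with W_ij = exp(-d_ij / d0) off the diagonal
  and rows normalized to unit sum.  rho in [0, 1) sets autocorrelation
  strength relative to noise (default 0.8) and d0 the characteristic length
  scale in mm.

d0 is estimated from data by fitting the three-parameter exponential to
all-gene correlated gene expression (CGE) versus distance and taking the
fitted decay length.

Every ensemble carries a JSON-serializable spec (kind, parameters, seed) from
which it can be regenerated bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .atlas import DistanceMatrix, ExpressionAtlas
from .scoring import ExpDecayFit, fit_exp_decay

__all__ = [
    "SpatialLagParams",
    "NullPhenotypeEnsemble",
    "generate_random_maps",
    "generate_spatial_lag_maps",
    "fit_spatial_scale",
    "all_gene_cge",
]


@dataclass(frozen=True)
class SpatialLagParams:
    """Spatial-lag model parameters: strength rho in [0, 1), scale d0 > 0 mm."""

    rho: float = 0.8
    d0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.d0 <= 0:
            raise ValueError(f"d0 must be positive, got {self.d0}")


@dataclass
class NullPhenotypeEnsemble:
    """Bank of surrogate phenotype maps (regions x n_null), column-standardized."""

    region_ids: pd.Index
    maps: np.ndarray
    spec: dict

    def __post_init__(self) -> None:
        self.region_ids = pd.Index(self.region_ids)
        if self.maps.shape[0] != len(self.region_ids):
            raise ValueError("ensemble maps not aligned to region ids")

    @property
    def n_null(self) -> int:
        return self.maps.shape[1]

    def align_to(self, atlas: ExpressionAtlas) -> np.ndarray:
        if not self.region_ids.equals(atlas.region_ids):
            if not set(atlas.region_ids) <= set(self.region_ids):
                raise ValueError("ensemble does not cover the atlas regions")
            pos = self.region_ids.get_indexer(atlas.region_ids)
            return self.maps[pos]
        return self.maps

    def save(self, path) -> None:
        """Persist as TSV matrix plus a JSON spec sidecar."""
        pd.DataFrame(
            self.maps, index=self.region_ids,
            columns=[f"map{i}" for i in range(self.n_null)],
        ).to_csv(path, sep="\t", float_format="%.10g")
        Path(str(path) + ".json").write_text(json.dumps(self.spec, indent=2, sort_keys=True))


def _standardize_columns(m: np.ndarray) -> np.ndarray:
    m = m - m.mean(axis=0, keepdims=True)
    sd = m.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return m / sd


def generate_random_maps(region_ids, n_null: int, seed: int) -> NullPhenotypeEnsemble:
    """SBP-random ensemble: i.i.d. standard-normal value per region per map."""
    if n_null < 1:
        raise ValueError(f"n_null must be >= 1, got {n_null}")
    region_ids = pd.Index(region_ids)
    rng = np.random.default_rng(seed)
    maps = _standardize_columns(rng.standard_normal((len(region_ids), n_null)))
    return NullPhenotypeEnsemble(
        region_ids, maps, spec={"kind": "random", "n_null": n_null, "seed": int(seed)}
    )


def _weight_matrix(d: np.ndarray, d0: float) -> np.ndarray:
    w = np.exp(-d / d0)
    np.fill_diagonal(w, 0.0)
    row = w.sum(axis=1, keepdims=True)
    if np.any(row == 0):
        raise ValueError("weight matrix has an all-zero row; d0 too small for these distances")
    return w / row


def generate_spatial_lag_maps(
    distances: DistanceMatrix,
    params: SpatialLagParams,
    n_null: int,
    seed: int,
    standardize: bool = True,
) -> NullPhenotypeEnsemble:
    """SBP-spatial ensemble from the spatial-lag model u = (I - rho W)^-1 eps.

    Row normalization of W bounds its spectral radius by 1, so I - rho W is
    invertible for every rho < 1.  Columns are standardized by default
    (set ``standardize=False`` to inspect the raw SAR covariance).
    """
    if n_null < 1:
        raise ValueError(f"n_null must be >= 1, got {n_null}")
    d = distances.d.to_numpy(dtype=float)
    w = _weight_matrix(d, params.d0)
    a = np.eye(len(d)) - params.rho * w
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((len(d), n_null))
    try:
        maps = linalg.solve(a, eps)
    except linalg.LinAlgError as exc:
        raise ValueError(f"I - rho W is singular at rho={params.rho}") from exc
    if standardize:
        maps = _standardize_columns(maps)
    return NullPhenotypeEnsemble(
        distances.region_ids,
        maps,
        spec={
            "kind": "spatial_lag",
            "rho": params.rho,
            "d0": params.d0,
            "n_null": n_null,
            "seed": int(seed),
            "standardized": bool(standardize),
        },
    )


def all_gene_cge(atlas: ExpressionAtlas, distances: DistanceMatrix) -> pd.DataFrame:
    """(distance, CGE) per region pair, CGE computed across all genes."""
    expr = atlas.expression.loc[distances.region_ids]
    x = expr.to_numpy(dtype=float)
    if np.isfinite(x).all():
        c = np.corrcoef(x)
    else:
        c = pd.DataFrame(x.T).corr(min_periods=3).to_numpy()
    i_idx, j_idx, d = distances.upper_pairs()
    cge = c[i_idx, j_idx]
    ok = np.isfinite(cge)
    return pd.DataFrame({"d": d[ok], "cge": cge[ok]})


def fit_spatial_scale(
    atlas: ExpressionAtlas,
    distances: DistanceMatrix,
    weak_r2: float = 0.1,
) -> ExpDecayFit:
    """Estimate the expression autocorrelation scale d0 from all-gene CGE(d).

    Fits CGE(d) = A exp(-d / lambda) + B and returns the full fit; the
    estimated d0 is the fitted decay length ``lam``.  A weak fit
    (R2 < *weak_r2*, e.g. spatially unstructured data) is returned with
    ``converged=False`` rather than trusted silently.
    """
    pairs = all_gene_cge(atlas, distances)
    try:
        fit = fit_exp_decay(pairs["d"], pairs["cge"])
    except ValueError as exc:
        raise ValueError(f"cannot estimate spatial scale: {exc}") from exc
    if not np.isfinite(fit.lam) or fit.lam <= 0:
        raise ValueError(f"degenerate spatial-scale fit: lambda={fit.lam}")
    if fit.r2 < weak_r2:
        fit.converged = False
    return fit
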