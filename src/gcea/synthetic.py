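"""Synthetic expression atlases with controlled coexpression and spatial structure.

The generator emulates the statistical structure that drives category-level
false positives in atlas GCEA, without any real data:

* each category ``c`` owns a latent spatial map ``L_c`` -- i.i.d. normal
  across regions, or a Gaussian process with exact exponential correlation
  exp(-d / ell) when an autocorrelation length ``ell`` is set;
* a member gene is ``w * L_c + sqrt(1 - w^2) * noise + gamma * G``, where
  ``G`` is one shared smooth linear gradient across the coordinate box and
  ``gamma`` the gradient strength, so the population pairwise correlation
  within a category is w^2 (at gamma = 0, unit noise);
* filler genes are pure noise plus the gradient term.

All genes are standardized across regions.  The exponential-covariance GP is
used for latents (rather than the spatial-lag surrogate generator) because
its correlation length is exactly ``ell``, giving an analytic target for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .atlas import ExpressionAtlas, PhenotypeMap
from .ontology import Category, CategoryTable

__all__ = [
    "CategorySpec",
    "SyntheticAtlasSpec",
    "make_synthetic_atlas",
    "make_random_categories",
    "make_gradient_aligned_phenotype",
]


@dataclass(frozen=True)
class CategorySpec:
    """One synthetic category: size s, coexpression weight w in [0, 1], and
    an optional spatial autocorrelation length ell (mm)."""

    size: int
    w: float = 0.0
    ell: float | None = None

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"category size must be >= 2, got {self.size}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"coexpression weight must lie in [0, 1], got {self.w}")
        if self.ell is not None and self.ell <= 0:
            raise ValueError(f"autocorrelation length must be positive, got {self.ell}")


@dataclass
class SyntheticAtlasSpec:
    """Recipe for a synthetic region x gene atlas (all sizes in mm)."""

    n_regions: int = 100
    n_genes: int = 2000
    coordinate_box: float = 10.0
    categories: list[CategorySpec] = field(default_factory=list)
    noise_sd: float = 1.0
    gradient_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be nonnegative")
        total = sum(c.size for c in self.categories)
        if total > self.n_genes:
            raise ValueError(
                f"category sizes sum to {total} > n_genes = {self.n_genes}"
            )


def _gp_exponential(
    dist: np.ndarray, ell: float, rng: np.random.Generator, n_draws: int = 1
) -> np.ndarray:
    """(n_regions, n_draws) draws from a GP with correlation exp(-d / ell)
    (tiny jitter on the diagonal for numerical positive-definiteness)."""
    k = np.exp(-dist / ell) + 1e-9 * np.eye(dist.shape[0])
    chol = np.linalg.cholesky(k)
    return chol @ rng.standard_normal((dist.shape[0], n_draws))


def make_synthetic_atlas(
    spec: SyntheticAtlasSpec,
    return_gradient: bool = False,
) -> tuple[ExpressionAtlas, CategoryTable] | tuple[ExpressionAtlas, CategoryTable, np.ndarray]:
    """Generate an atlas and its category table from a :class:`SyntheticAtlasSpec`.

    With ``return_gradient=True`` the shared gradient map G is returned as a
    third element (ground truth for alignment checks)."""
    rng = np.random.default_rng(spec.seed)
    coords = rng.uniform(0.0, spec.coordinate_box, size=(spec.n_regions, 3))
    dist = squareform(pdist(coords))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    grad = coords @ direction
    grad = (grad - grad.mean()) / grad.std()

    x = np.empty((spec.n_regions, spec.n_genes))
    cats: list[Category] = []
    gene_ids = [f"g{j:05d}" for j in range(spec.n_genes)]
    pos = 0
    for i, cs in enumerate(spec.categories):
        if cs.ell is not None:
            # spatial category: the shared latent AND each gene's
            # idiosyncratic part carry the exp(-d / ell) correlation, so
            # every member gene is individually spatially autocorrelated
            # (a shared latent alone is constant across genes and would
            # cancel out of the across-gene CGE correlation)
            draws = _gp_exponential(dist, cs.ell, rng, n_draws=cs.size + 1)
            latent, eps = draws[:, 0], draws[:, 1:] * spec.noise_sd
        else:
            latent = rng.standard_normal(spec.n_regions)
            eps = rng.standard_normal((spec.n_regions, cs.size)) * spec.noise_sd
        block = cs.w * latent[:, None] + np.sqrt(1.0 - cs.w**2) * eps
        block += spec.gradient_strength * grad[:, None]
        x[:, pos:pos + cs.size] = block
        cats.append(
            Category(
                f"C{i:04d}",
                f"synthetic w={cs.w} ell={cs.ell}",
                frozenset(gene_ids[pos:pos + cs.size]),
            )
        )
        pos += cs.size
    n_filler = spec.n_genes - pos
    if n_filler:
        x[:, pos:] = (
            rng.standard_normal((spec.n_regions, n_filler)) * spec.noise_sd
            + spec.gradient_strength * grad[:, None]
        )
    x = (x - x.mean(axis=0)) / x.std(axis=0)

    region_ids = [f"r{i:04d}" for i in range(spec.n_regions)]
    atlas = ExpressionAtlas(
        pd.DataFrame(x, index=region_ids, columns=gene_ids),
        coordinates=pd.DataFrame(coords, index=region_ids, columns=["x", "y", "z"]),
    )
    table = CategoryTable(cats)
    if return_gradient:
        return atlas, table, grad
    return atlas, table


def make_random_categories(
    gene_ids,
    n_categories: int,
    size_range: tuple[int, int] = (10, 200),
    seed: int = 0,
    prefix: str = "R",
) -> CategoryTable:
    """Categories as uniform random gene subsets with sizes drawn uniformly
    from *size_range* -- the random-annotation analogue used for calibration
    audits (categories may overlap, as real annotations do)."""
    gene_ids = list(gene_ids)
    lo, hi = size_range
    if hi > len(gene_ids):
        raise ValueError(f"max category size {hi} exceeds {len(gene_ids)} genes")
    rng = np.random.default_rng(seed)
    cats = []
    for i in range(n_categories):
        s = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=s, replace=False)
        cats.append(
            Category(f"{prefix}{i:05d}", f"random set {i}",
                     frozenset(gene_ids[j] for j in members))
        )
    return CategoryTable(cats)


def make_gradient_aligned_phenotype(
    atlas: ExpressionAtlas,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> PhenotypeMap:
    """Phenotype aligned with the atlas's dominant expression gradient.

    Returns the leading spatial principal component of the expression matrix
    (scores of regions on the first right-singular direction across genes),
    oriented to correlate positively with its top-loading gene, optionally
    plus i.i.d. noise.
    """
    if atlas.n_regions < 3:
        raise ValueError("need at least 3 regions")
    x = atlas.expression.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        col_mean = np.nanmean(x, axis=0)
        x = np.where(np.isfinite(x), x, col_mean[None, :])
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise ValueError("degenerate expression matrix: no leading component")
    pc = u[:, 0] * s[0]
    top_gene = int(np.argmax(np.abs(vt[0])))
    r = np.corrcoef(pc, x[:, top_gene])[0, 1]
    if r < 0:
        pc = -pc
    pc = (pc - pc.mean()) / pc.std()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pc = pc + rng.standard_normal(len(pc)) * noise_sd
    return PhenotypeMap(pd.Series(pc, index=atlas.region_ids, name="gradient_pc1"))
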