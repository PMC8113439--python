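"""Gene scoring, category aggregation, and per-category spatial diagnostics.

Gene scoring correlates each gene's spatial expression profile with a
phenotype map (Pearson by default, Spearman optional), using
pairwise-complete observations so that post-quality-filter missingness never
silently biases a score.  Category-level diagnostics follow two summary
statistics:

* the within-category coexpression score <r>: the mean of the unique
  (upper-triangular) pairwise Spearman correlations among a category's genes;
* the spatial autocorrelation score R2_exp: the goodness of fit of correlated
  gene expression versus distance, CGE(d) = A exp(-d / lambda) + B, fitted by
  nonlinear least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

from .atlas import DistanceMatrix, ExpressionAtlas, PhenotypeMap
from .ontology import CategoryTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScoreTable",
    "ExpDecayFit",
    "score_genes",
    "score_genes_against_maps",
    "aggregate_category_scores",
    "within_category_coexpression",
    "category_cge",
    "fit_exp_decay",
    "region_class_differential",
    "category_diagnostics",
]


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average ranks down each column, NaNs left as NaN."""
    out = np.full_like(x, np.nan, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        m = np.isfinite(col)
        if m.any():
            out[m, j] = stats.rankdata(col[m])
    return out


def pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each column of *x* against each column of *y*.

    *x* may contain NaNs (pairwise-complete per x-column); *y* must be fully
    observed.  Returns (r, n_used) with shapes (x_cols, y_cols) and (x_cols,).
    Vectorized as masked cross-products so the cost is a handful of matrix
    multiplications.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype maps must not contain missing values")
    m = np.isfinite(x)
    n = m.sum(axis=0).astype(float)  # per gene
    xm = np.where(m, x, 0.0)
    sx = xm.sum(axis=0)
    sxx = (xm * xm).sum(axis=0)
    sy = m.T @ y                      # (g, p) sums of y over each gene's mask
    syy = m.T @ (y * y)
    sxy = xm.T @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx[:, None] * sy / n[:, None]
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n[:, None]
        r = cov / np.sqrt(vx[:, None] * vy)
    r = np.clip(r, -1.0, 1.0)
    return r, n.astype(int)


@dataclass
class GeneScoreTable:
    """Per-gene correlation scores against one phenotype map."""

    table: pd.DataFrame  # index gene_id; columns score, n_used
    method: str
    transform: str = "raw"

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    def config_tag(self) -> str:
        return f"{self.method}/{self.transform}"


def score_genes(
    atlas: ExpressionAtlas,
    phenotype: PhenotypeMap,
    method: str = "pearson",
    min_regions: int = 3,
) -> GeneScoreTable:
    """Correlate every gene's expression profile with the phenotype map.

    Pairwise-complete regions per gene; genes with fewer than *min_regions*
    usable regions, or constant expression over the overlap, are dropped with
    a warning.  A constant phenotype is an error (correlation undefined).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown scoring method {method!r}")
    vals = phenotype.align_to(atlas, min_overlap=min_regions)
    sub = atlas.expression.loc[vals.index]
    y = vals.to_numpy(dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    x = sub.to_numpy(dtype=float)[keep]
    if np.nanstd(y) == 0:
        raise ValueError("undefined correlation: phenotype is constant over the atlas overlap")
    if method == "spearman":
        if np.isfinite(x).all():
            x = _rank_columns(x)
            y = stats.rankdata(y)
            r, n = pairwise_pearson(x, y)
        else:
            # ranks depend on each gene's complete-pair subset
            r = np.full((x.shape[1], 1), np.nan)
            n = np.zeros(x.shape[1], dtype=int)
            for j in range(x.shape[1]):
                m = np.isfinite(x[:, j])
                n[j] = int(m.sum())
                if n[j] >= min_regions and np.std(x[m, j]) > 0 and np.std(y[m]) > 0:
                    r[j, 0] = stats.spearmanr(x[m, j], y[m]).statistic
    else:
        r, n = pairwise_pearson(x, y)
    scores = pd.DataFrame({"score": r[:, 0], "n_used": n}, index=sub.columns)
    bad = scores["score"].isna() | (scores["n_used"] < min_regions)
    if bad.any():
        logger.warning("score_genes: dropped %d genes (constant or < %d usable regions)",
                       int(bad.sum()), min_regions)
    return GeneScoreTable(scores.loc[~bad], method=method)


def score_genes_against_maps(
    atlas: ExpressionAtlas,
    maps: np.ndarray,
    region_ids,
    method: str = "pearson",
) -> tuple[np.ndarray, pd.Index]:
    """Gene x map correlation matrix against a bank of phenotype maps.

    *maps* is (n_regions, n_maps) aligned to *region_ids*.  Spearman with
    missing expression falls back to a per-gene loop and is slow; with
    complete data both methods are matrix products.
    """
    region_ids = pd.Index(region_ids)
    sub = atlas.expression.loc[region_ids]
    x = sub.to_numpy(dtype=float)
    y = np.asarray(maps, dtype=float)
    if y.shape[0] != len(region_ids):
        raise ValueError("maps not aligned to region ids")
    if method == "spearman":
        if np.isfinite(x).all():
            x = _rank_columns(x)
            y = _rank_columns(y)
        else:
            r = np.empty((x.shape[1], y.shape[1]))
            for p in range(y.shape[1]):
                yp = stats.rankdata(y[:, p])
                for j in range(x.shape[1]):
                    m = np.isfinite(x[:, j])
                    r[j, p] = stats.spearmanr(x[m, j], y[m, p]).statistic
            return r, sub.columns
    r, _ = pairwise_pearson(x, y)
    return r, sub.columns


def aggregate_category_scores(
    scores: GeneScoreTable,
    categories: CategoryTable,
    transform: str = "raw",
) -> pd.DataFrame:
    """Mean (optionally absolute) member-gene score per category.

    Category members absent from the score table are dropped and the
    effective size recorded; categories with no scored member are excluded
    with a warning.
    """
    if transform not in ("raw", "absolute"):
        raise ValueError(f"unknown transform {transform!r}")
    s = scores.scores
    if transform == "absolute":
        s = s.abs()
    rows = []
    for c in categories:
        member = s.reindex(sorted(c.genes)).dropna()
        if member.empty:
            logger.warning("aggregate_category_scores: category %s has no scored members", c.category_id)
            continue
        if len(member) < c.size:
            logger.info("category %s: %d of %d members scored", c.category_id, len(member), c.size)
        rows.append((c.category_id, c.name, len(member), float(member.mean())))
    return pd.DataFrame(rows, columns=["category_id", "name", "size", "score"]).set_index("category_id")


def within_category_coexpression(atlas: ExpressionAtlas, genes) -> float:
    """Mean pairwise Spearman coexpression <r> over a category's gene pairs.

    The gene x gene Spearman matrix C is computed over pairwise-complete
    regions; <r> is the mean of its s(s-1)/2 upper-triangular entries.
    """
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("<r> requires at least 2 genes")
    x = atlas.expression.loc[:, genes].to_numpy(dtype=float)
    if np.isfinite(x).all():
        rho = stats.spearmanr(x).statistic
        if np.ndim(rho) == 0:  # spearmanr collapses the 2-gene case to a scalar
            return float(rho)
        c = np.asarray(rho)
    else:
        c = pd.DataFrame(x).corr(method="spearman", min_periods=3).to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    return float(np.nanmean(c[iu]))


def category_cge(
    atlas: ExpressionAtlas,
    genes,
    distances: DistanceMatrix,
) -> pd.DataFrame:
    """Correlated gene expression per region pair over a category's genes.

    For each unordered region pair (i, j), CGE_ij is the Pearson correlation
    across the category's genes between the two regions' expression vectors.
    Pairs involving a region with fewer than 3 observed category genes are
    dropped.
    """
    genes = sorted(genes)
    if len(genes) < 3:
        raise ValueError("CGE requires at least 3 genes in the category")
    expr = atlas.expression.loc[distances.region_ids, genes]
    x = expr.to_numpy(dtype=float)
    # correlation between region rows across genes, pairwise-complete
    c = pd.DataFrame(x.T).corr(min_periods=3).to_numpy()
    i_idx, j_idx, d = distances.upper_pairs()
    cge = c[i_idx, j_idx]
    ok = np.isfinite(cge)
    ids = distances.region_ids
    return pd.DataFrame(
        {
            "region_i": ids[i_idx[ok]],
            "region_j": ids[j_idx[ok]],
            "d": d[ok],
            "cge": cge[ok],
        }
    )


@dataclass
class ExpDecayFit:
    """Three-parameter exponential fit y = A exp(-d / lam) + B."""

    A: float
    lam: float
    B: float
    r2: float
    alt_spearman_stat: float
    converged: bool = True

    def predict(self, d):
        return self.A * np.exp(-np.asarray(d, dtype=float) / self.lam) + self.B


def fit_exp_decay(d, y) -> ExpDecayFit:
    """Nonlinear least-squares fit of A exp(-d/lam) + B to (d, y) pairs.

    Initialization: A0 = max(y) - min(y), lam0 = median(d), B0 = min(y),
    with lam constrained positive.  R2 = 1 - SS_res / SS_tot.  The
    model-free alternative statistic, minus the Spearman correlation of y
    with d, is always computed alongside.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(np.unique(d)) < 4:
        raise ValueError("exponential fit requires >= 4 distinct distances")
    alt = float(-stats.spearmanr(y, d).statistic)
    p0 = [float(y.max() - y.min()) or 1.0, float(np.median(d)) or 1.0, float(y.min())]
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda dd, A, lam, B: A * np.exp(-dd / lam) + B,
                d, y, p0=p0,
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError:
        popt, converged = p0, False
    A, lam, B = (float(v) for v in popt)
    resid = y - (A * np.exp(-d / lam) + B)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    return ExpDecayFit(A=A, lam=lam, B=B, r2=r2, alt_spearman_stat=alt, converged=converged)


def region_class_differential(
    atlas: ExpressionAtlas,
    class_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per gene between two region classes.

    Returns a table of (statistic, p, q) with Benjamini-Hochberg q-values.
    Genes fully missing in either class are excluded and logged.
    """
    labels = class_labels if class_labels is not None else atlas.region_class
    if labels is None:
        raise ValueError("no region class labels supplied")
    labels = labels.loc[atlas.region_ids]
    levels = labels.dropna().unique()
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 region classes, got {list(levels)}")
    a_idx = labels == levels[0]
    b_idx = labels == levels[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("both region classes need >= 2 regions")
    rows, skipped = [], 0
    for g in atlas.gene_ids:
        col = atlas.expression[g]
        a = col[a_idx].dropna().to_numpy()
        b = col[b_idx].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            skipped += 1
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append((g, float(res.statistic), float(res.pvalue)))
    if skipped:
        logger.warning("region_class_differential: excluded %d genes missing in one class", skipped)
    out = pd.DataFrame(rows, columns=["gene_id", "statistic", "p"]).set_index("gene_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def category_diagnostics(
    atlas: ExpressionAtlas,
    categories: CategoryTable,
    distances: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Per-category <r> and, when distances are supplied, the CGE(d)
    exponential-decay fit (A, lambda, B, R2_exp, Spearman alternative)."""
    rows = []
    for c in categories:
        genes = [g for g in c.genes if g in atlas.gene_ids]
        rec: dict = {"category_id": c.category_id, "size": len(genes)}
        rec["mean_coexpression"] = (
            within_category_coexpression(atlas, genes) if len(genes) >= 2 else np.nan
        )
        if distances is not None and len(genes) >= 3:
            pairs = category_cge(atlas, genes, distances)
            try:
                fit = fit_exp_decay(pairs["d"], pairs["cge"])
                rec.update(A=fit.A, lambda_mm=fit.lam, B=fit.B, R2_exp=fit.r2,
                           alt_spearman_stat=fit.alt_spearman_stat)
            except ValueError:
                pass
        rows.append(rec)
    return pd.DataFrame(rows).set_index("category_id")
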