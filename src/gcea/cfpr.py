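"""Category false-positive rate (CFPR) auditing.

The CFPR of a category is the percentage of null phenotypes for which that
category is called significant (q < alpha after BH-FDR) by a GCEA
configuration.  Three audit conditions are supported:

* ``reference`` -- each gene's expression profile independently randomized
  across regions (destroying gene-gene coexpression) and i.i.d. random
  phenotypes: the empirical statistical floor;
* ``sbp_random`` -- real expression, i.i.d. random phenotypes;
* ``sbp_spatial`` -- real expression, spatially autocorrelated phenotypes.

The inner GCEA defaults to the conventional random-gene null, because CFPR
measures the conventional method's false-positive behaviour; passing an
ensemble null bank instead audits the corrected method (expected to sit at
the nominal rate).  Per-phenotype results are streamed and reduced to
significance counts so that 10,000-phenotype audits run in bounded memory.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ExpressionAtlas
from .ontology import CategoryTable
from .nulls import NullBank, bh_reject_matrix, sample_subset_means
from .scoring import score_genes_against_maps
from .surrogates import NullPhenotypeEnsemble

logger = logging.getLogger(__name__)

__all__ = ["reference_randomize", "compute_cfpr", "summarize_cfpr"]


def reference_randomize(atlas: ExpressionAtlas, seed: int = 0) -> ExpressionAtlas:
    """Randomize each gene's values across regions with an independent
    permutation per gene, preserving each gene's missingness pattern."""
    rng = np.random.default_rng(seed)
    x = atlas.expression.to_numpy(dtype=float).copy()
    if np.isfinite(x).all():
        x = rng.permuted(x, axis=0)
    else:
        for j in range(x.shape[1]):
            obs = np.isfinite(x[:, j])
            x[obs, j] = rng.permutation(x[obs, j])
    expr = pd.DataFrame(x, index=atlas.region_ids, columns=atlas.gene_ids)
    return ExpressionAtlas(expr, coordinates=atlas.coordinates, region_class=atlas.region_class)


def _tail_p(z: np.ndarray, tail: str) -> np.ndarray:
    if tail == "right":
        return stats.norm.sf(z)
    if tail == "left":
        return stats.norm.cdf(z)
    if tail == "two_sided":
        return 2.0 * stats.norm.sf(np.abs(z))
    raise ValueError(f"unknown tail {tail!r}")


def compute_cfpr(
    atlas: ExpressionAtlas,
    categories: CategoryTable,
    ensemble: NullPhenotypeEnsemble,
    condition: str = "sbp_random",
    null_bank: NullBank | None = None,
    n_samples: int | None = None,
    method: str = "pearson",
    transform: str = "raw",
    tail: str = "right",
    alpha_fdr: float = 0.05,
    chunk: int = 256,
    seed: int = 0,
    keep_rejections: bool = False,
) -> pd.DataFrame:
    """Per-category false-positive rate over an ensemble of null phenotypes.

    For each phenotype map in *ensemble*, run GCEA (random-gene null by
    default; an ensemble *null_bank* may be supplied instead) and count the
    phenotypes for which each category reaches q < *alpha_fdr*.

    For the random-gene null, ``n_samples=None`` evaluates the Gaussian
    null at its exact finite-population moments (the infinite-resample
    limit), which makes the audit a fully vectorized computation; an integer
    ``n_samples`` reproduces the Monte-Carlo resampling per phenotype at the
    stated cost.

    With ``keep_rejections=True`` the full per-(category, phenotype)
    rejection indicator matrix is attached to the returned table as
    ``table.attrs["rejections"]`` (audits normally stream and keep counts
    only).
    """
    if alpha_fdr < 0 or alpha_fdr > 1:
        raise ValueError(f"alpha_fdr must lie in [0, 1], got {alpha_fdr}")
    maps = ensemble.align_to(atlas)
    member = categories.membership_matrix(atlas.gene_ids)
    n_cat = len(categories)
    cat_sizes = np.asarray(member.sum(axis=1)).ravel()
    if np.any(cat_sizes == 0):
        empty = [c.category_id for c, s in zip(categories, cat_sizes) if s == 0]
        raise ValueError(f"categories with no measured genes: {empty[:5]}")
    if null_bank is not None:
        null_bank.check_config(f"{method}/{transform}")
        mu_fix = np.array([null_bank.model_for(c.category_id, int(s)).mu
                           for c, s in zip(categories, cat_sizes)])
        sd_fix = np.array([null_bank.model_for(c.category_id, int(s)).sigma
                           for c, s in zip(categories, cat_sizes)])
    rng = np.random.default_rng(seed)
    n_pheno = maps.shape[1]
    n_sig = np.zeros(n_cat, dtype=int)
    rejections = np.zeros((n_cat, n_pheno), dtype=bool) if keep_rejections else None
    for start in range(0, n_pheno, chunk):
        block = maps[:, start:start + chunk]
        r, _ = score_genes_against_maps(atlas, block, atlas.region_ids, method=method)
        if transform == "absolute":
            r = np.abs(r)
        valid = np.isfinite(r).all(axis=1)
        if not valid.all():
            logger.warning("compute_cfpr: excluding %d unscorable genes", int((~valid).sum()))
        rv = r[valid]
        mm = member[:, valid]
        sizes = np.asarray(mm.sum(axis=1)).ravel()
        if np.any(sizes == 0):
            raise ValueError("a category lost all scored genes during the audit")
        cat_scores = (mm @ rv) / sizes[:, None]
        if null_bank is not None:
            z = (cat_scores - mu_fix[:, None]) / sd_fix[:, None]
        elif n_samples is None:
            n = rv.shape[0]
            m_p = rv.mean(axis=0)
            v_p = rv.std(axis=0, ddof=0)
            f_s = np.sqrt((n - sizes) / (sizes * (n - 1)))
            z = (cat_scores - m_p[None, :]) / (v_p[None, :] * f_s[:, None])
        else:
            z = np.empty_like(cat_scores)
            uniq = sorted(set(sizes.astype(int)))
            srt = {s: k for k, s in enumerate(uniq)}
            for p in range(rv.shape[1]):
                means = sample_subset_means(rv[:, p], uniq, n_samples, rng)
                mus = np.array([means[s].mean() for s in uniq])
                sds = np.array([means[s].std(ddof=1) for s in uniq])
                ks = np.array([srt[int(s)] for s in sizes])
                z[:, p] = (cat_scores[:, p] - mus[ks]) / sds[ks]
        pvals = np.clip(_tail_p(z, tail), 1e-300, 1.0)
        if alpha_fdr > 0:
            rej = bh_reject_matrix(pvals, alpha_fdr)
            n_sig += rej.sum(axis=1)
            if rejections is not None:
                rejections[:, start:start + rej.shape[1]] = rej
    out = pd.DataFrame(
        {
            "category_id": categories.category_ids,
            "condition": condition,
            "n_phenotypes": n_pheno,
            "n_significant": n_sig,
            "cfpr_percent": 100.0 * n_sig / n_pheno,
        }
    ).set_index("category_id")
    if rejections is not None:
        out.attrs["rejections"] = rejections
    return out


def _equiprobable_bins(values: pd.Series, n_bins: int) -> list[pd.Index]:
    """Split categories into n_bins rank-ordered groups of near-equal count
    (sizes differ by at most one)."""
    order = values.sort_values(kind="mergesort").index
    return [pd.Index(chunk) for chunk in np.array_split(np.asarray(order), n_bins)]


def summarize_cfpr(
    tables: dict[str, pd.DataFrame],
    diagnostics: pd.DataFrame | None = None,
    literature_labels: pd.Series | None = None,
    n_bins: int = 8,
) -> dict[str, pd.DataFrame]:
    """Summaries across audit conditions.

    Returns a dict with:

    * ``fold_change`` -- ratio of mean CFPR between every ordered pair of
      conditions (zero-CFPR categories included in the means);
    * ``bins`` -- equiprobable CFPR bins per condition with per-bin mean
      CFPR, mean within-category coexpression / R2_exp (when *diagnostics*
      given) and the proportion of literature-reported categories (when
      *literature_labels*, a per-category report count, is given);
    * ``delta`` -- per-category CFPR change sbp_spatial minus sbp_random,
      when both conditions are present.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if not tables:
        raise ValueError("no CFPR tables supplied")
    means = {cond: float(t["cfpr_percent"].mean()) for cond, t in tables.items()}
    fc_rows = []
    for a in tables:
        for b in tables:
            if a != b:
                fc_rows.append((a, b, means[b] / means[a] if means[a] > 0 else np.inf))
    fold = pd.DataFrame(fc_rows, columns=["from", "to", "fold_change"])

    bin_rows = []
    for cond, t in tables.items():
        if len(t) < n_bins:
            raise ValueError(f"condition {cond}: fewer categories ({len(t)}) than bins ({n_bins})")
        cfpr = t["cfpr_percent"]
        total_reports = float(literature_labels.sum()) if literature_labels is not None else np.nan
        for k, idx in enumerate(_equiprobable_bins(cfpr, n_bins)):
            rec = {
                "condition": cond,
                "bin": k,
                "n_categories": len(idx),
                "cfpr_mean": float(cfpr.loc[idx].mean()),
                "cfpr_min": float(cfpr.loc[idx].min()),
                "cfpr_max": float(cfpr.loc[idx].max()),
            }
            if diagnostics is not None:
                sub = diagnostics.reindex(idx)
                if "mean_coexpression" in sub:
                    rec["mean_coexpression"] = float(sub["mean_coexpression"].mean())
                if "R2_exp" in sub:
                    rec["R2_exp"] = float(sub["R2_exp"].mean())
            if literature_labels is not None and total_reports > 0:
                rec["literature_proportion"] = float(
                    literature_labels.reindex(idx).fillna(0).sum() / total_reports
                )
            bin_rows.append(rec)
    bins = pd.DataFrame(bin_rows)

    out = {"fold_change": fold, "bins": bins}
    if "sbp_random" in tables and "sbp_spatial" in tables:
        delta = (
            tables["sbp_spatial"]["cfpr_percent"] - tables["sbp_random"]["cfpr_percent"]
        ).rename("cfpr_change")
        out["delta"] = delta.to_frame()
    return out
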