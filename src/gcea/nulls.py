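"""Null models and p-value machinery for gene-category enrichment.

Two families of null distribution for a category's mean gene score:

* random-gene null: the classical gene-score-resampling null.  For a
  category of size s, the null is the distribution of the mean of s gene
  scores drawn uniformly without replacement from the full scored-gene pool
  (default 40,000 resamples per size, or the exact finite-population
  Gaussian moments in the infinite-resample limit);
* ensemble null: a phenotype-randomization null.  Each category's observed
  scoring pipeline is re-run against a bank of surrogate phenotype maps
  (SBP-random or SBP-spatial), yielding one null category score per map.

Both are summarized by a Gaussian fit (mu, sigma), from which tail p-values
are estimated analytically (p_Z); an exact empirical permutation mode is
available where the full null samples are retained.  Multiple-testing
correction is Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import ExpressionAtlas
from .ontology import CategoryTable
from .scoring import GeneScoreTable, score_genes_against_maps
from .surrogates import NullPhenotypeEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryNullModel",
    "NullBank",
    "build_random_gene_null",
    "random_gene_null_moments",
    "build_ensemble_null",
    "gaussian_p",
    "empirical_p",
    "bh_fdr",
    "sample_subset_means",
]

P_FLOOR = 1e-300


@dataclass
class CategoryNullModel:
    """Gaussian summary (mu, sigma) of a null category-score distribution.

    ``key`` is the category id for ensemble nulls, or the integer category
    size for random-gene nulls (the random-gene null depends on the category
    only through its size).
    """

    key: object
    mu: float
    sigma: float
    n_samples: int | None
    null_kind: str
    score_config: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"null sigma must be positive, got {self.sigma}")


@dataclass
class NullBank:
    """Collection of per-key CategoryNullModels plus the spec that built it."""

    models: dict
    null_kind: str
    score_config: str
    spec: dict = field(default_factory=dict)
    samples: dict | None = None  # key -> null score vector, for empirical p

    def __getitem__(self, key) -> CategoryNullModel:
        return self.models[key]

    def __contains__(self, key) -> bool:
        return key in self.models

    def model_for(self, category_id: str, size: int) -> CategoryNullModel:
        if self.null_kind == "random_gene":
            return self.models[size]
        return self.models[category_id]

    def check_config(self, score_config: str) -> None:
        if score_config != self.score_config:
            raise ValueError(
                f"null bank was built with scoring config {self.score_config!r}, "
                f"cannot evaluate with {score_config!r}"
            )

    def save(self, path) -> None:
        payload = {
            "null_kind": self.null_kind,
            "score_config": self.score_config,
            "spec": self.spec,
            "models": [
                {"key": m.key, "mu": m.mu, "sigma": m.sigma, "n_samples": m.n_samples}
                for m in self.models.values()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "NullBank":
        payload = json.loads(Path(path).read_text())
        models = {
            m["key"]: CategoryNullModel(
                key=m["key"], mu=m["mu"], sigma=m["sigma"], n_samples=m["n_samples"],
                null_kind=payload["null_kind"], score_config=payload["score_config"],
            )
            for m in payload["models"]
        }
        return cls(models=models, null_kind=payload["null_kind"],
                   score_config=payload["score_config"], spec=payload["spec"])


# ---------------------------------------------------------------------------
# random-gene null
# ---------------------------------------------------------------------------


def random_gene_null_moments(pool: np.ndarray, sizes) -> dict[int, tuple[float, float]]:
    """Exact moments of the mean of s scores drawn without replacement.

    For a finite pool of N scores with population mean m and variance v
    (ddof=0), the mean of a uniform s-subset has mean m and variance
    (v / s) * (N - s) / (N - 1).  These are the infinite-resample limits of
    the Gaussian fitted to sampled nulls.
    """
    pool = np.asarray(pool, dtype=float)
    n = len(pool)
    m = float(pool.mean())
    v = float(pool.var(ddof=0))
    out = {}
    for s in sorted(set(int(s) for s in sizes)):
        if s > n:
            raise ValueError(f"category size {s} exceeds the scored-gene pool ({n})")
        var = v / s * (n - s) / (n - 1) if n > 1 else 0.0
        out[s] = (m, float(np.sqrt(var)))
    return out


def sample_subset_means(
    pool: np.ndarray,
    sizes,
    n_samples: int,
    rng: np.random.Generator,
    chunk: int = 2048,
) -> dict[int, np.ndarray]:
    """n_samples means of uniform without-replacement s-subsets, per size.

    Uses a shared random-key construction: for each resample, every pool
    element gets an i.i.d. uniform key, and the s elements with the smallest
    keys form a uniform s-subset for every s simultaneously.  Only the
    smallest max(sizes) keys are materialized (argpartition + sort), so the
    cost is O(n_samples * N) independent of the number of sizes.
    """
    pool = np.asarray(pool, dtype=float)
    n = len(pool)
    sizes = sorted(set(int(s) for s in sizes))
    if sizes and sizes[-1] > n:
        raise ValueError(f"category size {sizes[-1]} exceeds the scored-gene pool ({n})")
    smax = sizes[-1]
    sums = np.empty((n_samples, len(sizes)))
    done = 0
    while done < n_samples:
        b = min(chunk, n_samples - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, smax - 1, axis=1)[:, :smax]
        order = np.argsort(np.take_along_axis(keys, idx, axis=1), axis=1)
        idx = np.take_along_axis(idx, order, axis=1)
        csum = np.cumsum(pool[idx], axis=1)
        for k, s in enumerate(sizes):
            sums[done:done + b, k] = csum[:, s - 1]
        done += b
    return {s: sums[:, k] / s for k, s in enumerate(sizes)}


def build_random_gene_null(
    scores: GeneScoreTable,
    sizes,
    n_samples: int | None = 40_000,
    seed: int = 0,
    transform: str = "raw",
    keep_samples: bool = False,
) -> NullBank:
    """Random-gene (gene-score resampling) null per category size.

    For each size s, the null is formed from ``n_samples`` means of s gene
    scores resampled without replacement from the scored pool and summarized
    by a fitted Gaussian.  ``n_samples=None`` uses the exact
    finite-population moments (the infinite-resample limit) instead of
    Monte-Carlo sampling.
    """
    pool = scores.scores.to_numpy(dtype=float)
    if transform == "absolute":
        pool = np.abs(pool)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes:
        raise ValueError("no category sizes supplied")
    config = f"{scores.method}/{transform}"
    spec = {"kind": "random_gene", "n_samples": n_samples, "seed": int(seed),
            "pool_size": int(len(pool))}
    if n_samples is None:
        moments = random_gene_null_moments(pool, sizes)
        models = {
            s: CategoryNullModel(s, mu, sd, None, "random_gene", config)
            for s, (mu, sd) in moments.items()
        }
        return NullBank(models, "random_gene", config, spec)
    if n_samples < 100:
        raise ValueError(f"n_samples must be >= 100 (or None for exact moments), got {n_samples}")
    rng = np.random.default_rng(seed)
    means = sample_subset_means(pool, sizes, n_samples, rng)
    models = {
        s: CategoryNullModel(s, float(m.mean()), float(m.std(ddof=1)),
                             n_samples, "random_gene", config)
        for s, m in means.items()
    }
    return NullBank(models, "random_gene", config, spec,
                    samples=means if keep_samples else None)


# ---------------------------------------------------------------------------
# ensemble null
# ---------------------------------------------------------------------------


def build_ensemble_null(
    atlas: ExpressionAtlas,
    categories: CategoryTable,
    ensemble: NullPhenotypeEnsemble,
    method: str = "pearson",
    transform: str = "raw",
    keep_samples: bool = False,
    chunk: int = 512,
) -> NullBank:
    """Per-category null from a bank of surrogate phenotype maps.

    For every null map, all genes are scored and aggregated per category
    exactly as in the real analysis; the n_null category scores are
    summarized by a fitted Gaussian per category.  The result depends only
    on the atlas, the categories and the ensemble -- never on the phenotype
    under test -- so it is a one-off computation that can be cached and
    reused across phenotypes.
    """
    maps = ensemble.align_to(atlas)
    member = categories.membership_matrix(atlas.gene_ids)
    sizes = np.asarray(member.sum(axis=1)).ravel()
    if np.any(sizes == 0):
        empty = [c.category_id for c, s in zip(categories, sizes) if s == 0]
        raise ValueError(f"categories with no measured genes: {empty[:5]}")
    n_cat, n_null = len(categories), maps.shape[1]
    # stream over map blocks: only per-category running sums are retained
    count = np.zeros(n_cat)
    total = np.zeros(n_cat)
    total2 = np.zeros(n_cat)
    kept = np.empty((n_cat, n_null)) if keep_samples else None
    for start in range(0, n_null, chunk):
        block = maps[:, start:start + chunk]
        r, _ = score_genes_against_maps(atlas, block, atlas.region_ids, method=method)
        if transform == "absolute":
            r = np.abs(r)
        r = np.nan_to_num(r, nan=0.0)
        cat_scores = (member @ r) / sizes[:, None]
        count += block.shape[1]
        total += cat_scores.sum(axis=1)
        total2 += (cat_scores**2).sum(axis=1)
        if kept is not None:
            kept[:, start:start + block.shape[1]] = cat_scores
    mu = total / count
    var = (total2 - count * mu**2) / (count - 1)
    config = f"{method}/{transform}"
    kind = f"ensemble({ensemble.spec.get('kind', 'unknown')})"
    models = {}
    for i, c in enumerate(categories):
        models[c.category_id] = CategoryNullModel(
            c.category_id, float(mu[i]), float(np.sqrt(var[i])), int(n_null), kind, config
        )
    samples = (
        {c.category_id: kept[i] for i, c in enumerate(categories)} if kept is not None else None
    )
    return NullBank(models, kind, config,
                    spec={"kind": kind, "ensemble": ensemble.spec}, samples=samples)


# ---------------------------------------------------------------------------
# p-values and FDR
# ---------------------------------------------------------------------------


def gaussian_p(score: float, null: CategoryNullModel, tail: str = "right") -> float:
    """Tail p-value from the fitted Gaussian null (p_Z).

    Right tail: p = 1 - Phi((score - mu) / sigma); two-sided doubles the
    smaller tail.  Floored at the smallest positive representable value and
    capped at 1.
    """
    if not np.isfinite(score):
        raise ValueError(f"non-finite category score: {score}")
    z = (score - null.mu) / null.sigma
    if tail == "right":
        p = stats.norm.sf(z)
    elif tail == "left":
        p = stats.norm.cdf(z)
    elif tail == "two_sided":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(np.clip(p, P_FLOOR, 1.0))


def empirical_p(score: float, null_samples: np.ndarray, tail: str = "right") -> float:
    """Permutation p-value with the standard +1 correction."""
    x = np.asarray(null_samples, dtype=float)
    n = len(x)
    if tail == "right":
        k = int((x >= score).sum())
    elif tail == "left":
        k = int((x <= score).sum())
    elif tail == "two_sided":
        mu = x.mean()
        k = int((np.abs(x - mu) >= abs(score - mu)).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (k + 1) / (n + 1)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_reject_matrix(p: np.ndarray, alpha: float) -> np.ndarray:
    """Column-wise BH rejection mask for a (m tests x k analyses) p matrix.

    Vectorized over columns: for each column, the BH step-up threshold is the
    largest i with p_(i) <= i * alpha / m; all p at or below p_(i) are
    rejected.
    """
    p = np.asarray(p, dtype=float)
    m, k = p.shape
    order = np.argsort(p, axis=0)
    ps = np.take_along_axis(p, order, axis=0)
    thresh = (np.arange(1, m + 1)[:, None] * alpha) / m
    ok = ps <= thresh
    # largest passing rank per column (0 if none)
    any_ok = ok.any(axis=0)
    last = np.where(any_ok, m - 1 - np.argmax(ok[::-1], axis=0), -1)
    cutoff = np.where(any_ok, ps[np.clip(last, 0, m - 1), np.arange(k)], -np.inf)
    return p <= cutoff[None, :]
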