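"""Model/results interface for gene-category enrichment analysis.

:class:`GCEA` bundles an expression atlas, a phenotype map and a category
table; :meth:`GCEA.fit` scores every gene against the phenotype, aggregates
scores per category, evaluates each category against the requested null
model, applies BH-FDR correction, and returns an :class:`EnrichmentResults`
carrying the full per-category table (full outputs, never only the
significant rows), the run configuration, and the fitted null bank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DistanceMatrix, ExpressionAtlas, PhenotypeMap, write_enrichment_table
from .ontology import CategoryTable
from .nulls import (
    NullBank,
    bh_fdr,
    build_ensemble_null,
    build_random_gene_null,
    empirical_p,
    gaussian_p,
)
from .scoring import aggregate_category_scores, category_diagnostics, score_genes
from .surrogates import (
    NullPhenotypeEnsemble,
    SpatialLagParams,
    fit_spatial_scale,
    generate_random_maps,
    generate_spatial_lag_maps,
)

logger = logging.getLogger(__name__)

__all__ = ["GCEA", "EnrichmentResults", "run_gcea"]


class GCEA:
    """Gene-category enrichment analysis of a spatial phenotype.

    Parameters
    ----------
    atlas
        Region x gene expression matrix.
    phenotype
        Spatial brain phenotype; aligned to the atlas by region id.
    categories
        Category table (propagated, universe-intersected gene sets).
    method
        Gene scoring correlation: ``pearson`` (default) or ``spearman``.
    transform
        Category aggregation of gene scores: ``raw`` signed mean (default)
        or ``absolute``.
    tail
        Test tail for category p-values; ``right`` by default (is the
        category more strongly correlated than expected under the null).
    """

    def __init__(
        self,
        atlas: ExpressionAtlas,
        phenotype: PhenotypeMap,
        categories: CategoryTable,
        method: str = "pearson",
        transform: str = "raw",
        tail: str = "right",
    ) -> None:
        self.atlas = atlas
        self.phenotype = phenotype
        self.categories = categories
        self.method = method
        self.transform = transform
        self.tail = tail
        self._scores = None

    @classmethod
    def from_files(
        cls,
        expression_path,
        phenotype_path,
        categories_path,
        coordinates_path=None,
        **kwargs,
    ) -> "GCEA":
        from .atlas import load_expression, load_phenotype
        from .ontology import CategoryTable as CT

        atlas = load_expression(expression_path, coordinates_path=coordinates_path)
        phen = load_phenotype(phenotype_path)
        path = str(categories_path)
        cats = CT.from_gmt(path) if path.endswith(".gmt") else CT.from_json(path)
        return cls(atlas, phen, cats, **kwargs)

    @property
    def gene_scores(self):
        """Per-gene score table (computed once, cached)."""
        if self._scores is None:
            self._scores = score_genes(self.atlas, self.phenotype, method=self.method)
        return self._scores

    def score_config(self) -> str:
        return f"{self.method}/{self.transform}"

    def diagnostics(self, distances: DistanceMatrix | None = None) -> pd.DataFrame:
        """Per-category <r> (and CGE exponential fit when distances given)."""
        return category_diagnostics(self.atlas, self.categories, distances=distances)

    def build_null(
        self,
        null: str = "random_gene",
        n_null: int = 40_000,
        n_samples: int | None = 40_000,
        seed: int = 0,
        distances: DistanceMatrix | None = None,
        spatial_params: SpatialLagParams | None = None,
        ensemble: NullPhenotypeEnsemble | None = None,
        keep_samples: bool = False,
    ) -> NullBank:
        """Construct a null bank of the requested kind.

        ``random_gene`` resamples this phenotype's gene scores;
        ``sbp_random`` / ``sbp_spatial`` build phenotype ensembles (the
        spatial kind fits d0 from the atlas unless ``spatial_params`` is
        given) and score every category against them.  A prebuilt *ensemble*
        overrides the ensemble generation step.
        """
        null = null.replace("-", "_")
        if null == "random_gene":
            cat_scores = aggregate_category_scores(
                self.gene_scores, self.categories, transform=self.transform
            )
            return build_random_gene_null(
                self.gene_scores, cat_scores["size"], n_samples=n_samples,
                seed=seed, transform=self.transform, keep_samples=keep_samples,
            )
        if ensemble is None:
            if null == "sbp_random":
                ensemble = generate_random_maps(self.atlas.region_ids, n_null, seed)
            elif null == "sbp_spatial":
                if distances is None:
                    from .atlas import compute_distance_matrix

                    distances = compute_distance_matrix(self.atlas)
                if spatial_params is None:
                    fit = fit_spatial_scale(self.atlas, distances)
                    if not fit.converged:
                        logger.warning(
                            "weak spatial-scale fit (R2=%.3f); d0=%.3g used anyway",
                            fit.r2, fit.lam,
                        )
                    spatial_params = SpatialLagParams(rho=0.8, d0=fit.lam)
                ensemble = generate_spatial_lag_maps(distances, spatial_params, n_null, seed)
            else:
                raise ValueError(f"unknown null kind {null!r}")
        return build_ensemble_null(
            self.atlas, self.categories, ensemble,
            method=self.method, transform=self.transform, keep_samples=keep_samples,
        )

    def fit(
        self,
        null: str | NullBank = "random_gene",
        alpha_fdr: float = 0.05,
        p_mode: str = "gaussian",
        n_samples: int | None = 40_000,
        n_null: int = 40_000,
        seed: int = 0,
        distances: DistanceMatrix | None = None,
        spatial_params: SpatialLagParams | None = None,
        ensemble: NullPhenotypeEnsemble | None = None,
    ) -> "EnrichmentResults":
        """Run the enrichment analysis and return the full result table.

        ``p_mode='gaussian'`` estimates p_Z from the Gaussian fitted to the
        null (fast, slightly anti-conservative in the far tail);
        ``'empirical'`` uses the permutation p over the retained null
        samples (resolution limited to 1 / (n_samples + 1)).
        """
        if p_mode not in ("gaussian", "empirical"):
            raise ValueError(f"unknown p_mode {p_mode!r}")
        cat_scores = aggregate_category_scores(
            self.gene_scores, self.categories, transform=self.transform
        )
        if isinstance(null, NullBank):
            bank = null
            bank.check_config(self.score_config())
        else:
            bank = self.build_null(
                null, n_null=n_null, n_samples=n_samples, seed=seed,
                distances=distances, spatial_params=spatial_params, ensemble=ensemble,
                keep_samples=(p_mode == "empirical"),
            )
        if p_mode == "empirical" and bank.samples is None:
            raise ValueError("empirical p requires a null bank built with keep_samples=True")
        ps = []
        for cid, row in cat_scores.iterrows():
            model = bank.model_for(cid, int(row["size"]))
            if p_mode == "gaussian":
                ps.append(gaussian_p(row["score"], model, tail=self.tail))
            else:
                ps.append(empirical_p(row["score"], bank.samples[model.key], tail=self.tail))
        table = cat_scores.reset_index()
        table["p"] = ps
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["null_kind"] = bank.null_kind
        table = table.sort_values(["p", "category_id"], kind="mergesort").reset_index(drop=True)
        config = {
            "method": self.method,
            "transform": self.transform,
            "tail": self.tail,
            "p_mode": p_mode,
            "alpha_fdr": alpha_fdr,
            "seed": int(seed),
            "null": bank.spec,
        }
        return EnrichmentResults(table=table, alpha_fdr=alpha_fdr, config=config,
                                 null_bank=bank, model=self)


@dataclass
class EnrichmentResults:
    """Full per-category enrichment output of a :class:`GCEA` fit."""

    table: pd.DataFrame  # category_id, name, size, score, p, q, null_kind
    alpha_fdr: float
    config: dict
    null_bank: NullBank | None = None
    model: GCEA | None = None

    @property
    def significant(self) -> pd.DataFrame:
        """Rows with q below the configured FDR threshold."""
        return self.table[self.table["q"] < self.alpha_fdr]

    @property
    def n_significant(self) -> int:
        return int((self.table["q"] < self.alpha_fdr).sum())

    def save(self, path) -> None:
        write_enrichment_table(self.table, path, config=self.config)

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the fit and its top categories."""
        lines = [
            "Gene-category enrichment analysis",
            "=" * 49,
            f"categories tested:   {len(self.table)}",
            f"null model:          {self.table['null_kind'].iloc[0] if len(self.table) else '-'}",
            f"scoring:             {self.config['method']} / {self.config['transform']}"
            f" / {self.config['tail']}-tailed ({self.config['p_mode']} p)",
            f"significant (q < {self.alpha_fdr:g}): {self.n_significant}",
            "-" * 49,
        ]
        cols = ["category_id", "name", "size", "score", "p", "q"]
        head = self.table[cols].head(top)
        lines.append(head.to_string(index=False,
                                    float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def plot(self, top: int = 15, ax=None):
        """Horizontal bar chart of -log10 p for the top categories, with the
        BH significance threshold marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * top + 1))
        head = self.table.head(top).iloc[::-1]
        ax.barh(head["name"].str.slice(0, 40), -np.log10(head["p"]), color="#4878b0")
        ax.set_xlabel(r"$-\log_{10} p$")
        ax.set_title(f"top categories ({self.table['null_kind'].iloc[0]} null)")
        return ax


def run_gcea(
    atlas: ExpressionAtlas,
    phenotype: PhenotypeMap,
    categories: CategoryTable,
    null: str | NullBank = "random_gene",
    method: str = "pearson",
    transform: str = "raw",
    tail: str = "right",
    alpha_fdr: float = 0.05,
    **fit_kwargs,
) -> EnrichmentResults:
    """One-call end-to-end GCEA; see :class:`GCEA` for parameters."""
    model = GCEA(atlas, phenotype, categories, method=method,
                 transform=transform, tail=tail)
    return model.fit(null=null, alpha_fdr=alpha_fdr, **fit_kwargs)
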