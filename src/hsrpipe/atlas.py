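"""Identity mapping of query transcriptomes onto a reference atlas.

The stage reproduces the classical atlas-comparison recipe for assessing
the spatiotemporal identity of in-vitro derived neurons: every query
profile is compared with every atlas sample by Spearman correlation of
within-profile gene ranks, and each annotation category (brain region,
optionally crossed with developmental stage) is then tested for carrying
higher correlation coefficients than the background of all paired
correlations with a one-sided Wilcoxon rank-sum test. The resulting
-log10 p values form the score heatmap.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError, InsufficientOverlapError, UndefinedCorrelationError
from .matrix import ExpressionMatrix
from .rankstats import wilcoxon_rank_sum

log = logging.getLogger(__name__)

#: Default minimum size of the query/atlas gene intersection.
MIN_GENES = 500

#: Separator used to print a (region, stage) category as one label.
CATEGORY_SEP = ":"


def intersect_genes(query: ExpressionMatrix, atlas: ExpressionMatrix,
                    min_genes: int = MIN_GENES,
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, identically ordered.

    The shared gene set is sorted lexicographically so the output order
    does not depend on input order. Raises
    :class:`~hsrpipe.errors.InsufficientOverlapError` when fewer than
    ``min_genes`` genes are shared.
    """
    shared = sorted(set(query.gene_ids) & set(atlas.gene_ids))
    if len(shared) < min_genes:
        raise InsufficientOverlapError(
            f"only {len(shared)} genes shared between query and atlas "
            f"(minimum {min_genes})")
    log.info("gene intersection: %d shared genes", len(shared))
    return query.subset_genes(shared), atlas.subset_genes(shared)


def correlate_all_pairs(query: ExpressionMatrix,
                        atlas: ExpressionMatrix) -> pd.DataFrame:
    """Spearman coefficient for every (query sample, atlas sample) pair.

    Both inputs must already be gene-intersected. Each profile is ranked
    independently; the pairwise coefficients are then the Pearson
    correlations of the rank vectors, which coincides with the
    rank-difference formula whenever a pair is tie-free.

    Returns a tidy table with columns
    ``query_id, atlas_sample_id, rho, n_genes_used``.
    """
    if query.gene_ids != atlas.gene_ids:
        raise InputError("query and atlas must share an identical, "
                         "identically ordered gene set (run intersect_genes)")
    n = query.n_genes
    if n < 3:
        raise InputError("need at least 3 shared genes to correlate")
    qr = _rank_columns(query)
    ar = _rank_columns(atlas)
    qz = _standardize(qr, query.sample_ids, "query")
    az = _standardize(ar, atlas.sample_ids, "atlas")
    rho = (qz.T @ az) / n  # columns are z-scored, so this is Pearson-on-ranks
    np.clip(rho, -1.0, 1.0, out=rho)
    rows = pd.DataFrame({
        "query_id": np.repeat(query.sample_ids, atlas.n_samples),
        "atlas_sample_id": np.tile(atlas.sample_ids, query.n_samples),
        "rho": rho.ravel(),
        "n_genes_used": n,
    })
    return rows


def _rank_columns(m: ExpressionMatrix) -> np.ndarray:
    vals = m.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InputError("expression values must be finite for ranking")
    return _sps.rankdata(vals, method="average", axis=0)


def _standardize(ranks: np.ndarray, ids, role: str) -> np.ndarray:
    centered = ranks - ranks.mean(axis=0)
    sd = centered.std(axis=0)
    flat = sd == 0
    if flat.any():
        bad = [ids[i] for i in np.flatnonzero(flat)[:5]]
        raise UndefinedCorrelationError(
            f"zero rank variance in {role} profile(s): {bad}")
    return centered / sd


def category_enrichment(corr: pd.DataFrame, atlas_meta: pd.DataFrame,
                        granularity: str = "region_x_stage",
                        alternative: str = "greater",
                        background: str = "inclusive") -> pd.DataFrame:
    """Score every (query, category) cell of the identity heatmap.

    For each query, the rho values of every atlas category are tested
    against the background of all paired correlations for that query
    (``background='inclusive'``, the default, keeps the category's own
    pairs in the background; ``'exclusive'`` removes them).

    Returns one row per query x category with columns ``query_id,
    region, stage, category, n_category, w_statistic, p_value,
    neglog10_p, direction_confirmed, q_value`` (q_value is a
    Benjamini-Hochberg annotation across the categories of each query;
    the heatmap itself reports raw -log10 p).
    """
    if granularity not in ("region", "region_x_stage"):
        raise ValueError(f"unknown granularity: {granularity!r}")
    if background not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown background mode: {background!r}")
    meta = atlas_meta
    if granularity == "region_x_stage" and "stage" not in meta.columns:
        raise InputError("region_x_stage granularity requires a 'stage' "
                         "column in the atlas metadata")
    categories = _category_table(meta, granularity)
    sample_cat = _sample_categories(meta, granularity)

    out = []
    for query_id, sub in corr.groupby("query_id", sort=False):
        rho = sub.set_index("atlas_sample_id")["rho"]
        missing = [s for s in sample_cat.index if s not in rho.index]
        if missing:
            raise InputError(
                f"correlation table lacks atlas samples {missing[:5]} "
                f"for query {query_id!r}")
        all_values = rho.loc[sample_cat.index].to_numpy()
        bg_median = float(np.median(all_values))
        for cat_label, row in categories.iterrows():
            members = sample_cat.index[sample_cat == cat_label]
            if len(members) == 0:
                log.warning("category %r has no atlas samples; skipped",
                            cat_label)
                continue
            cat_values = rho.loc[members].to_numpy()
            if background == "inclusive":
                bg = all_values
            else:
                bg = rho.loc[sample_cat.index.difference(members)].to_numpy()
            w, p = wilcoxon_rank_sum(cat_values, bg, alternative=alternative)
            out.append({
                "query_id": query_id,
                "region": row["region"],
                "stage": row.get("stage", pd.NA),
                "category": cat_label,
                "n_category": len(members),
                "w_statistic": w,
                "p_value": p,
                "neglog10_p": -np.log10(p),
                "direction_confirmed": bool(
                    np.median(cat_values) > bg_median),
            })
    result = pd.DataFrame(out)
    if result.empty:
        return result
    result["q_value"] = np.nan
    for _, idx in result.groupby("query_id", sort=False).groups.items():
        result.loc[idx, "q_value"] = multipletests(
            result.loc[idx, "p_value"].to_numpy(), method="fdr_bh")[1]
    return result


def _category_table(meta: pd.DataFrame, granularity: str) -> pd.DataFrame:
    """Categories in presentation order: region-major, stage in the order
    the stages first appear in the metadata (generators and readers emit
    stages in chronological order)."""
    regions = list(dict.fromkeys(meta["region"]))
    if granularity == "region":
        return pd.DataFrame({"region": regions},
                            index=pd.Index(regions, name="category"))
    stages = list(dict.fromkeys(meta["stage"]))
    labels, rows = [], []
    for r in regions:
        present = set(meta.loc[meta["region"] == r, "stage"])
        for s in stages:
            if s in present:
                labels.append(f"{r}{CATEGORY_SEP}{s}")
                rows.append({"region": r, "stage": s})
    return pd.DataFrame(rows, index=pd.Index(labels, name="category"))


def _sample_categories(meta: pd.DataFrame, granularity: str) -> pd.Series:
    if granularity == "region":
        return meta["region"].astype(str)
    return meta["region"].astype(str) + CATEGORY_SEP + meta["stage"].astype(str)


def score_map_matrix(scores: pd.DataFrame,
                     mask_alpha: float | None = None) -> pd.DataFrame:
    """Pivot enrichment rows to the categories x queries heatmap matrix.

    Rows follow the category order of the score table (region-major,
    chronological stages); cells are -log10 p. With ``mask_alpha`` set,
    cells with p >= mask_alpha are blanked (NaN), mirroring heatmaps
    that display significant cells only.
    """
    vals = scores.copy()
    if mask_alpha is not None:
        vals.loc[vals["p_value"] >= mask_alpha, "neglog10_p"] = np.nan
    cat_order = list(dict.fromkeys(vals["category"]))
    query_order = list(dict.fromkeys(vals["query_id"]))
    mat = vals.pivot(index="category", columns="query_id",
                     values="neglog10_p")
    return mat.reindex(index=cat_order, columns=query_order)


def write_score_map(scores: pd.DataFrame, path,
                    mask_alpha: float | None = None,
                    render: str | None = None) -> pd.DataFrame:
    """Write the heatmap matrix as TSV; optionally render a PNG.

    Values are serialized with 12 significant digits so a read-back
    reproduces them; masked/blank cells are written as ``NA``.
    Returns the written matrix.
    """
    mat = score_map_matrix(scores, mask_alpha=mask_alpha)
    try:
        mat.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")
    except OSError as exc:
        raise InputError(f"cannot write score map to {path}: {exc}") from exc
    if render is not None:
        _render_heatmap(mat, render)
    return mat


def _render_heatmap(mat: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * mat.shape[1], 1 + 0.22 * mat.shape[0]))
    im = ax.imshow(mat.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), labels=mat.columns, rotation=90)
    ax.set_yticks(range(mat.shape[0]), labels=mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
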