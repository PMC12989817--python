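"""Differential enrichment analysis (DEA) and PCA quality control.

Per-protein Welch (unequal-variance) two-sample t-tests with
Satterthwaite degrees of freedom compare two sample cohorts on the
imputed, normalized log2 matrix; Benjamini-Hochberg adjustment is
reported alongside.  A protein is called enriched when it exceeds a
fold-change threshold (default >4-fold, i.e. log2 fold change > 2,
strict) at raw p < 0.05, the thresholds used for every contrast.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .ingest import LogMatrix, SampleDesign

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Enrichment call thresholds.

    fc_threshold is on the log2 scale (2 -> ">4-fold", strict);
    p_threshold applies to the raw p-value unless use_adjusted is set.
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold < 0:
            raise ConfigError("fc_threshold must be >= 0")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")


@dataclass
class DEAResult:
    """Per-protein statistics for one two-cohort contrast.

    ``table`` is indexed by protein id with columns: gene_symbol,
    log2fc (mean A - mean B), t_stat, df, p_value, adj_p,
    enriched_in_A, enriched_in_B.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    thresholds: Thresholds | None = None

    def enriched(self, side: str = "A") -> pd.DataFrame:
        col = {"A": "enriched_in_A", "B": "enriched_in_B"}[side]
        return self.table[self.table[col]]

    def enriched_symbols(self, side: str = "A") -> set[str]:
        """Uppercased gene symbols of enriched proteins; blanks dropped."""
        syms = self.enriched(side)["gene_symbol"]
        blank = int((syms.str.strip() == "").sum())
        if blank:
            log.info("%s vs %s: %d enriched proteins lack a gene symbol and are "
                     "excluded from symbol-level sets", self.group_a, self.group_b,
                     blank)
        return {s.upper() for s in syms if s.strip()}


def _cohort_columns(m: LogMatrix, design: SampleDesign, group, assay):
    cols = [s for s in design.samples(group=group, assay=assay)
            if s in m.values.columns]
    if len(cols) < 2:
        raise DataError(f"cohort {group!r}/{assay!r} has {len(cols)} replicates; "
                        "DEA needs >= 2")
    return cols


def welch_dea(m: LogMatrix, design: SampleDesign, group_a, group_b,
              assay: str | None = None) -> DEAResult:
    """Welch two-sample t-test per protein, A vs B, with BH adjustment.

    ``group_a`` / ``group_b`` may be a single group label or a list of
    labels whose replicates are pooled (e.g. all TurboID lines vs
    control).  The matrix must be complete (imputed) over the used
    columns.
    """
    cols_a = _cohort_columns(m, design, group_a, assay)
    cols_b = _cohort_columns(m, design, group_b, assay)
    a = m.values[cols_a].to_numpy(dtype=float)
    b = m.values[cols_b].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise DataError("DEA requires a complete matrix; impute first")

    import warnings

    with warnings.catch_warnings():
        # near-identical rows (e.g. post quantile normalization) trip a
        # scipy precision warning; degenerate rows are handled below
        warnings.filterwarnings("ignore", message="Precision loss",
                                category=RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.array(res.statistic, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    df = np.array(res.df, dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    # degenerate rows: both cohorts zero-variance
    zv = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if zv.any():
        eq = zv & (log2fc == 0)
        ne = zv & (log2fc != 0)
        t[eq], p[eq], df[eq] = 0.0, 1.0, a.shape[1] + b.shape[1] - 2
        if ne.any():
            log.warning("%d zero-variance proteins with unequal means; p set to 0",
                        int(ne.sum()))
            t[ne] = np.sign(log2fc[ne]) * np.inf
            p[ne], df[ne] = 0.0, a.shape[1] + b.shape[1] - 2

    adj_p = multipletests(p, method="fdr_bh")[1]
    name_a = group_a if isinstance(group_a, str) else "+".join(group_a)
    name_b = group_b if isinstance(group_b, str) else "+".join(group_b)
    table = pd.DataFrame(
        {
            "gene_symbol": m.gene_symbols.loc[m.values.index].values,
            "log2fc": log2fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "adj_p": adj_p,
            "enriched_in_A": False,
            "enriched_in_B": False,
        },
        index=m.values.index,
    )
    return DEAResult(table, name_a, name_b)


def classify_deps(r: DEAResult, th: Thresholds) -> DEAResult:
    """Apply the enrichment thresholds (strict > on |log2fc|, < on p)."""
    p = r.table["adj_p"] if th.use_adjusted else r.table["p_value"]
    fc = r.table["log2fc"]
    table = r.table.copy()
    table["enriched_in_A"] = (fc > th.fc_threshold) & (p < th.p_threshold)
    table["enriched_in_B"] = (-fc > th.fc_threshold) & (p < th.p_threshold)
    return replace(r, table=table, thresholds=th)


def pca(m: LogMatrix, n_components: int | None = None):
    """PCA of samples on the protein-centered log2 matrix.

    Returns ``(scores, loadings, variance_fractions)``: sample scores on
    the orthonormal components, per-protein loadings, and the fraction
    of total variance each component explains (non-increasing, summing
    to 1 when all min(n_samples - 1, n_proteins) components are kept).
    """
    X = m.values.to_numpy(dtype=float).T  # samples x proteins
    if np.isnan(X).any():
        raise DataError("PCA requires a complete matrix; impute first")
    n_samples = X.shape[0]
    if n_samples < 2:
        raise DataError("PCA needs at least 2 samples")
    max_comp = min(n_samples, X.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    scores_df = pd.DataFrame(scores, index=m.values.columns,
                             columns=[f"PC{i + 1}" for i in range(k)])
    loadings = pd.DataFrame(model.components_.T, index=m.values.index,
                            columns=scores_df.columns)
    return scores_df, loadings, model.explained_variance_ratio_


def write_dea(r: DEAResult, path) -> None:
    """Write a volcano-ready DEA TSV (one row per protein)."""
    out = r.table.copy()
    out.insert(0, "protein_id", out.index)
    out.to_csv(path, sep="\t", index=False)
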