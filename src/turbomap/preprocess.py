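"""Missing-value imputation and normalization of log2 LFQ matrices.

Two normalization schemes are applied downstream of imputation:

* **bait-abundance normalization** for affinity-purified (AP) samples of
  bait-expressing lines — every AP column is shifted so the bait (the
  Kv1.3-TurboID fusion) has constant log2 intensity across those
  samples, removing differences caused by unequal bait expression or
  biotinylation rather than by biology;
* **quantile normalization** for the whole-cell (bulk) proteome, forcing
  identical per-column intensity distributions.

Imputation follows the Perseus convention for left-censored (MNAR)
missingness: per sample, missing cells are drawn from a normal
distribution down-shifted by ``shift`` standard deviations and narrowed
to ``width`` standard deviations of the observed values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .ingest import CONTROL_GROUP, LogMatrix, SampleDesign

log = logging.getLogger(__name__)


@dataclass
class ImputeParams:
    """Missingness filter and down-shifted-normal imputation parameters.

    min_valid_fraction
        Keep a protein iff quantified in at least this fraction of the
        replicates of at least one (group, assay) cohort.  Default 0.5,
        i.e. tolerate up to 50% missingness within one experimental group.
    width, shift
        Multipliers of the per-sample standard deviation defining the
        imputation distribution Normal(mean - shift*sd, (width*sd)^2);
        defaults 0.3 / 1.8 (the Perseus defaults).
    """

    min_valid_fraction: float = 0.5
    width: float = 0.3
    shift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_valid_fraction <= 1:
            raise ConfigError("min_valid_fraction must be in (0, 1]")
        if self.width <= 0:
            raise ConfigError("width must be > 0")
        if self.shift < 0:
            raise ConfigError("shift must be >= 0")


def filter_by_missingness(m: LogMatrix, design: SampleDesign,
                          min_valid_fraction: float = 0.5) -> LogMatrix:
    """Keep proteins quantified in >= min_valid_fraction of >=1 cohort."""
    if not 0 < min_valid_fraction <= 1:
        raise ConfigError("min_valid_fraction must be in (0, 1]")
    keep = pd.Series(False, index=m.values.index)
    for group, assay, samples in design.cohorts():
        cols = [s for s in samples if s in m.values.columns]
        if not cols:
            continue
        frac = m.values[cols].notna().mean(axis=1)
        keep |= frac >= min_valid_fraction
    n_removed = int((~keep).sum())
    log.info("missingness filter: removed %d/%d proteins (threshold %.2f)",
             n_removed, len(keep), min_valid_fraction)
    return m.with_values(m.values.loc[keep].copy(),
                         f"missingness_filter({min_valid_fraction})")


def impute(m: LogMatrix, params: ImputeParams) -> LogMatrix:
    """Fill missing cells column-wise from a down-shifted normal.

    For column *j* with observed mean ``mu_j`` and sd ``sd_j`` (ddof=1),
    missing cells are drawn from Normal(mu_j - shift*sd_j, (width*sd_j)^2).
    Observed cells are untouched (bit-identical); deterministic given the
    seed, with one RNG consumed column by column in matrix order.
    """
    rng = np.random.default_rng(params.seed)
    vals = m.values.to_numpy(dtype=float).copy()
    for j, col in enumerate(m.values.columns):
        x = vals[:, j]
        miss = np.isnan(x)
        if not miss.any():
            continue
        obs = x[~miss]
        if obs.size < 2:
            raise DataError(
                f"sample {col!r} has {obs.size} observed values; "
                "imputation needs >= 2 to estimate a standard deviation")
        mu, sd = obs.mean(), obs.std(ddof=1)
        x[miss] = rng.normal(mu - params.shift * sd, params.width * sd, miss.sum())
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return m.with_values(
        out, f"impute(width={params.width},shift={params.shift},seed={params.seed})")


def normalize_to_bait(m: LogMatrix, design: SampleDesign, bait_id: str,
                      bait_groups: list[str] | None = None) -> LogMatrix:
    """Normalize AP samples of bait-expressing groups to bait abundance.

    For each AP sample *j* of a bait-bearing group, with bait log2
    intensity ``b_j``:  ``x'_ij = x_ij - b_j + mean(b)``.  The recenter
    by mean(b) keeps the matrix on the original log2 scale; the bait row
    becomes constant across the normalized samples.  Control (bait-free)
    AP samples are left unchanged — the control-vs-bait-line fold change
    therefore mixes scales, mitigated by the recentering (logged).
    """
    if bait_id not in m.values.index:
        raise DataError(f"bait {bait_id!r} not present in matrix")
    if bait_groups is None:
        bait_groups = [g for g in design.groups if g != CONTROL_GROUP]
    cols = [s for s in design.samples(group=bait_groups, assay="AP")
            if s in m.values.columns]
    if not cols:
        raise ConfigError("no AP samples found for bait-bearing groups")
    b = m.values.loc[bait_id, cols]
    if b.isna().any():
        bad = list(b.index[b.isna()])
        raise DataError(f"bait {bait_id!r} unobserved in AP sample(s): {bad}")
    out = m.values.copy()
    out[cols] = out[cols] - b + float(b.mean())
    log.info("bait normalization: %d AP samples shifted to mean bait %.3f; "
             "control AP samples untouched", len(cols), float(b.mean()))
    return m.with_values(out, f"normalize_to_bait({bait_id})")


def quantile_normalize(m: LogMatrix) -> LogMatrix:
    """Force identical per-column value distributions.

    Each column's sorted vector becomes the row-wise mean of all sorted
    columns; tied values within a column share the mean of their rank
    range.  Requires a complete matrix (run after imputation).
    """
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise DataError("quantile normalization requires a complete matrix; "
                        "impute first")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties share the mean of the reference values over their rank range
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    res = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(res, "quantile_normalize")
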