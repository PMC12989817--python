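"""Gene-set over-representation analysis (ORA).

Hypergeometric upper-tail test of a query gene set against each term of
a GMT collection, restricted to an explicit background universe (for
proteomics: all proteins quantified after filtering, not the genome).
P(X >= k) with X ~ Hypergeom(N, K, n); Benjamini-Hochberg adjustment
across the terms of a collection; significance at adjusted p < 0.05.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError, FormatError

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """term_id -> (description, gene set); symbols uppercase, sets non-empty."""

    terms: dict[str, tuple[str, frozenset[str]]]
    source: str = ""

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise DataError(f"gene set {tid!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EnrichmentResult:
    """Per-term ORA statistics; ``table`` sorted by p-value."""

    table: pd.DataFrame
    background_size: int
    query_size: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a GMT file (term <tab> description <tab> genes...)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i} has {len(fields)} fields; "
                                  "GMT needs term, description, >=1 gene")
            tid, desc = fields[0], fields[1]
            if tid in terms:
                raise FormatError(f"{path}: duplicate term id {tid!r} at line {i}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: line {i} ({tid!r}) has no genes")
            terms[tid] = (desc, genes)
    return GeneSetCollection(terms, source=source or str(path))


def write_gmt(gsc: GeneSetCollection, path) -> None:
    """Write a canonical GMT (insertion order of terms, sorted genes)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for tid, (desc, genes) in gsc.terms.items():
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(query: set, background: set, gsc: GeneSetCollection,
        threshold: float = 0.05) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` in each term.

    Per term: the term is restricted to the background (K genes), the
    overlap with the query counted (k), and the upper tail P(X >= k)
    computed for N = background size, n = query size.  Terms absent
    from the background (K = 0) are skipped.  Raises if the query is
    not a subset of the background.
    """
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    if not background:
        raise DataError("background universe is empty")
    stray = query - background
    if stray:
        shown = sorted(stray)[:10]
        raise DataError(f"{len(stray)} query symbols outside the background, "
                        f"e.g. {shown}")
    N, n = len(background), len(query)
    rows = []
    for tid, (desc, genes) in gsc.terms.items():
        term_bg = genes & background
        K = len(term_bg)
        if K == 0:
            continue
        overlap = term_bg & query
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((tid, desc, k, n, K, N, p, ";".join(sorted(overlap))))
    table = pd.DataFrame(rows, columns=["term_id", "name", "k", "n", "K", "N",
                                        "p_value", "members"])
    if len(table):
        table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["adj_p"] < threshold
        table = table.sort_values(["p_value", "term_id"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        table["adj_p"] = []
        table["significant"] = []
    return EnrichmentResult(table, background_size=N, query_size=n)


def write_enrichment(result: EnrichmentResult, path) -> None:
    cols = ["term_id", "name", "k", "n", "K", "N", "p_value", "adj_p",
            "significant", "members"]
    result.table[cols].to_csv(path, sep="\t", index=False)
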