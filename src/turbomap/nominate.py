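"""Set-logic nomination of interactor classes from DEA calls.

This layer turns per-contrast enrichment calls into the named protein
sets of a proximity-labeling study:

* ``ap_specific`` — AP-enriched proteins not explained by whole-cell
  (bulk) abundance changes from transduction/over-expression;
* terminus partitioning — proteins unique to the N- or C-terminal AP
  interactome, combined with the direct N-vs-C contrast;
* PDZ dependence — interactions lost or gained when the PDZ-binding
  motif is deleted from the C terminus;
* cross-cell-type overlap and annotation intersections (membrane
  proteins, disease risk genes) plus a fold-change correlation.

All operations key on uppercased gene symbols (cross-species Venn and
annotation layers are symbol-level); proteins lacking a symbol are
excluded upstream with a logged count.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from scipy.stats import pearsonr

from .dea import DEAResult, Thresholds
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class InteractorCatalog:
    """Named, provenance-tracked gene-symbol sets.

    ``provenance[name]`` records the contrast(s), thresholds and input
    set sizes that produced ``sets[name]``, so any set can be
    regenerated from its record alone.
    """

    sets: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, members: set[str], **prov) -> set[str]:
        self.sets[name] = set(members)
        self.provenance[name] = {"size": len(members), **prov}
        return self.sets[name]

    def venn_counts(self) -> dict[str, int]:
        return {name: len(s) for name, s in sorted(self.sets.items())}

    def write(self, out_dir) -> None:
        """One TSV per set plus venn_counts.json."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, members in sorted(self.sets.items()):
            prov = json.dumps(self.provenance[name], sort_keys=True)
            with open(out_dir / f"set_{name}.tsv", "w", newline="\n") as fh:
                fh.write(f"# provenance: {prov}\n")
                fh.write("gene_symbol\n")
                for sym in sorted(members):
                    fh.write(sym + "\n")
        with open(out_dir / "venn_counts.json", "w", newline="\n") as fh:
            json.dump(self.venn_counts(), fh, sort_keys=True, indent=2)
            fh.write("\n")


def _upper(s: set) -> set[str]:
    return {str(x).upper() for x in s}


def ap_specific(ap_deps: set, bulk_deps: set) -> set[str]:
    """AP-enriched proteins absent from the bulk-proteome DEP list."""
    return _upper(ap_deps) - _upper(bulk_deps)


def terminal_partition(n_deps: set, c_deps: set):
    """Partition N- and C-terminal DEP sets into (unique_N, unique_C, shared)."""
    n, c = _upper(n_deps), _upper(c_deps)
    return n - c, c - n, n & c


def terminal_combined(unique: set, enriched_direct: set) -> set[str]:
    """Union of terminus-unique and directly terminus-enriched proteins."""
    return _upper(unique) | _upper(enriched_direct)


def pdz_dependence(dea_c_vs_dpdz: DEAResult, th: Thresholds):
    """Interactions lost/gained on PDZ-binding-domain deletion.

    The contrast must be full C-terminus (A) vs C-terminus-dPDZ (B):
    enrichment in A means the interaction is *lost* with the deletion,
    enrichment in B means it is *gained*.  Disjoint by construction.
    """
    from .dea import classify_deps

    r = classify_deps(dea_c_vs_dpdz, th)
    return r.enriched_symbols("A"), r.enriched_symbols("B")


def cross_overlap(set_a: set, set_b: set):
    """(shared, only_A, only_B) after case-folding (cross-species safe)."""
    a, b = _upper(set_a), _upper(set_b)
    return a & b, a - b, b - a


def annotate_interactors(interactors: set, annotation: set) -> set[str]:
    """Interactors carrying an annotation (membrane, risk gene, ...)."""
    if not annotation:
        log.warning("annotation set is empty; intersection is empty")
        return set()
    hits = _upper(interactors) & _upper(annotation)
    frac = len(hits) / len(interactors) if interactors else 0.0
    log.info("annotation hit: %d/%d interactors (%.1f%%)",
             len(hits), len(interactors), 100 * frac)
    return hits


def foldchange_correlation(dea_a: DEAResult, dea_b: DEAResult):
    """(n_shared, R^2) of log2 fold changes over shared gene symbols.

    Symbols are uppercased; duplicated symbols keep their first
    occurrence (logged).  Requires >= 3 shared symbols.
    """
    def fc_by_symbol(r: DEAResult):
        t = r.table[r.table["gene_symbol"].str.strip() != ""].copy()
        t["gene_symbol"] = t["gene_symbol"].str.upper()
        dup = int(t["gene_symbol"].duplicated().sum())
        if dup:
            log.info("%d duplicate symbols in %s vs %s; keeping first",
                     dup, r.group_a, r.group_b)
        t = t.drop_duplicates("gene_symbol")
        return t.set_index("gene_symbol")["log2fc"]

    fa, fb = fc_by_symbol(dea_a), fc_by_symbol(dea_b)
    shared = fa.index.intersection(fb.index)
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} shared symbols; "
                        "correlation needs >= 3")
    r, _ = pearsonr(fa.loc[shared], fb.loc[shared])
    return len(shared), float(r) ** 2


def build_catalog(ap_all: DEAResult, bulk_all: DEAResult, ap_n: DEAResult,
                  ap_c: DEAResult, ap_n_vs_c: DEAResult,
                  ap_c_vs_dpdz: DEAResult, th: Thresholds) -> InteractorCatalog:
    """Assemble the full named-set catalog from the six standard contrasts.

    All DEA inputs must already be classified at ``th`` (this function
    classifies them, so raw ``welch_dea`` output is accepted).
    """
    from .dea import classify_deps

    thr = {"fc_threshold": th.fc_threshold, "p_threshold": th.p_threshold,
           "use_adjusted": th.use_adjusted}

    def contrast(r: DEAResult) -> dict:
        return {"group_a": r.group_a, "group_b": r.group_b, "thresholds": thr}

    cat = InteractorCatalog()
    ap_all, bulk_all = classify_deps(ap_all, th), classify_deps(bulk_all, th)
    ap_n, ap_c = classify_deps(ap_n, th), classify_deps(ap_c, th)
    ap_n_vs_c = classify_deps(ap_n_vs_c, th)

    ap_deps = cat.add("ap_interactors", ap_all.enriched_symbols("A"),
                      op="enriched_in_A", **contrast(ap_all))
    bulk_up = cat.add("bulk_deps_up", bulk_all.enriched_symbols("A"),
                      op="enriched_in_A", **contrast(bulk_all))
    bulk_dn = cat.add("bulk_deps_down", bulk_all.enriched_symbols("B"),
                      op="enriched_in_B", **contrast(bulk_all))
    cat.add("ap_specific", ap_specific(ap_deps, bulk_up | bulk_dn),
            op="ap_interactors - (bulk_deps_up | bulk_deps_down)",
            **contrast(ap_all))

    n_deps = cat.add("n_term_deps", ap_n.enriched_symbols("A"),
                     op="enriched_in_A", **contrast(ap_n))
    c_deps = cat.add("c_term_deps", ap_c.enriched_symbols("A"),
                     op="enriched_in_A", **contrast(ap_c))
    uniq_n, uniq_c, shared = terminal_partition(n_deps, c_deps)
    cat.add("unique_N", uniq_n, op="n_term_deps - c_term_deps")
    cat.add("unique_C", uniq_c, op="c_term_deps - n_term_deps")
    cat.add("shared_NC", shared, op="n_term_deps & c_term_deps")

    direct_n = cat.add("enriched_direct_N", ap_n_vs_c.enriched_symbols("A"),
                       op="enriched_in_A", **contrast(ap_n_vs_c))
    direct_c = cat.add("enriched_direct_C", ap_n_vs_c.enriched_symbols("B"),
                       op="enriched_in_B", **contrast(ap_n_vs_c))
    cat.add("combined_N", terminal_combined(uniq_n, direct_n),
            op="unique_N | enriched_direct_N")
    cat.add("combined_C", terminal_combined(uniq_c, direct_c),
            op="unique_C | enriched_direct_C")

    lost, gained = pdz_dependence(ap_c_vs_dpdz, th)
    cat.add("pdz_lost", lost, op="enriched_in_A", **contrast(ap_c_vs_dpdz))
    cat.add("pdz_gained", gained, op="enriched_in_B", **contrast(ap_c_vs_dpdz))
    return cat
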