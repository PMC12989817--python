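"""End-to-end orchestration: ingest -> preprocess -> DEA -> nominate -> ORA.

``run_pipeline`` executes the full analysis from a single config and
writes DEA tables, named interactor sets, Venn counts, enrichment
tables, PCA scores and a manifest recording the seed, a config hash and
the row count at every filter step.  Outputs are byte-identical across
reruns with the same config and seed: the one global seed is fanned out
to per-stage child seeds via a counter, and no timestamps are written.

``demo`` generates a small synthetic study, runs the pipeline on it and
scores recovery of the planted ground truth.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dea, enrich, ingest, nominate, preprocess, synthetic
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: canonical construct-group labels expected in the design table
GROUPS = synthetic.GROUPS
TURBOID_GROUPS = synthetic.TURBOID_GROUPS


def child_seed(seed: int, counter: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 1_000_003 + counter) % (2**31)


@dataclass
class PipelineConfig:
    """Paths, thresholds and parameters for one pipeline run."""

    ap_protein_groups: str
    bulk_protein_groups: str
    design: str
    out_dir: str
    gmt: list = field(default_factory=list)
    annotations: dict = field(default_factory=dict)
    bait_id: str = synthetic.BAIT_ID
    thresholds: dea.Thresholds = field(default_factory=dea.Thresholds)
    impute: preprocess.ImputeParams = field(default_factory=preprocess.ImputeParams)
    ora_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            th = dea.Thresholds(**raw.pop("thresholds", {}))
            imp = preprocess.ImputeParams(**raw.pop("impute", {}))
            return cls(thresholds=th, impute=imp, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config {path}: {exc}") from exc

    def validate_paths(self) -> None:
        paths = [self.ap_protein_groups, self.bulk_protein_groups, self.design,
                 *self.gmt, *self.annotations.values()]
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input file(s): {missing}")

    def to_dict(self) -> dict:
        """Config as a plain dict with paths reduced to file names.

        Keeping only basenames makes the manifest (and its digest)
        byte-identical across reruns in different directories; the full
        paths live in the user's config file, not in the outputs.
        """
        d = asdict(self)
        for key in ("ap_protein_groups", "bulk_protein_groups", "design"):
            d[key] = Path(d[key]).name
        d.pop("out_dir")  # the manifest already lives there
        d["gmt"] = [Path(p).name for p in d["gmt"]]
        d["annotations"] = {k: Path(v).name
                            for k, v in sorted(d["annotations"].items())}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _prepare_assay(table: ingest.IntensityTable, design: ingest.SampleDesign,
                   cfg: PipelineConfig, assay: str, counts: dict):
    """Shared preprocessing: filter -> log2 -> missingness filter -> impute."""
    counts[f"{assay}_rows_in"] = len(table)
    table = ingest.filter_rows(table)
    counts[f"{assay}_rows_after_flag_filter"] = len(table)
    m = ingest.to_log2(table)
    m = preprocess.filter_by_missingness(m, design, cfg.impute.min_valid_fraction)
    counts[f"{assay}_rows_after_missingness_filter"] = len(m.values)
    if assay == "AP":
        # bait observability must hold before imputation: an imputed bait
        # value would silently corrupt the normalization of its column
        cols = [s for s in design.samples(group=TURBOID_GROUPS, assay="AP")
                if s in m.values.columns]
        if cfg.bait_id not in m.values.index:
            raise DataError(f"bait {cfg.bait_id!r} absent from AP matrix")
        b = m.values.loc[cfg.bait_id, cols]
        if b.isna().any():
            raise DataError(f"bait {cfg.bait_id!r} not quantified in AP "
                            f"sample(s): {list(b.index[b.isna()])}")
    seed = child_seed(cfg.seed, {"AP": 1, "bulk": 2}[assay])
    params = preprocess.ImputeParams(cfg.impute.min_valid_fraction,
                                     cfg.impute.width, cfg.impute.shift, seed)
    counts[f"{assay}_cells_imputed"] = m.n_missing()
    return preprocess.impute(m, params)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the output manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    design = ingest.read_design(config.design)
    ap_raw = ingest.read_protein_groups(config.ap_protein_groups)
    bulk_raw = ingest.read_protein_groups(config.bulk_protein_groups)

    m_ap = _prepare_assay(ap_raw, design, config, "AP", counts)
    m_ap = preprocess.normalize_to_bait(m_ap, design, config.bait_id,
                                        bait_groups=TURBOID_GROUPS)
    m_bulk = _prepare_assay(bulk_raw, design, config, "bulk", counts)
    m_bulk = preprocess.quantile_normalize(m_bulk)

    scores, _, var_frac = dea.pca(m_ap)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    with open(out / "pca_variance_fractions.json", "w", newline="\n") as fh:
        json.dump({f"PC{i + 1}": float(v) for i, v in enumerate(var_frac)},
                  fh, sort_keys=True, indent=2)
        fh.write("\n")

    th = config.thresholds
    contrasts = {
        "ap_turboid_vs_control": dea.welch_dea(
            m_ap, design, TURBOID_GROUPS, ingest.CONTROL_GROUP, assay="AP"),
        "bulk_turboid_vs_control": dea.welch_dea(
            m_bulk, design, TURBOID_GROUPS, ingest.CONTROL_GROUP, assay="bulk"),
        "ap_n_term_vs_control": dea.welch_dea(
            m_ap, design, "N_term", ingest.CONTROL_GROUP, assay="AP"),
        "ap_c_term_vs_control": dea.welch_dea(
            m_ap, design, "C_term", ingest.CONTROL_GROUP, assay="AP"),
        "ap_n_term_vs_c_term": dea.welch_dea(
            m_ap, design, "N_term", "C_term", assay="AP"),
        "ap_c_term_vs_dpdz": dea.welch_dea(
            m_ap, design, "C_term", "C_term_dPDZ", assay="AP"),
    }
    for name, r in contrasts.items():
        classified = dea.classify_deps(r, th)
        dea.write_dea(classified, out / f"dea_{name}.tsv")
        counts[f"n_enriched_A_{name}"] = int(classified.table["enriched_in_A"].sum())
        counts[f"n_enriched_B_{name}"] = int(classified.table["enriched_in_B"].sum())

    catalog = nominate.build_catalog(
        contrasts["ap_turboid_vs_control"], contrasts["bulk_turboid_vs_control"],
        contrasts["ap_n_term_vs_control"], contrasts["ap_c_term_vs_control"],
        contrasts["ap_n_term_vs_c_term"], contrasts["ap_c_term_vs_dpdz"], th)

    for name, path in sorted(config.annotations.items()):
        ann = ingest.read_gene_list(path)
        catalog.add(f"{name}_hits",
                    nominate.annotate_interactors(catalog.sets["ap_specific"], ann),
                    op=f"ap_specific & annotation:{name}", annotation=str(path))
    catalog.write(out / "sets")

    background = {s.upper() for s in m_ap.gene_symbols if str(s).strip()}
    for gmt_path in config.gmt:
        gsc = enrich.read_gmt(gmt_path)
        result = enrich.ora(catalog.sets["ap_specific"], background, gsc,
                            threshold=config.ora_threshold)
        stem = Path(gmt_path).stem
        enrich.write_enrichment(result, out / f"enrichment_{stem}.tsv")
        counts[f"n_significant_terms_{stem}"] = int(
            result.table["significant"].sum())

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "counts": counts,
        "set_sizes": catalog.venn_counts(),
        "pca_variance_fractions": [float(v) for v in var_frac[:5]],
    }
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    log.info("pipeline finished: %d named sets, outputs in %s",
             len(catalog.sets), out)
    return manifest


def score_recovery(catalog_sets: dict, truth: synthetic.TruthCatalog) -> dict:
    """Sensitivity / false-discovery proportion of named sets vs the truth.

    The pooled TurboID-vs-control contrast targets the shared-interactor
    class (terminus-restricted effects are diluted 3x in the pooled
    mean), so ap_specific sensitivity is scored on that class while its
    FDP counts any planted interactor (or the bait) as a true positive.
    """
    def rates(found: set, target: set, allowed: set) -> dict:
        sens = len(found & target) / len(target) if target else float("nan")
        fdp = len(found - allowed) / len(found) if found else 0.0
        return {"sensitivity": sens, "fdp": fdp, "n_found": len(found),
                "n_target": len(target)}

    t = truth.symbols
    any_interactor = t(*synthetic.INTERACTOR_CLASSES) | {synthetic.BAIT_ID}
    n_only = t("interactor_N_only")
    c_side = t("interactor_C_only") | t("interactor_PDZ_dependent",
                                        subtype="lost")
    return {
        "ap_specific": rates(catalog_sets["ap_specific"],
                             t("interactor_shared"), any_interactor),
        "combined_N": rates(catalog_sets["combined_N"], n_only, n_only),
        "combined_C": rates(catalog_sets["combined_C"], c_side, c_side),
        "pdz_lost": rates(catalog_sets["pdz_lost"],
                          t("interactor_PDZ_dependent", subtype="lost"),
                          t("interactor_PDZ_dependent", subtype="lost")),
        "pdz_gained": rates(catalog_sets["pdz_gained"],
                            t("interactor_PDZ_dependent", subtype="gained"),
                            t("interactor_PDZ_dependent", subtype="gained")),
    }


def demo(seed: int = 0, out_dir="turbomap_demo", n_proteins: int = 2000,
         quiet: bool = False) -> dict:
    """Simulate a small study, run the pipeline, score truth recovery.

    Writes inputs under ``out_dir/input`` and results under
    ``out_dir/results`` (including ``recovery_summary.json``); prints a
    summary table of named-set sizes with recovery rates.
    """
    out_dir = Path(out_dir)
    params = synthetic.SimParams(n_proteins=n_proteins,
                                 seed=child_seed(seed, 0))
    paths = synthetic.simulate_bundle(params, out_dir / "input")
    config = PipelineConfig(
        ap_protein_groups=paths["ap_protein_groups"],
        bulk_protein_groups=paths["bulk_protein_groups"],
        design=paths["design"],
        gmt=[paths["gmt"]],
        out_dir=str(out_dir / "results"),
        seed=seed,
    )
    manifest = run_pipeline(config)

    truth = synthetic.TruthCatalog(
        pd.read_csv(paths["truth"], sep="\t", keep_default_na=False))
    sets = {}
    for p in sorted((out_dir / "results" / "sets").glob("set_*.tsv")):
        name = p.name[len("set_"):-len(".tsv")]
        syms = [line.strip() for line in p.read_text().splitlines()[2:]]
        sets[name] = set(syms)
    recovery = score_recovery(sets, truth)
    manifest["recovery"] = recovery
    with open(out_dir / "results" / "recovery_summary.json", "w",
              newline="\n") as fh:
        json.dump(recovery, fh, sort_keys=True, indent=2)
        fh.write("\n")

    if not quiet:
        print(f"{'set':<14}{'size':>6}{'target':>8}{'sens':>8}{'fdp':>8}")
        for name, r in recovery.items():
            print(f"{name:<14}{r['n_found']:>6}{r['n_target']:>8}"
                  f"{r['sensitivity']:>8.3f}{r['fdp']:>8.3f}")
        print("sens = fraction of planted interactors recovered; "
              "fdp = fraction of nominated proteins not planted")
    return manifest
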