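"""Synthetic label-free proteomics experiments with known ground truth.

Emulates the statistical structure of a TurboID proximity-labeling
study: four construct groups (``control``, ``N_term``, ``C_term``,
``C_term_dPDZ``), streptavidin affinity-purified (AP) and whole-cell
(bulk) assays, three replicates per cohort, log-normal intensities,
intensity-dependent (MNAR) missingness written as 0 in the MaxQuant
dialect, a single strongly enriched bait ("TURBOID") and planted
interactor classes with ~4-256-fold AP enrichment.  Every protein
carries a known class so downstream stages can be scored exactly
against the truth table.

Protein classes
---------------
bait                       the Kv1.3-TurboID fusion; absent from control
interactor_shared          AP-enriched in every TurboID group
interactor_N_only          AP-enriched only in the N-terminal fusion line
interactor_C_only          AP-enriched in both C-terminal lines
interactor_PDZ_dependent   lost subtype: enriched in C_term only;
                           gained subtype: enriched in C_term_dPDZ only
background                 no planted effect anywhere
endogenous_biotin          equal AP boost in all groups (control included)
contaminant / reverse_decoy  "+"-flagged rows exercising the filters
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .errors import ConfigError
from .ingest import CONTROL_GROUP, FLAG_COLUMNS, IntensityTable, SampleDesign

log = logging.getLogger(__name__)

GROUPS = [CONTROL_GROUP, "N_term", "C_term", "C_term_dPDZ"]
TURBOID_GROUPS = GROUPS[1:]
BAIT_ID = "TURBOID"

CLASSES = [
    "bait",
    "interactor_shared",
    "interactor_N_only",
    "interactor_C_only",
    "interactor_PDZ_dependent",
    "background",
    "endogenous_biotin",
    "contaminant",
    "reverse_decoy",
]
INTERACTOR_CLASSES = CLASSES[1:5]

DEFAULT_FRACTIONS = {
    "background": 0.70,
    "interactor_shared": 0.08,
    "interactor_N_only": 0.04,
    "interactor_C_only": 0.04,
    "interactor_PDZ_dependent": 0.02,
    "endogenous_biotin": 0.05,
    "contaminant": 0.05,
    "reverse_decoy": 0.02,
}


@dataclass
class SimParams:
    """Simulation parameters; defaults emulate the study design.

    All abundance parameters are on the log2-intensity scale.  The MNAR
    model sets P(missing) = logistic(-mnar_slope * (x - mnar_midpoint)),
    a left-censoring curve decreasing in true intensity, OR-ed with a
    small uniform (MCAR) dropout.
    """

    n_proteins: int = 2000
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    n_replicates: int = 3
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.4
    effect_log2_range: tuple = (2.0, 8.0)  # ~4- to 256-fold planted enrichment
    mnar_midpoint: float = 23.0
    mnar_slope: float = 2.5  # 10-90% detection band ~1.8 log2 units
    mcar_rate: float = 0.02
    bait_log2_boost: float = 8.0
    endogenous_ap_boost: float = 3.0
    pdz_lost_fraction: float = 0.6  # of the PDZ-dependent class; rest "gained"
    only_site_rate: float = 0.01   # of background rows, flagged only-by-site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ConfigError("n_proteins must be >= 2 (bait + one more)")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown classes in fractions: {sorted(unknown)}")
        if "bait" in self.class_fractions:
            raise ConfigError("the single bait row is implicit; do not give it "
                              "a class fraction")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions sum to {total}, not 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigError("class fractions must be non-negative")
        for name in ("mcar_rate", "only_site_rate", "pdz_lost_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.effect_log2_range
        if lo < 0 or hi < lo:
            raise ConfigError("effect_log2_range must be 0 <= lo <= hi")


@dataclass
class TruthCatalog:
    """Ground-truth table: one row per protein.

    Columns: protein_id, gene_symbol, clazz, subtype ("" or
    "lost"/"gained" for the PDZ-dependent class), base_log2,
    effect_N_term / effect_C_term / effect_C_term_dPDZ (planted AP
    enrichment per TurboID group, log2 units; 0 for background),
    only_by_site flag.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if int((self.df["clazz"] == "bait").sum()) != 1:
            raise ConfigError("catalog must contain exactly one bait protein")

    def __len__(self) -> int:
        return len(self.df)

    def symbols(self, *classes: str, subtype: str | None = None) -> set[str]:
        sel = self.df[self.df["clazz"].isin(classes)]
        if subtype is not None:
            sel = sel[sel["subtype"] == subtype]
        return set(sel["gene_symbol"].str.upper())

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _allocate_counts(fractions: dict, n: int) -> dict:
    """Largest-remainder allocation of n rows to classes (sums exactly n)."""
    items = [(c, fractions.get(c, 0.0)) for c in CLASSES if c != "bait"]
    raw = [(c, f * n) for c, f in items]
    counts = {c: int(np.floor(x)) for c, x in raw}
    short = n - sum(counts.values())
    leftovers = sorted(raw, key=lambda cf: (-(cf[1] - np.floor(cf[1])), cf[0]))
    for c, _ in leftovers[:short]:
        counts[c] += 1
    return counts


def generate_catalog(params: SimParams) -> TruthCatalog:
    """Draw a ground-truth catalog: classes, base abundances, effects."""
    rng = np.random.default_rng(params.seed)
    counts = _allocate_counts(params.class_fractions, params.n_proteins - 1)

    rows = []
    i = 0
    for clazz in CLASSES:
        for _ in range(counts.get(clazz, 0)):
            i += 1
            if clazz == "contaminant":
                pid, sym = f"CON__P{i:05d}", f"CONGENE{i:04d}"
            elif clazz == "reverse_decoy":
                pid, sym = f"REV__P{i:05d}", f"REVGENE{i:04d}"
            else:
                pid, sym = f"P{i:05d}", f"GENE{i:04d}"
            rows.append((pid, sym, clazz))
    rows.append((BAIT_ID, BAIT_ID, "bait"))

    df = pd.DataFrame(rows, columns=["protein_id", "gene_symbol", "clazz"])
    df["subtype"] = ""
    df["base_log2"] = rng.normal(params.base_log2_mean, params.base_log2_sd,
                                 len(df))
    lo, hi = params.effect_log2_range
    effect = rng.uniform(lo, hi, len(df))

    for g in TURBOID_GROUPS:
        df[f"effect_{g}"] = 0.0
    def is_cls(name: str) -> np.ndarray:
        return (df["clazz"] == name).to_numpy()

    for g in TURBOID_GROUPS:
        df.loc[is_cls("interactor_shared"), f"effect_{g}"] = \
            effect[is_cls("interactor_shared")]
    df.loc[is_cls("interactor_N_only"), "effect_N_term"] = \
        effect[is_cls("interactor_N_only")]
    # the dPDZ construct still carries the C terminus, so PDZ-independent
    # C-terminal interactors are enriched in both C-terminal lines
    for col in ("effect_C_term", "effect_C_term_dPDZ"):
        df.loc[is_cls("interactor_C_only"), col] = \
            effect[is_cls("interactor_C_only")]

    pdz_idx = df.index[is_cls("interactor_PDZ_dependent")]
    n_lost = int(round(params.pdz_lost_fraction * len(pdz_idx)))
    lost_idx, gained_idx = pdz_idx[:n_lost], pdz_idx[n_lost:]
    df.loc[lost_idx, "subtype"] = "lost"
    df.loc[lost_idx, "effect_C_term"] = effect[lost_idx]
    df.loc[gained_idx, "subtype"] = "gained"
    df.loc[gained_idx, "effect_C_term_dPDZ"] = effect[gained_idx]

    bg = df.index[is_cls("background")]
    flagged = rng.random(len(bg)) < params.only_site_rate
    df["only_by_site"] = False
    df.loc[bg[flagged], "only_by_site"] = True

    log.info("catalog: %s", {c: int((df['clazz'] == c).sum()) for c in CLASSES})
    return TruthCatalog(df)


def make_design(groups=None, assays=("AP", "bulk"),
                n_replicates: int = 3) -> SampleDesign:
    """Full-factorial design: group x assay x replicate."""
    groups = list(groups) if groups is not None else list(GROUPS)
    rows = [(f"{a}_{g}_{r}", g, a, r)
            for a in assays for g in groups for r in range(1, n_replicates + 1)]
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "group", "assay", "replicate"]))


def _planted_log2(catalog: TruthCatalog, params: SimParams, group: str,
                  assay: str) -> np.ndarray:
    """Noise-free expected log2 intensity per protein for one cohort."""
    df = catalog.df
    x = df["base_log2"].to_numpy(dtype=float).copy()
    is_bait = (df["clazz"] == "bait").to_numpy()
    if assay == "AP":
        if group != CONTROL_GROUP:
            x += df[f"effect_{group}"].to_numpy(dtype=float)
        x[(df["clazz"] == "endogenous_biotin").to_numpy()] += params.endogenous_ap_boost
    if group != CONTROL_GROUP:
        # the fusion protein is expressed (bulk) and captured (AP) only
        # in the transduced lines
        x[is_bait] += params.bait_log2_boost
    return x


def simulate_experiment(catalog: TruthCatalog, params: SimParams,
                        groups=None, assay: str = "AP") -> IntensityTable:
    """Simulate one assay's raw LFQ intensity table.

    intensity = 2^(base + planted effects + Normal(0, noise_sd)); a cell
    is then censored (written as 0) with probability
    logistic(-mnar_slope*(log2 - mnar_midpoint)) OR mcar_rate.  The bait
    is structurally absent from control samples.  Deterministic given
    ``params.seed`` (the AP and bulk assays consume distinct streams).
    """
    groups = list(groups) if groups is not None else list(GROUPS)
    unknown = [g for g in groups if g not in GROUPS]
    if unknown:
        raise ConfigError(f"unknown construct group(s): {unknown}")
    if assay not in ("AP", "bulk"):
        raise ConfigError(f"assay must be 'AP' or 'bulk', got {assay!r}")

    rng = np.random.default_rng(np.random.SeedSequence(
        (params.seed, {"AP": 1, "bulk": 2}[assay])))
    df = catalog.df
    n = len(df)
    is_bait = (df["clazz"] == "bait").to_numpy()

    cols, data, missing = [], [], []
    for g in groups:
        mu = _planted_log2(catalog, params, g, assay)
        for r in range(1, params.n_replicates + 1):
            cols.append(f"{assay}_{g}_{r}")
            x = mu + rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 \
                else mu.copy()
            if params.mnar_slope == np.inf:
                p_mnar = (x < params.mnar_midpoint).astype(float)
            else:
                p_mnar = 1.0 / (1.0 + np.exp(
                    np.clip(params.mnar_slope * (x - params.mnar_midpoint),
                            -700, 700)))
            mnar = rng.random(n) < p_mnar
            mcar = rng.random(n) < params.mcar_rate
            if g == CONTROL_GROUP:
                # structural absence of the fusion protein
                miss = mnar | mcar | is_bait
            else:
                # the over-expressed fusion dominates the eluate/lysate of
                # transduced lines and is never randomly dropped
                miss = mnar | (mcar & ~is_bait)
            data.append(x)
            missing.append(miss)

    log2 = np.column_stack(data)
    miss = np.column_stack(missing)
    inten = np.where(miss, 0.0, np.exp2(log2))

    proteins = pd.DataFrame(
        {
            "gene_symbol": df["gene_symbol"].values,
            "contaminant": (df["clazz"] == "contaminant").values,
            "reverse": (df["clazz"] == "reverse_decoy").values,
            "only_by_site": df["only_by_site"].values,
        },
        index=pd.Index(df["protein_id"], name="protein_id"),
    )
    intensities = pd.DataFrame(inten, index=proteins.index, columns=cols)
    return IntensityTable(proteins, intensities)


def write_protein_groups(table: IntensityTable, path,
                         intensity_prefix: str = "LFQ intensity ") -> None:
    """Write the MaxQuant-style TSV dialect consumed by the ingest reader."""
    out = pd.DataFrame({"Protein IDs": table.proteins.index,
                        "Gene names": table.proteins["gene_symbol"].values})
    for attr, col in FLAG_COLUMNS.items():
        out[col] = np.where(table.proteins[attr].values, "+", "")
    for s in table.samples:
        out[intensity_prefix + s] = [
            format(v, ".17g") for v in table.intensities[s].to_numpy()]
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def generate_genesets(catalog: TruthCatalog, n_terms: int = 20,
                      planted_terms: int = 2, seed: int = 0,
                      term_size_range: tuple = (10, 50),
                      planted_size: int = 30,
                      planted_fraction: float = 0.8) -> GeneSetCollection:
    """Random GMT-style gene sets over the catalog, some enriched by design.

    Planted terms draw ``planted_fraction`` of their members from the
    interactor classes (so an ORA of the true-interactor query finds
    them); the remaining terms are uniform draws over non-decoy
    proteins.  Deterministic given the seed.
    """
    if planted_terms > n_terms:
        raise ConfigError("planted_terms cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    df = catalog.df
    pool = df[~df["clazz"].isin(["contaminant", "reverse_decoy"])]
    universe = sorted(pool["gene_symbol"].str.upper())
    inter = sorted(pool[pool["clazz"].isin(INTERACTOR_CLASSES)]
                   ["gene_symbol"].str.upper())
    if planted_terms and not inter:
        raise ConfigError("cannot plant enriched terms without interactors")

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(planted_terms):
        k_in = min(int(round(planted_fraction * planted_size)), len(inter))
        members = list(rng.choice(inter, size=k_in, replace=False))
        rest = [g for g in universe if g not in set(members)]
        k_out = min(planted_size - k_in, len(rest))
        members += list(rng.choice(rest, size=k_out, replace=False))
        terms[f"PLANTED_{t + 1:02d}"] = ("planted enriched term",
                                         frozenset(members))
    lo, hi = term_size_range
    for t in range(n_terms - planted_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=min(size, len(universe)),
                             replace=False)
        terms[f"RANDOM_{t + 1:02d}"] = ("uniform background term",
                                        frozenset(members))
    return GeneSetCollection(terms, source="synthetic")


def simulate_bundle(params: SimParams, out_dir) -> dict:
    """Write a complete synthetic study (AP + bulk tables, design, truth,
    gene sets) under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(params)
    design = make_design(n_replicates=params.n_replicates)
    ap = simulate_experiment(catalog, params, assay="AP")
    bulk = simulate_experiment(catalog, params, assay="bulk")
    gsc = generate_genesets(catalog, seed=params.seed + 1)

    from .enrich import write_gmt

    paths = {
        "ap_protein_groups": out_dir / "proteinGroups_AP.txt",
        "bulk_protein_groups": out_dir / "proteinGroups_bulk.txt",
        "design": out_dir / "design.tsv",
        "truth": out_dir / "truth.tsv",
        "gmt": out_dir / "genesets.gmt",
    }
    write_protein_groups(ap, paths["ap_protein_groups"])
    write_protein_groups(bulk, paths["bulk_protein_groups"])
    write_design(design, paths["design"])
    catalog.write(paths["truth"])
    write_gmt(gsc, paths["gmt"])
    return {k: str(v) for k, v in paths.items()}
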