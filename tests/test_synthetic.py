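"""Ground-truth generator: determinism, planted structure, missingness."""
import numpy as np
import pandas as pd
import pytest

from turbomap import (SimParams, generate_catalog, generate_genesets,
                      simulate_experiment)
from turbomap.enrich import write_gmt
from turbomap.errors import ConfigError
from turbomap.synthetic import (GROUPS, TURBOID_GROUPS, make_design,
                                simulate_bundle, write_protein_groups)
from turbomap.ingest import read_design, read_protein_groups


def test_catalog_counts_match_fractions_exactly():
    """Class counts, verified by exhaustive count over generated rows."""
    p = SimParams(n_proteins=100, seed=3, class_fractions={
        "background": 0.8, "interactor_shared": 0.2})
    cat = generate_catalog(p)
    counts = cat.df["clazz"].value_counts().to_dict()
    # 99 non-bait rows split 80/20 by largest remainder -> 79 + 20
    assert counts == {"background": 79, "interactor_shared": 20, "bait": 1}
    assert len(cat) == 100


def test_all_background_still_contains_one_bait():
    p = SimParams(n_proteins=1000, seed=0, class_fractions={"background": 1.0})
    cat = generate_catalog(p)
    assert (cat.df["clazz"] == "background").sum() == 999
    assert (cat.df["clazz"] == "bait").sum() == 1


def test_generators_deterministic_under_seed(small_params):
    a, b = generate_catalog(small_params), generate_catalog(small_params)
    pd.testing.assert_frame_equal(a.df, b.df)
    ta = simulate_experiment(a, small_params, assay="AP")
    tb = simulate_experiment(b, small_params, assay="AP")
    pd.testing.assert_frame_equal(ta.intensities, tb.intensities)


def test_invalid_fractions_rejected():
    with pytest.raises(ConfigError):
        SimParams(class_fractions={"background": 0.5})
    with pytest.raises(ConfigError):
        SimParams(class_fractions={"background": 0.9, "nonsense": 0.1})
    with pytest.raises(ConfigError):
        SimParams(class_fractions={"background": 0.9, "bait": 0.1})


def test_zero_noise_zero_effect_groups_identical():
    """With no noise and no planted effects, every replicate equals base."""
    p = SimParams(n_proteins=120, seed=5, noise_sd=0.0,
                  effect_log2_range=(0.0, 0.0), mcar_rate=0.0,
                  mnar_midpoint=-1e9, endogenous_ap_boost=0.0,
                  class_fractions={"background": 0.6, "interactor_shared": 0.4})
    cat = generate_catalog(p)
    t = simulate_experiment(cat, p, assay="AP")
    log2 = np.log2(t.intensities.replace(0, np.nan))
    nonbait = cat.df["clazz"] != "bait"
    expected = cat.df.loc[nonbait.values, "base_log2"].to_numpy()
    for col in t.samples:
        np.testing.assert_allclose(
            log2.loc[nonbait.values, col].to_numpy(), expected, rtol=1e-12)


def test_planted_log2fc_recovered_at_large_n():
    """Sample-mean oracle: empirical AP log2FC ~ planted effect at n=50."""
    p = SimParams(n_proteins=60, seed=9, noise_sd=0.4, n_replicates=50,
                  effect_log2_range=(4.0, 4.0), mcar_rate=0.0,
                  mnar_midpoint=-1e9,
                  class_fractions={"background": 0.7, "interactor_shared": 0.3})
    cat = generate_catalog(p)
    t = simulate_experiment(cat, p, groups=["control", "N_term"], assay="AP")
    log2 = np.log2(t.intensities.replace(0, np.nan))
    n_cols = [c for c in t.samples if "N_term" in c]
    c_cols = [c for c in t.samples if "control" in c]
    fc = log2[n_cols].mean(axis=1) - log2[c_cols].mean(axis=1)
    shared = cat.df["clazz"].eq("interactor_shared").to_numpy()
    assert np.abs(fc.to_numpy()[shared] - 4.0).max() < 0.2


def test_extreme_censoring_removes_everything():
    p = SimParams(n_proteins=100, seed=2, mnar_slope=np.inf,
                  mnar_midpoint=1e9)
    cat = generate_catalog(p)
    t = simulate_experiment(cat, p, assay="AP")
    assert (t.intensities.to_numpy() == 0).all()


def test_missingness_monotone_in_intensity():
    """Empirical missing rate per true-intensity decile is non-increasing
    (mcar off, >= 10,000 cells)."""
    p = SimParams(n_proteins=1000, seed=13, mcar_rate=0.0, n_replicates=10,
                  class_fractions={"background": 1.0})
    cat = generate_catalog(p)
    t = simulate_experiment(cat, p, groups=["control"], assay="AP")
    base = cat.df.set_index("protein_id")["base_log2"]
    miss = (t.intensities == 0).mean(axis=1)
    deciles = pd.qcut(base.loc[miss.index], 10, labels=False)
    rate = miss.groupby(deciles).mean().to_numpy()
    assert t.intensities.size >= 10_000
    assert (np.diff(rate) <= 1e-12).all()


def test_bulk_carries_no_planted_effect(small_params, small_catalog):
    """Group-mean differences in bulk are centred on 0 for interactors."""
    t = simulate_experiment(small_catalog, small_params, assay="bulk")
    log2 = np.log2(t.intensities.replace(0, np.nan))
    inter = small_catalog.df["clazz"].str.startswith("interactor").to_numpy()
    for g in TURBOID_GROUPS:
        gc = [c for c in t.samples if f"_{g}_" in c]
        cc = [c for c in t.samples if "_control_" in c]
        diff = (log2[gc].mean(axis=1) - log2[cc].mean(axis=1)).to_numpy()[inter]
        assert abs(np.nanmean(diff)) < 0.2


def test_unknown_group_rejected(small_params, small_catalog):
    with pytest.raises(ConfigError):
        simulate_experiment(small_catalog, small_params, groups=["Q_term"])


def test_protein_groups_roundtrip(tmp_path, small_params, small_catalog):
    """Writer output is read back identically by the ingest parser."""
    t = simulate_experiment(small_catalog, small_params, assay="AP")
    path = tmp_path / "pg.txt"
    write_protein_groups(t, path)
    back = read_protein_groups(path)
    pd.testing.assert_frame_equal(back.intensities, t.intensities)
    pd.testing.assert_frame_equal(back.proteins, t.proteins)


def test_design_covers_every_sample(tmp_path, small_params, small_catalog):
    design = make_design(n_replicates=small_params.n_replicates)
    ap = simulate_experiment(small_catalog, small_params, assay="AP")
    bulk = simulate_experiment(small_catalog, small_params, assay="bulk")
    assert set(ap.samples) | set(bulk.samples) == set(design.table["sample_id"])
    assert design.groups == GROUPS


def test_genesets_planted_term_is_interactor_rich(small_catalog):
    gsc = generate_genesets(small_catalog, n_terms=10, planted_terms=1, seed=4)
    inter = small_catalog.symbols("interactor_shared", "interactor_N_only",
                                  "interactor_C_only",
                                  "interactor_PDZ_dependent")
    _, genes = gsc.terms["PLANTED_01"]
    assert len(genes & inter) >= 0.7 * len(genes)


def test_genesets_zero_planted_all_random(small_catalog):
    gsc = generate_genesets(small_catalog, n_terms=5, planted_terms=0, seed=4)
    assert all(t.startswith("RANDOM_") for t in gsc.terms)


def test_genesets_gmt_bytes_deterministic(tmp_path, small_catalog):
    p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
    write_gmt(generate_genesets(small_catalog, seed=8), p1)
    write_gmt(generate_genesets(small_catalog, seed=8), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_genesets_too_many_planted_rejected(small_catalog):
    with pytest.raises(ConfigError):
        generate_genesets(small_catalog, n_terms=2, planted_terms=3)


def test_bundle_writes_all_inputs(tmp_path, small_params):
    paths = simulate_bundle(small_params, tmp_path)
    for p in paths.values():
        assert len(open(p).readlines()) > 1
    design = read_design(paths["design"])
    assert len(design.table) == 2 * len(GROUPS) * small_params.n_replicates
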