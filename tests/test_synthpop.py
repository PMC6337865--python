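"""Population generator: determinism, spectrum, breed structure,
ascertainment, annotation labels, phenotypes, and region injection."""

import numpy as np
import pandas as pd
import pytest

from _oracles import hudson_fst, maf_decile_counts
from conftest import tiny_sim_config
from ovimpute.synthpop import (
    BreedSpec,
    ConfigError,
    CrossSpec,
    ShortfallError,
    SimConfig,
    ascertain_array_panel,
    ascertain_nested_panels,
    assign_annotation_classes,
    default_config,
    inject_low_fidelity_region,
    simulate_phenotypes,
    simulate_population,
)


# ---------------------------------------------------------------- generation


def test_seeded_determinism():
    cfg = tiny_sim_config(seed=7)
    a = simulate_population(cfg)
    b = simulate_population(tiny_sim_config(seed=7))
    assert np.array_equal(a.haplotypes, b.haplotypes)
    pd.testing.assert_frame_equal(a.variants, b.variants)
    assert a.individual_ids == b.individual_ids


def test_config_validation_errors():
    cfg = tiny_sim_config()
    cfg.breeds = {"MER": BreedSpec(10, 20, 5, 20)}
    cfg.crosses = [CrossSpec("F1", ("MER", "PD"), 4)]
    with pytest.raises(ConfigError):
        cfg.validate()
    cfg2 = tiny_sim_config()
    cfg2.n_variants = 100  # smaller than the HD array request
    with pytest.raises(ConfigError):
        cfg2.validate()


def test_site_frequency_spectrum_rare_skew(tiny_panel):
    maf = tiny_panel.variants["maf"].to_numpy()
    assert (maf < 0.05).mean() >= 0.40
    assert (maf < 0.05).sum() > ((maf >= 0.45) & (maf <= 0.5)).sum()


def test_panel_structure(tiny_panel, tiny_cfg):
    assert tiny_panel.n_haplotypes == 2 * tiny_panel.n_individuals
    # frequencies recorded in the variant table match the matrix
    alt = tiny_panel.haplotypes.sum(axis=0)
    mac = np.minimum(alt, tiny_panel.n_haplotypes - alt)
    assert np.array_equal(mac, tiny_panel.variants["mac"].to_numpy())
    # F1 crosses present with one haplotype per parental breed
    n_f1 = sum(1 for b in tiny_panel.breed_labels if b == "F1")
    assert n_f1 == tiny_cfg.crosses[0].n_individuals


def _two_breed_freqs(generations: int, seed: int):
    cfg = SimConfig(
        seed=seed,
        n_variants=20_000,
        chrom_length_bp=10_000_000,
        n_chroms=1,
        ancestral_haplotypes=100,  # founders = whole pool: divergence is pure drift
        breeds={
            "A": BreedSpec(50, founder_haplotypes=100, generations=generations,
                           ne_haplotypes=100),
            "B": BreedSpec(50, founder_haplotypes=100, generations=generations,
                           ne_haplotypes=100),
        },
        young_variant_fraction=0.0,
    )
    cfg.validate()
    panel = simulate_population(cfg)
    a = panel.subset_breed("A")
    b = panel.subset_breed("B")
    pa = a.haplotypes.mean(axis=0)
    pb = b.haplotypes.mean(axis=0)
    pooled = (pa + pb) / 2
    # common sites only: rare-site polymorphism conditioning biases Fst
    keep = (pooled >= 0.05) & (pooled <= 0.95)
    return pa[keep], pb[keep], a.n_haplotypes, b.n_haplotypes


def test_fst_near_zero_without_divergence():
    """With zero divergence generations both breeds sample one pool, so the
    replicate-mean Hudson Fst sits within 3 standard errors of 0 (the SE is
    taken across replicate simulations: within-genome blocks share samples
    and would understate it)."""
    vals = np.array([hudson_fst(*_two_breed_freqs(0, seed)) for seed in range(6)])
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) <= 3 * se


def test_fst_increases_with_divergence_time():
    """Mean Hudson Fst (independent brute-force estimator) is monotone in
    divergence generations over {5, 20, 50}, and strictly larger at 50 than
    at 5 generations."""
    means = {}
    for gens in (5, 20, 50):
        vals = [hudson_fst(*_two_breed_freqs(gens, seed)) for seed in (1, 2, 3)]
        means[gens] = np.mean(vals)
    assert means[5] < means[20] < means[50]


# ------------------------------------------------------------- ascertainment


def test_ascertainment_exhaustive_and_floor(tiny_panel):
    maf = tiny_panel.variants["maf"].to_numpy()
    n_eligible = int((maf >= 0.2).sum())
    arr = ascertain_array_panel(tiny_panel, n_eligible, maf_floor=0.2, seed=1)
    assert len(arr) == n_eligible  # exactly the eligible set
    arr2 = ascertain_array_panel(tiny_panel, 50, maf_floor=0.1, seed=1)
    idx = arr2.member_mask(tiny_panel.variants)
    assert tiny_panel.variants.loc[idx, "maf"].min() >= 0.1


def test_ascertainment_shortfall_error(tiny_panel):
    with pytest.raises(ShortfallError) as err:
        ascertain_array_panel(tiny_panel, tiny_panel.n_variants + 10, maf_floor=0.4)
    assert err.value.deficit > 0
    assert str(err.value.deficit) in str(err.value)


def test_uniform_maf_flattens_deciles(tiny_panel):
    """uniform_maf balances MAF-decile counts better than random_common,
    verified by direct decile counting."""
    floor, size = 0.05, 300
    stds = {}
    for scheme in ("uniform_maf", "random_common"):
        arr = ascertain_array_panel(tiny_panel, size, maf_floor=floor, scheme=scheme, seed=3)
        m = tiny_panel.variants.loc[arr.member_mask(tiny_panel.variants), "maf"].to_numpy()
        stds[scheme] = maf_decile_counts(m, floor).std()
    assert stds["uniform_maf"] < stds["random_common"]


def test_nested_panels_are_nested(tiny_arrays):
    assert tiny_arrays["LD"].is_subset_of(tiny_arrays["50k"])
    assert tiny_arrays["50k"].is_subset_of(tiny_arrays["HD"])


def test_unknown_scheme_rejected(tiny_panel):
    with pytest.raises(ConfigError):
        ascertain_array_panel(tiny_panel, 10, scheme="bogus")


# ----------------------------------------------------------------- annotation


def _variants_frame(n: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    maf = np.minimum(rng.beta(0.4, 3.0, n) / 2, 0.5)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1),
            "ref_allele": "A",
            "alt_allele": "C",
            "maf": maf,
            "mac": (maf * 200).astype(int),
        }
    )


def test_degenerate_proportions_label_everything_intergenic():
    v = assign_annotation_classes(
        _variants_frame(500),
        {"intergenic": 1.0, "intronic": 0, "updownstream5kb": 0, "missense": 0, "utr": 0},
        seed=1,
    )
    assert (v["annotation_class"] == "intergenic").all()


def test_default_class_proportions_realized():
    v = assign_annotation_classes(_variants_frame(20_000), seed=2)
    realized = v["annotation_class"].value_counts(normalize=True)
    expected = {"intergenic": 0.63, "intronic": 0.30, "updownstream5kb": 0.064,
                "missense": 0.003, "utr": 0.003}
    for cls, p in expected.items():
        assert abs(realized.get(cls, 0.0) - p) <= 0.01


def test_missense_enriched_for_rare_alleles():
    v = assign_annotation_classes(_variants_frame(20_000), seed=3)
    rare = v["maf"] < 0.05
    frac = v.groupby("annotation_class").apply(
        lambda g: (g["maf"] < 0.05).mean(), include_groups=False
    )
    assert frac["missense"] > frac["intergenic"]
    assert rare.any()


def test_bad_proportions_rejected():
    with pytest.raises(ConfigError):
        assign_annotation_classes(_variants_frame(100), {"intergenic": 0.8, "intronic": 0.1,
                                                         "updownstream5kb": 0, "missense": 0,
                                                         "utr": 0})


# ----------------------------------------------------------------- phenotypes


def test_phenotypes_null_and_noiseless_limits(tiny_panel):
    p0 = simulate_phenotypes(tiny_panel, n_causal=50, target_h2=0.0, seed=1)
    assert (p0.frame["true_breeding_value"] == 0).all()
    p1 = simulate_phenotypes(tiny_panel, n_causal=50, target_h2=1.0, seed=1)
    assert np.allclose(p1.frame["y_adj"], p1.frame["true_breeding_value"])


def test_phenotype_heritability_realized(tiny_panel):
    ph = simulate_phenotypes(tiny_panel, n_causal=100, target_h2=0.3, seed=4)
    ratio = ph.frame["true_breeding_value"].var(ddof=0) / ph.frame["y_adj"].var(ddof=0)
    assert abs(ratio - 0.3) <= 0.02


def test_phenotype_h2_out_of_range(tiny_panel):
    with pytest.raises(ConfigError):
        simulate_phenotypes(tiny_panel, n_causal=10, target_h2=1.5)


# ------------------------------------------------------------ region injection


def test_region_identity_when_no_op(tiny_panel):
    out = inject_low_fidelity_region(tiny_panel, ("chr1", 1, 2_000_000), 0.0, 1.0, seed=1)
    assert np.array_equal(out.haplotypes, tiny_panel.haplotypes)
    pd.testing.assert_frame_equal(out.variants, tiny_panel.variants)


def test_region_density_multiplier_counts(tiny_panel):
    region = ("chr1", 500_001, 1_500_000)
    v = tiny_panel.variants
    before = int(
        ((v["chrom"] == "chr1") & (v["pos"] >= region[1]) & (v["pos"] <= region[2])).sum()
    )
    out = inject_low_fidelity_region(tiny_panel, region, 0.0, 3.0, seed=2)
    vo = out.variants
    after = int(
        ((vo["chrom"] == "chr1") & (vo["pos"] >= region[1]) & (vo["pos"] <= region[2])).sum()
    )
    # Poisson(2 * before) insertions on top of `before`
    assert abs(after - 3 * before) < 5 * np.sqrt(2 * before)
    new_pos = set(vo.loc[vo["chrom"] == "chr1", "pos"]) - set(v.loc[v["chrom"] == "chr1", "pos"])
    assert all(region[1] <= p <= region[2] for p in new_pos)


def test_region_outside_genome_rejected(tiny_panel):
    with pytest.raises(ConfigError):
        inject_low_fidelity_region(tiny_panel, ("chr9", 1, 100), 0.1, 1.0)
    with pytest.raises(ConfigError):
        inject_low_fidelity_region(tiny_panel, ("chr1", 1, 10_000_000_000), 0.1, 1.0)


def test_region_untouched_outside(tiny_panel):
    region = ("chr1", 500_001, 1_500_000)
    out = inject_low_fidelity_region(tiny_panel, region, 0.3, 1.0, seed=3)
    v = tiny_panel.variants
    outside = ~((v["chrom"] == "chr1") & (v["pos"] >= region[1]) & (v["pos"] <= region[2]))
    assert np.array_equal(
        out.haplotypes[:, outside.to_numpy()], tiny_panel.haplotypes[:, outside.to_numpy()]
    )
    inside = (~outside).to_numpy()
    assert not np.array_equal(out.haplotypes[:, inside], tiny_panel.haplotypes[:, inside])


def test_default_config_is_valid():
    cfg = default_config(seed=3)
    cfg.validate()
    assert set(cfg.array_sizes) == {"LD", "50k", "HD"}
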