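"""Haplotype-copying imputation: MAC filter, forward-backward correctness
against exhaustive enumeration, limits, dosage/genotype rules, the quality
statistic, and stepwise chaining."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import enumerate_copying_posteriors
from conftest import make_panel
from ovimpute.evaluate import mask_to_panel
from ovimpute.imputer import (
    HmmParams,
    RawReference,
    filter_reference,
    impute_panel,
    li_stephens_posteriors,
    rsq_statistic,
    rsq_statistic_matrix,
    stepwise_impute,
)
from ovimpute.types import ArrayPanel, PanelError


def _variants(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "ref_allele": "A",
            "alt_allele": "C",
            "maf": 0.0,
            "mac": 0,
        }
    )


def _array_for(panel, idx, name="arr"):
    return ArrayPanel(
        name=name, positions=panel.variants.iloc[idx][["chrom", "pos"]],
        target_size=len(idx),
    )


# ------------------------------------------------------------------ filtering


def test_mac_filter_boundary():
    """MAC 4 is removed, MAC 5 is retained (the filter is strictly < 5)."""
    rng = np.random.default_rng(0)
    hap = np.zeros((20, 3), dtype=np.uint8)
    hap[:4, 0] = 1   # MAC 4
    hap[:5, 1] = 1   # MAC 5
    hap[:10, 2] = 1  # MAC 10
    panel = make_panel(hap)
    out = filter_reference(panel, min_mac=5)
    assert out.n_variants == 2
    assert out.variants["mac"].min() == 5
    log = out.metadata["filter_log"]
    assert log["removed_mac_below_min"] == 1
    assert log["retained"] + log["removed_mac_below_min"] == log["input_variants"]


def test_mac_filter_identity_when_all_pass():
    hap = np.zeros((20, 2), dtype=np.uint8)
    hap[:8, 0] = 1
    hap[:9, 1] = 1
    panel = make_panel(hap)
    out = filter_reference(panel, min_mac=5)
    assert np.array_equal(out.haplotypes, panel.haplotypes)


# ----------------------------------------------------------------- HMM params


def test_hmm_params_validation():
    with pytest.raises(PanelError):
        HmmParams(error_rate=0.0)
    with pytest.raises(PanelError):
        HmmParams(error_rate=0.6)
    with pytest.raises(PanelError):
        HmmParams(switch_scale=-1)


def test_stay_probability_resets_across_chromosomes():
    v = pd.concat([_variants([100, 200]), _variants([100], chrom="chr2")], ignore_index=True)
    stay = HmmParams().stay_probabilities(v)
    assert stay[0] > 0.99
    assert stay[1] == 0.0


# ---------------------------------------------------- forward-backward limits


def test_perfect_copy_limit():
    """A target identical to one reference haplotype at every typed site puts
    nearly all posterior mass on it, and untyped dosages copy its alleles."""
    rng = np.random.default_rng(1)
    M, H = 40, 4
    ref_h = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
    ref = RawReference(ref_h, _variants(np.arange(1, M + 1) * 2000))
    typed = np.arange(0, M, 2)
    params = HmmParams(error_rate=1e-8, switch_scale=1.0)
    post, dos = li_stephens_posteriors(ref_h[2, typed], typed, ref, params)
    assert (post[:, 2] >= 0.999).all()
    assert np.allclose(dos, ref_h[2], atol=1e-3)


def test_uninformative_limit_no_typed_sites():
    rng = np.random.default_rng(2)
    M, H = 10, 4
    ref_h = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
    ref = RawReference(ref_h, _variants(np.arange(1, M + 1) * 1000))
    post, dos = li_stephens_posteriors(np.empty(0, dtype=np.int8), np.empty(0, dtype=int),
                                       ref, HmmParams())
    assert np.allclose(post, 1.0 / H)
    assert np.allclose(dos, ref_h.mean(axis=0))


def test_three_site_two_hap_instance_matches_enumeration():
    """3 typed sites, H=2, eps=0.1: forward-backward equals exhaustive
    enumeration over the 2**3 hidden paths."""
    ref_h = np.array([[0, 1, 0], [1, 1, 1]], dtype=np.uint8)
    variants = _variants([1_000, 400_000, 1_200_000])
    obs = np.array([0, 1, 1], dtype=np.int8)
    params = HmmParams(error_rate=0.1)
    post, dos = li_stephens_posteriors(obs, np.arange(3), RawReference(ref_h, variants), params)
    stay = params.stay_probabilities(variants)
    oracle = enumerate_copying_posteriors(ref_h, obs, stay, 0.1)
    assert np.abs(post - oracle).max() < 1e-10
    assert np.allclose(dos, (oracle * ref_h.T).sum(axis=1), atol=1e-10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_posteriors_match_enumeration_property(seed):
    """Random small instances: forward-backward equals path enumeration and
    posterior rows are normalised."""
    rng = np.random.default_rng(seed)
    H = int(rng.integers(2, 4))
    M = int(rng.integers(1, 5))
    ref_h = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
    obs = rng.integers(-1, 2, size=M).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=M, replace=False))
    variants = _variants(pos)
    params = HmmParams(error_rate=float(rng.uniform(0.01, 0.4)))
    typed = np.flatnonzero(obs >= 0)
    post, _ = li_stephens_posteriors(obs[typed], typed, RawReference(ref_h, variants), params)
    oracle = enumerate_copying_posteriors(
        ref_h, obs, params.stay_probabilities(variants), params.error_rate
    )
    assert np.abs(post - oracle).max() < 1e-10
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_posterior_concentration_decays_with_distance():
    """With a single typed site, posterior mass on the copied haplotype decays
    monotonically with distance from that site."""
    M = 9
    pos = np.array([1, 200_000, 400_000, 600_000, 800_000,
                    1_000_000, 1_400_000, 2_000_000, 3_000_000])
    ref_h = np.array([[1] * M, [0] * M], dtype=np.uint8)
    ref = RawReference(ref_h, _variants(pos))
    typed = np.array([0])
    post, _ = li_stephens_posteriors(np.array([1], dtype=np.int8), typed, ref, HmmParams())
    mass = post[:, 0]
    assert np.all(np.diff(mass) <= 1e-12)


def test_typed_position_out_of_scope_rejected():
    ref = RawReference(np.zeros((2, 3), dtype=np.uint8), _variants([1, 2, 3]))
    with pytest.raises(PanelError):
        li_stephens_posteriors(np.array([1]), np.array([5]), ref, HmmParams())


# -------------------------------------------------------------- impute_panel


def test_self_imputation_sanity():
    """Targets drawn from the reference itself with a dense array are
    recovered nearly perfectly."""
    rng = np.random.default_rng(3)
    n_ind, M = 12, 300
    base = rng.integers(0, 2, size=(6, M)).astype(np.uint8)
    hap = base[rng.integers(0, 6, size=2 * n_ind)]
    panel = make_panel(hap, positions=np.sort(rng.choice(4_000_000, M, replace=False)) + 1)
    arr = _array_for(panel, np.arange(0, M, 3))
    targets = mask_to_panel(panel.take_individuals(np.arange(3)), arr)
    ref = panel.take_individuals(np.arange(3, n_ind))
    imp = impute_panel(targets, ref, arr)
    truth = panel.take_individuals(np.arange(3)).genotypes()
    agree = (imp.most_likely == truth).mean()
    assert agree >= 0.99


def test_diploid_dosage_equals_sum_of_hap_oracles():
    """Single individual, H=2 reference: genotype dosages equal the sum of
    the two haplotypes' enumeration-oracle dosages."""
    ref_h = np.array([[0, 1, 0, 1], [1, 1, 1, 0]], dtype=np.uint8)
    pos = [1_000, 300_000, 700_000, 1_100_000]
    panel = make_panel(np.vstack([ref_h, np.array([[0, 1, 1, 0], [1, 1, 0, 1]], dtype=np.uint8)]),
                       positions=pos)
    arr = _array_for(panel, np.array([0, 2]))
    ref = panel.take_individuals(np.array([0]))
    target_full = panel.take_individuals(np.array([1]))
    targets = mask_to_panel(target_full, arr)
    params = HmmParams(error_rate=0.1)
    imp = impute_panel(targets, ref, arr, params)
    stay = params.stay_probabilities(ref.variants)
    expected = np.zeros(4)
    for h in range(2):
        obs = np.full(4, -1, dtype=np.int8)
        obs[[0, 2]] = target_full.haplotypes[h, [0, 2]]
        oracle = enumerate_copying_posteriors(ref.haplotypes, obs, stay, 0.1)
        expected += (oracle * ref.haplotypes.T).sum(axis=1)
    assert np.abs(imp.geno_dosages[0] - expected).max() < 1e-10


def test_nothing_to_impute_when_array_covers_everything():
    rng = np.random.default_rng(4)
    founders = rng.integers(0, 2, size=(6, 50)).astype(np.uint8)
    # targets copy founders and the reference contains every founder, so each
    # observed allele is explainable without mismatch
    hap = founders[[0, 1, 2, 3, 0, 1, 2, 3, 4, 5, 0, 1]]
    panel = make_panel(hap, positions=np.arange(1, 51) * 10_000)
    arr = _array_for(panel, np.arange(50))
    targets = panel.take_individuals(np.array([0, 1]))
    ref = panel.take_individuals(np.arange(2, 6))
    imp = impute_panel(
        mask_to_panel(targets, arr), ref, arr,
        HmmParams(error_rate=1e-8, switch_scale=1.0),
    )
    assert np.allclose(imp.geno_dosages, targets.genotypes(), atol=1e-5)
    assert imp.typed_mask.all()


def test_most_likely_rounds_half_to_even():
    from ovimpute.imputer import ImputedSet

    geno = np.array([[0.5, 1.5, 0.49, 1.51]])
    ml = np.clip(np.round(geno), 0, 2).astype(np.int8)
    assert ml.tolist() == [[0, 2, 0, 2]]


def test_target_positions_must_match_array(tiny_panel, tiny_arrays):
    ref = tiny_panel.take_individuals(np.arange(10, 40))
    bad_targets = tiny_panel.take_individuals(np.arange(2))  # not masked
    with pytest.raises(PanelError):
        impute_panel(bad_targets, ref, tiny_arrays["HD"])


# ----------------------------------------------------------------------- rsq


def test_rsq_closed_forms():
    assert rsq_statistic(np.full(10, 0.37)) == 0.0
    hard = np.array([1, 0, 0, 1, 1, 0, 0, 0], dtype=float)
    assert rsq_statistic(hard) == pytest.approx(1.0, abs=1e-12)
    assert rsq_statistic(np.array([0.1, 0.9, 0.5, 0.5])) == pytest.approx(0.32, abs=1e-12)
    assert rsq_statistic(np.zeros(5)) == 0.0  # estimated frequency 0


def test_rsq_rejects_bad_dosages():
    with pytest.raises(PanelError):
        rsq_statistic(np.array([0.2, 1.4]))
    with pytest.raises(PanelError):
        rsq_statistic(np.array([0.5]))


def test_rsq_matrix_matches_scalar():
    rng = np.random.default_rng(5)
    d = rng.random((30, 8))
    vec = rsq_statistic_matrix(d)
    for j in range(8):
        assert vec[j] == pytest.approx(rsq_statistic(d[:, j]), abs=1e-12)


# ------------------------------------------------------------------- stepwise


def test_stepwise_degenerate_stages_equal_direct(tiny_panel):
    rng = np.random.default_rng(6)
    sub = tiny_panel.take_variants(np.arange(0, 300))
    arr_all = _array_for(sub, np.arange(sub.n_variants))
    arrays = {"LD": arr_all, "50k": arr_all, "HD": arr_all}
    targets_idx = np.array([0, 1])
    ref = sub.take_individuals(np.arange(5, 25))
    targets = mask_to_panel(sub.take_individuals(targets_idx), arr_all)
    # tiny emission error so hardening between stages reproduces the inputs
    params = HmmParams(error_rate=1e-8)
    direct = impute_panel(targets, ref, arr_all, params)
    stepped = stepwise_impute(targets, ref, ref, ref, arrays, params)
    assert np.allclose(stepped.geno_dosages, direct.geno_dosages, atol=1e-8)


def test_stepwise_requires_nested_arrays(tiny_panel, tiny_arrays):
    arrays = {"LD": tiny_arrays["HD"], "50k": tiny_arrays["LD"], "HD": tiny_arrays["50k"]}
    ref = tiny_panel.take_individuals(np.arange(10, 30))
    targets = mask_to_panel(tiny_panel.take_individuals(np.arange(2)), tiny_arrays["HD"])
    with pytest.raises(PanelError, match="nested"):
        stepwise_impute(targets, ref, ref, ref, arrays)


def test_stage_position_missing_from_reference_names_it(tiny_panel, tiny_arrays):
    """If a stage's reference lacks a typed position the error names it."""
    ref_50k = mask_to_panel(tiny_panel.take_individuals(np.arange(10, 30)),
                            tiny_arrays["50k"])
    ref_50k_broken = ref_50k.take_variants(np.arange(1, ref_50k.n_variants))
    targets = mask_to_panel(tiny_panel.take_individuals(np.arange(2)), tiny_arrays["LD"])
    ref = tiny_panel.take_individuals(np.arange(10, 30))
    dropped = (ref_50k.variants.iloc[0]["chrom"], int(ref_50k.variants.iloc[0]["pos"]))
    ld_keys = set(zip(tiny_arrays["LD"].positions["chrom"],
                      tiny_arrays["LD"].positions["pos"].astype(int)))
    if dropped not in ld_keys:
        # make sure we drop an LD position so stage 1 actually trips
        first_ld = next(iter(sorted(ld_keys)))
        keep = [
            i for i, (c, p) in enumerate(zip(ref_50k.variants["chrom"],
                                             ref_50k.variants["pos"].astype(int)))
            if (c, p) != first_ld
        ]
        ref_50k_broken = ref_50k.take_variants(np.array(keep))
        dropped = first_ld
    with pytest.raises(PanelError, match=str(dropped[1])):
        stepwise_impute(targets, ref_50k_broken, ref, ref,
                        {"LD": tiny_arrays["LD"], "50k": tiny_arrays["50k"],
                         "HD": tiny_arrays["HD"]})
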