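"""Pre-configured desk-scale study designs.

Each function wires the full pipeline into one of the evaluation designs the
package exists for, at a scale that runs on a single CPU in seconds to a few
minutes, and returns plain dictionaries of the quantities the design
measures.  They are the single source of the study conditions used by both
the test suite and the reproduction script, so the conditions are defined
once and never drift apart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import (
    apply_threshold,
    cross_validate_impute,
    make_fold_plan,
    mask_to_panel,
    per_variant_accuracy,
    stratified_summary,
)
from .gpred import (
    BayesRConfig,
    BayesRModel,
    PredictionResult,
    accuracy_se,
    run_stratified_prediction,
)
from .imputer import HmmParams, filter_reference, impute_panel, stepwise_impute
from .synthpop import (
    BreedSpec,
    SimConfig,
    ascertain_nested_panels,
    default_config,
    inject_low_fidelity_region,
    simulate_phenotypes,
    simulate_population,
)
from .types import HaplotypePanel

__all__ = [
    "default_cv_study",
    "paired_mean_accuracy",
    "stepwise_vs_direct_study",
    "problem_region_study",
    "reference_composition_study",
    "h2_recovery_study",
    "stratified_h2_study",
]


def default_cv_study(seed: int = 1) -> dict:
    """The headline design: fivefold cross-validated HD -> WGS imputation of
    the 117 Merino-like targets against the full multi-breed reference.

    Returns the per-variant accuracy tables computed from dosages and from
    most-likely genotypes, plus the panel/arrays/fold plan for reuse.
    """
    cfg = default_config(seed=seed)
    panel = simulate_population(cfg)
    arrays = ascertain_nested_panels(
        panel, cfg.array_sizes, maf_floor=cfg.array_maf_floor, seed=seed + 1
    )
    plan = make_fold_plan(panel.individual_ids, k=5, seed=seed + 2)
    mer = [i for i, b in zip(panel.individual_ids, panel.breed_labels) if b == "MER"]
    imputed = cross_validate_impute(panel, arrays["HD"], plan, target_ids=mer)
    acc_dosage = per_variant_accuracy(imputed, panel, plan, use_dosage=True)
    acc_hard = per_variant_accuracy(imputed, panel, plan, use_dosage=False)
    return {
        "config": cfg,
        "panel": panel,
        "arrays": arrays,
        "fold_plan": plan,
        "imputed": imputed,
        "acc_dosage": acc_dosage,
        "acc_hard": acc_hard,
    }


def paired_mean_accuracy(acc_a: pd.DataFrame, acc_b: pd.DataFrame) -> tuple[float, float]:
    """Mean empirical accuracy of two scoring routes over the variants that
    are scorable under both (the paired comparison; an accuracy mean over
    different variant sets is not comparable)."""
    both = (acc_a["excluded_reason"] == "none") & (acc_b["excluded_reason"] == "none")
    return (
        float(acc_a.loc[both, "empirical_r"].mean()),
        float(acc_b.loc[both, "empirical_r"].mean()),
    )


# --------------------------------------------------------------------------- #


def _small_multibreed_config(seed: int, n_variants: int = 30_000) -> SimConfig:
    cfg = SimConfig(
        seed=seed,
        n_variants=n_variants,
        chrom_length_bp=20_000_000,
        n_chroms=1,
        breeds={
            "MER": BreedSpec(60, founder_haplotypes=150, generations=20, ne_haplotypes=150),
            "PD": BreedSpec(15, founder_haplotypes=80, generations=20, ne_haplotypes=80),
            "BL": BreedSpec(15, founder_haplotypes=70, generations=20, ne_haplotypes=70),
        },
        array_sizes={"LD": 150, "50k": 600, "HD": 2000},
    )
    cfg.validate()
    return cfg


def stepwise_vs_direct_study(seed: int = 1, n_targets: int = 12) -> dict:
    """Three-stage LD -> 50k -> HD -> WGS imputation versus direct HD -> WGS
    on the same Merino-like targets; returns the paired mean accuracies."""
    cfg = _small_multibreed_config(seed)
    panel = simulate_population(cfg)
    arrays = ascertain_nested_panels(
        panel, cfg.array_sizes, maf_floor=cfg.array_maf_floor, seed=seed + 1
    )
    filtered = filter_reference(panel, 5)
    mer_idx = np.flatnonzero(np.asarray(filtered.breed_labels) == "MER")
    rng = np.random.default_rng(seed + 2)
    targets_idx = rng.choice(mer_idx, size=n_targets, replace=False)
    ref_idx = np.setdiff1d(np.arange(filtered.n_individuals), targets_idx)
    ref = filtered.take_individuals(ref_idx)
    truth = filtered.take_individuals(targets_idx)
    params = HmmParams()

    direct = impute_panel(mask_to_panel(truth, arrays["HD"]), ref, arrays["HD"], params)
    stepped = stepwise_impute(
        mask_to_panel(truth, arrays["LD"]),
        mask_to_panel(ref, arrays["50k"]),
        mask_to_panel(ref, arrays["HD"]),
        ref,
        arrays,
        params,
    )
    plan = make_fold_plan(list(truth.individual_ids), k=2, seed=seed + 3)
    # single-shot design: wrap each ImputedSet as one "fold" covering everyone
    single = {0: direct}
    acc_direct = per_variant_accuracy(single, truth, plan, use_dosage=False)
    acc_step = per_variant_accuracy({0: stepped}, truth, plan, use_dosage=False)
    step_mean, direct_mean = paired_mean_accuracy(acc_step, acc_direct)
    return {
        "stepwise_mean": step_mean,
        "direct_mean": direct_mean,
        "acc_direct": acc_direct,
        "acc_stepwise": acc_step,
    }


# --------------------------------------------------------------------------- #

PROBLEM_REGION = ("chr1", 8_000_001, 10_000_000)


def problem_region_study(
    seed: int = 1,
    error_rate: float = 0.05,
    density_multiplier: float = 2.0,
    n_targets: int = 12,
) -> dict:
    """Inject a 2-Mb low-fidelity region and measure its visibility in 1-Mb
    window accuracy means, before and after thr4 filtering."""
    cfg = SimConfig(
        seed=seed,
        n_variants=20_000,
        chrom_length_bp=20_000_000,
        n_chroms=1,
        breeds={
            "MER": BreedSpec(60, founder_haplotypes=150, generations=20, ne_haplotypes=150),
        },
        array_sizes={"HD": 1500},
    )
    cfg.validate()
    panel = simulate_population(cfg)
    panel = inject_low_fidelity_region(
        panel, PROBLEM_REGION, error_rate, density_multiplier, seed=seed + 1
    )
    arrays = ascertain_nested_panels(
        panel, cfg.array_sizes, maf_floor=cfg.array_maf_floor, seed=seed + 2
    )
    filtered = filter_reference(panel, 5)
    rng = np.random.default_rng(seed + 3)
    targets_idx = rng.choice(filtered.n_individuals, size=n_targets, replace=False)
    ref = filtered.take_individuals(np.setdiff1d(np.arange(filtered.n_individuals), targets_idx))
    truth = filtered.take_individuals(targets_idx)
    imp = impute_panel(mask_to_panel(truth, arrays["HD"]), ref, arrays["HD"])
    plan = make_fold_plan(list(truth.individual_ids), k=2, seed=seed + 4)
    acc = per_variant_accuracy({0: imp}, truth, plan, use_dosage=False)
    windows = stratified_summary(acc, "windows_1mb")
    in_region = (windows["window_start"] >= PROBLEM_REGION[1] - 1) & (
        windows["window_end"] <= PROBLEM_REGION[2]
    )
    region_mean = float(windows.loc[in_region, "mean_r"].mean())
    chrom_mean = float(windows["mean_r"].mean())

    scorable = acc[acc["excluded_reason"] == "none"]
    pos = scorable["pos"].to_numpy()
    region_rows = (pos >= PROBLEM_REGION[1]) & (pos <= PROBLEM_REGION[2])
    region_thr0 = float(scorable.loc[region_rows, "empirical_r"].mean())
    thr4_acc, _, _ = apply_threshold(acc, "thr4")
    pos4 = thr4_acc["pos"].to_numpy()
    region4 = (pos4 >= PROBLEM_REGION[1]) & (pos4 <= PROBLEM_REGION[2])
    region_thr4 = float(thr4_acc.loc[region4, "empirical_r"].mean())
    return {
        "windows": windows,
        "region_window_mean": region_mean,
        "chromosome_window_mean": chrom_mean,
        "detected": region_mean < chrom_mean,
        "region_mean_thr0": region_thr0,
        "region_mean_thr4": region_thr4,
        "acc": acc,
    }


# --------------------------------------------------------------------------- #


def reference_composition_study(seed: int = 1, ref_size: int = 60, n_targets: int = 10) -> dict:
    """Impute a small-breed (Poll-Dorset-like) target with a multi-breed
    reference versus a single-breed (Merino-only) reference truncated to the
    same size; returns the paired mean accuracies."""
    cfg = SimConfig(
        seed=seed,
        n_variants=20_000,
        chrom_length_bp=20_000_000,
        n_chroms=1,
        breeds={
            "MER": BreedSpec(80, founder_haplotypes=180, generations=20, ne_haplotypes=180),
            "PD": BreedSpec(26, founder_haplotypes=90, generations=20, ne_haplotypes=90),
            "BL": BreedSpec(20, founder_haplotypes=70, generations=20, ne_haplotypes=70),
        },
        array_sizes={"HD": 1500},
    )
    cfg.validate()
    panel = simulate_population(cfg)
    arrays = ascertain_nested_panels(
        panel, cfg.array_sizes, maf_floor=cfg.array_maf_floor, seed=seed + 1
    )
    labels = np.asarray(panel.breed_labels)
    rng = np.random.default_rng(seed + 2)
    pd_idx = np.flatnonzero(labels == "PD")
    targets_idx = rng.choice(pd_idx, size=n_targets, replace=False)
    remaining = np.setdiff1d(np.arange(panel.n_individuals), targets_idx)
    rem_labels = labels[remaining]
    # multi-breed reference: remaining PD first, topped up with MER and BL
    multi = np.concatenate(
        [
            remaining[rem_labels == "PD"],
            remaining[rem_labels == "BL"],
            remaining[rem_labels == "MER"],
        ]
    )[:ref_size]
    single = remaining[rem_labels == "MER"][:ref_size]
    truth = panel.take_individuals(targets_idx)
    plan = make_fold_plan(list(truth.individual_ids), k=2, seed=seed + 3)

    def run(ref_rows: np.ndarray) -> pd.DataFrame:
        ref = filter_reference(panel.take_individuals(ref_rows), 5)
        scope = set(zip(ref.variants["chrom"], ref.variants["pos"].astype(int)))
        arr = arrays["HD"]
        keep = [
            (c, int(p)) in scope
            for c, p in zip(arr.positions["chrom"], arr.positions["pos"])
        ]
        from .types import ArrayPanel

        arr = ArrayPanel(
            name=arr.name, positions=arr.positions[np.asarray(keep)],
            target_size=arr.target_size,
        )
        imp = impute_panel(mask_to_panel(truth, arr), ref, arr)
        return per_variant_accuracy({0: imp}, truth, plan, use_dosage=False)

    acc_multi = run(multi)
    acc_single = run(single)
    multi_mean, single_mean = paired_mean_accuracy(acc_multi, acc_single)
    return {
        "multi_breed_mean": multi_mean,
        "single_breed_mean": single_mean,
        "multi_ref_breeds": dict(zip(*np.unique(labels[multi], return_counts=True))),
    }


# --------------------------------------------------------------------------- #


def simulate_cohort_panel(
    seed: int,
    n_individuals: int = 1_000,
    n_variants: int = 2_500,
    chrom_length_bp: int = 10_000_000,
) -> HaplotypePanel:
    """A single-breed cohort large enough for genomic-prediction training."""
    cfg = SimConfig(
        seed=seed,
        n_variants=n_variants,
        chrom_length_bp=chrom_length_bp,
        n_chroms=1,
        breeds={
            "MER": BreedSpec(
                n_individuals, founder_haplotypes=200, generations=10, ne_haplotypes=200
            )
        },
    )
    cfg.validate()
    return simulate_population(cfg)


def h2_recovery_study(
    seed: int = 1,
    n_individuals: int = 1_000,
    m_variants: int = 2_000,
    n_causal: int = 100,
    target_h2: float = 0.3,
    config: BayesRConfig | None = None,
) -> dict:
    """Fit BayesR to a simulated trait whose causal variants sit inside the
    fitted set and report the posterior-mean genomic heritability."""
    panel = simulate_cohort_panel(seed, n_individuals=n_individuals,
                                  n_variants=int(m_variants * 3))
    maf = panel.variants["maf"].to_numpy()
    eligible = np.flatnonzero(maf > 0.01)
    rng = np.random.default_rng(seed + 1)
    cols = np.sort(rng.choice(eligible, size=m_variants, replace=False))
    sub = panel.take_variants(cols)
    phenos = simulate_phenotypes(sub, n_causal=n_causal, target_h2=target_h2, seed=seed + 2)
    X = sub.genotypes().astype(float)
    y = phenos.y_for(sub.individual_ids)
    res = BayesRModel(X, y, config or BayesRConfig()).fit(seed=seed + 3)
    return {"h2_posterior_mean": res.h2_mean, "results": res,
            "realized_h2": float(phenos.frame["true_breeding_value"].var() / np.var(y))}


def stratified_h2_study(
    seed: int = 1,
    n_individuals: int = 250,
    n_variants: int = 15_000,
    array_size: int = 250,
    set_size: int = 400,
    n_sets: int = 3,
    n_chains: int = 2,
    permute_phenotypes: bool = False,
) -> dict:
    """The R2-stratified prediction experiment on an LD-array-imputed cohort.

    A single-breed cohort is imputed from a sparse (LD-density) array via
    cross-validation, so a substantial share of variants is poorly imputed;
    matched variant sets from the thr0-4 / thr4 / thr8 strata then feed
    BayesR, and per-stratum genomic heritability and GEBV accuracy are
    returned.
    """
    cfg = SimConfig(
        seed=seed,
        n_variants=n_variants,
        chrom_length_bp=20_000_000,
        n_chroms=1,
        breeds={
            "MER": BreedSpec(
                n_individuals, founder_haplotypes=250, generations=15, ne_haplotypes=250
            )
        },
        array_sizes={"LD": array_size},
        array_maf_floor=0.1,
    )
    cfg.validate()
    panel = simulate_population(cfg)
    # several hard-to-impute regions, so the poorly-imputed stratum contains
    # common variants too (mirroring real poorly-mapped / highly polymorphic
    # regions rather than only rare alleles)
    for k, (start, end) in enumerate(
        [(2_000_001, 4_500_000), (7_000_001, 9_500_000),
         (12_000_001, 14_500_000), (16_000_001, 18_500_000)]
    ):
        panel = inject_low_fidelity_region(
            panel, ("chr1", start, end), error_rate=0.08, density_multiplier=1.0,
            seed=seed + 100 + k,
        )
    arrays = ascertain_nested_panels(
        panel, cfg.array_sizes, maf_floor=cfg.array_maf_floor, seed=seed + 1
    )
    plan = make_fold_plan(panel.individual_ids, k=5, seed=seed + 2)
    imputed = cross_validate_impute(panel, arrays["LD"], plan)
    acc = per_variant_accuracy(imputed, panel, plan, use_dosage=True)

    id_order: list[str] = []
    blocks = []
    for fold in sorted(imputed):
        id_order.extend(imputed[fold].individual_ids)
        blocks.append(imputed[fold].geno_dosages)
    dosages = np.vstack(blocks)
    phenos = simulate_phenotypes(panel, n_causal=150, target_h2=0.3, seed=seed + 3)
    y = phenos.y_for(id_order)
    rng = np.random.default_rng(seed + 4)
    scorable = acc["excluded_reason"].to_numpy() == "none"
    cols = np.flatnonzero(scorable)
    var_tab = acc.loc[scorable, ["maf", "rsq"]].reset_index(drop=True)
    perm = rng.permutation(len(id_order))
    n_target = len(id_order) // 3
    target_idx, train_idx = perm[:n_target], perm[n_target:]
    config = BayesRConfig(n_iter=1_500, n_burnin=750, n_chains=n_chains, seed=seed + 5)
    common = dict(set_size=set_size, config=config)
    if permute_phenotypes:
        # proper permutation null: one analysis per independent phenotype
        # shuffle, with the standard error taken ACROSS permutations (set-level
        # accuracies within one shuffle share its chance associations);
        # correlations are scaled by the trait h2, playing the role of the
        # externally estimated trait heritability
        per_stratum: dict[str, list[float]] = {}
        for p_i in range(n_sets):
            yp = y[rng.permutation(len(y))]
            res_p = run_stratified_prediction(
                dosages[:, cols], var_tab, yp, train_idx, target_idx,
                n_sets=1, seed=seed + 6 + 31 * p_i, h2_scale=0.3, **common,
            )
            for s, pr in res_p.items():
                per_stratum.setdefault(s, []).append(pr.accuracy)
        results = {
            s: PredictionResult(
                stratum=s,
                set_accuracies=accs,
                set_h2=[],
                accuracy=float(np.mean(accs)),
                accuracy_se=accuracy_se(accs),
                h2_mean=float("nan"),
                chain_spread=0.0,
            )
            for s, accs in per_stratum.items()
        }
    else:
        results = run_stratified_prediction(
            dosages[:, cols], var_tab, y, train_idx, target_idx,
            n_sets=n_sets, seed=seed + 6, **common,
        )
    from .evaluate import THRESHOLD_POLICIES

    pool_sizes = {
        s: int(np.sum(p.keep(var_tab["rsq"].to_numpy()) & (var_tab["maf"] > 0.01)))
        for s, p in THRESHOLD_POLICIES.items()
    }
    return {"results": results, "acc": acc, "stratum_pool": pool_sizes}
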