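"""Imputation-accuracy assessment: masking, cross-validation, per-variant
empirical accuracy, quality-score thresholds, and stratified summaries.

The central object is the per-variant accuracy table: for every sequence
variant, the Pearson correlation between imputed and true genotypes across
all held-out individuals pooled over the cross-validation folds, joined to
the variant's reference MAF, pooled dosage-variance quality score (rsq),
1-Mb window, and annotation class.  Typed (array) variants and variants that
are monomorphic on either side of the comparison are flagged and counted,
never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputer import HmmParams, ImputedSet, LiStephensImputer, rsq_statistic_matrix
from .types import ArrayPanel, HaplotypePanel, PanelError

__all__ = [
    "FoldPlan",
    "ThresholdPolicy",
    "THRESHOLD_POLICIES",
    "MAF_BANDS_DEFAULT",
    "MAF_BANDS_PRINTED",
    "make_fold_plan",
    "mask_to_panel",
    "cross_validate_impute",
    "per_variant_accuracy",
    "apply_threshold",
    "stratified_summary",
]


# --------------------------------------------------------------------------- #
# folds and masking
# --------------------------------------------------------------------------- #


@dataclass
class FoldPlan:
    """Balanced random partition of individuals into k folds."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_members(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f == fold]

    def fold_sizes(self) -> list[int]:
        return [len(self.fold_members(f)) for f in range(self.k)]


def make_fold_plan(individual_ids: list[str], k: int = 5, seed: int = 0) -> FoldPlan:
    n = len(individual_ids)
    if k < 2 or k > n:
        raise PanelError(f"fold count k={k} must satisfy 2 <= k <= n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = {individual_ids[idx]: int(i % k) for i, idx in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def mask_to_panel(panel: HaplotypePanel, array: ArrayPanel) -> HaplotypePanel:
    """Reduce a phased panel to exactly the array positions (masking)."""
    lookup = panel.variant_indexer()
    idx = []
    for c, p in zip(array.positions["chrom"], array.positions["pos"]):
        key = (c, int(p))
        if key not in lookup:
            raise PanelError(f"array position {key} missing from panel")
        idx.append(lookup[key])
    return panel.take_variants(np.asarray(idx, dtype=np.int64))


def cross_validate_impute(
    panel: HaplotypePanel,
    array: ArrayPanel,
    fold_plan: FoldPlan,
    target_ids: list[str] | None = None,
    params: HmmParams | None = None,
    min_mac: int = 5,
) -> dict[int, ImputedSet]:
    """Run the masking/imputation design fold by fold.

    For each fold, the fold's members of ``target_ids`` (default: everyone in
    the plan) are masked down to the array and imputed against a reference
    made of all remaining individuals, so most same-breed animals stay in the
    reference.  The MAC filter is applied once to the full panel so every
    fold shares one variant scope.
    """
    from .imputer import filter_reference, impute_panel

    params = params or HmmParams()
    filtered = filter_reference(panel, min_mac)
    scope = set(zip(filtered.variants["chrom"], filtered.variants["pos"].astype(int)))
    in_scope = [
        (c, int(p)) in scope
        for c, p in zip(array.positions["chrom"], array.positions["pos"])
    ]
    if not all(in_scope):
        # array SNPs that fail reference QC drop out of the design
        import logging

        logging.getLogger(__name__).warning(
            "%d array positions fell below the reference MAC filter and are dropped",
            len(in_scope) - sum(in_scope),
        )
        array = ArrayPanel(
            name=array.name,
            positions=array.positions[np.asarray(in_scope)],
            target_size=array.target_size,
            maf_floor=array.maf_floor,
            scheme=array.scheme,
        )
    id_to_idx = {iid: i for i, iid in enumerate(filtered.individual_ids)}
    results: dict[int, ImputedSet] = {}
    for fold in range(fold_plan.k):
        held = [i for i in fold_plan.fold_members(fold) if target_ids is None or i in set(target_ids)]
        if not held:
            continue
        held_idx = np.array([id_to_idx[i] for i in held])
        ref_idx = np.setdiff1d(np.arange(filtered.n_individuals), held_idx)
        ref = filtered.take_individuals(ref_idx)
        targets = mask_to_panel(filtered.take_individuals(held_idx), array)
        results[fold] = impute_panel(targets, ref, array, params)
    return results


# --------------------------------------------------------------------------- #
# per-variant accuracy
# --------------------------------------------------------------------------- #


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n, m) matrices; NaN where either
    column is constant."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


def per_variant_accuracy(
    imputed_by_fold: dict[int, ImputedSet],
    truth: HaplotypePanel,
    fold_plan: FoldPlan,
    use_dosage: bool = True,
) -> pd.DataFrame:
    """Per-variant empirical accuracy pooled across cross-validation folds.

    ``use_dosage=True`` scores the continuous genotype dosage (the "MMprob"
    contrast); ``False`` scores the most-likely 0/1/2 genotype ("MM012").
    Typed variants and variants monomorphic in either truth or imputation are
    flagged in ``excluded_reason`` with no correlation reported.
    """
    folds = sorted(imputed_by_fold)
    first = imputed_by_fold[folds[0]]
    variants = first.variants
    M = len(variants)

    seen: set[str] = set()
    blocks_imp, blocks_truth, blocks_hap = [], [], []
    typed = np.zeros(M, dtype=bool)
    truth_lookup = {iid: i for i, iid in enumerate(truth.individual_ids)}
    truth_cols = _match_variant_columns(truth.variants, variants)
    truth_geno = truth.genotypes()[:, truth_cols]
    for f in folds:
        imp = imputed_by_fold[f]
        if len(imp.variants) != M or not np.array_equal(
            imp.variants["pos"].to_numpy(), variants["pos"].to_numpy()
        ):
            raise PanelError("imputed sets disagree on variant scope across folds")
        dup = set(imp.individual_ids) & seen
        if dup:
            raise PanelError(f"individual(s) imputed in two folds: {sorted(dup)[:3]}")
        seen |= set(imp.individual_ids)
        rows = [truth_lookup[i] for i in imp.individual_ids]
        blocks_truth.append(truth_geno[rows])
        blocks_imp.append(imp.geno_dosages if use_dosage else imp.most_likely.astype(float))
        blocks_hap.append(imp.hap_dosages)
        typed |= imp.typed_mask

    imp_mat = np.vstack(blocks_imp)
    truth_mat = np.vstack(blocks_truth).astype(float)
    pooled_rsq = rsq_statistic_matrix(np.vstack(blocks_hap))

    r = _pearson_columns(imp_mat, truth_mat)
    mono_truth = truth_mat.var(axis=0) == 0
    mono_imp = imp_mat.var(axis=0) == 0

    excluded = np.full(M, "none", dtype=object)
    excluded[mono_imp] = "monomorphic_imputed"
    excluded[mono_truth] = "monomorphic_truth"
    excluded[typed] = "typed"
    r = np.where(excluded == "none", r, np.nan)

    pos = variants["pos"].to_numpy()
    out = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "pos": pos,
            "empirical_r": r,
            "rsq": pooled_rsq,
            "maf": variants["maf"].to_numpy(),
            "window_id": [
                f"{c}:{(p - 1) // 1_000_000}" for c, p in zip(variants["chrom"], pos)
            ],
            "n_individuals": imp_mat.shape[0],
            "excluded_reason": excluded,
        }
    )
    if "annotation_class" in variants.columns:
        out["annotation_class"] = variants["annotation_class"].to_numpy()
    return out


def _match_variant_columns(truth_variants: pd.DataFrame, scope: pd.DataFrame) -> np.ndarray:
    lookup = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(truth_variants["chrom"], truth_variants["pos"]))
    }
    cols = []
    for c, p in zip(scope["chrom"], scope["pos"]):
        key = (c, int(p))
        if key not in lookup:
            raise PanelError(f"truth panel does not cover imputed variant {key}")
        cols.append(lookup[key])
    return np.asarray(cols, dtype=np.int64)


# --------------------------------------------------------------------------- #
# quality-score thresholds
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ThresholdPolicy:
    """Named predicate on the rsq quality score."""

    name: str
    description: str

    def keep(self, rsq: np.ndarray) -> np.ndarray:
        rsq = np.asarray(rsq, dtype=float)
        if self.name == "thr0":
            return np.ones(rsq.shape, dtype=bool)
        if self.name == "thr4":
            return rsq > 0.4
        if self.name == "thr8":
            return rsq > 0.8
        if self.name == "thr0-4":
            return rsq <= 0.4
        raise PanelError(f"unknown threshold policy {self.name!r}")


THRESHOLD_POLICIES = {
    "thr0": ThresholdPolicy("thr0", "retain all variants"),
    "thr4": ThresholdPolicy("thr4", "retain rsq > 0.4"),
    "thr8": ThresholdPolicy("thr8", "retain rsq > 0.8"),
    "thr0-4": ThresholdPolicy("thr0-4", "retain rsq <= 0.4 (the poorly imputed stratum)"),
}


def apply_threshold(
    acc: pd.DataFrame, policy: ThresholdPolicy | str
) -> tuple[pd.DataFrame, int, int]:
    """Filter the scorable rows of an accuracy table by an rsq policy.

    Returns ``(filtered_table, retained_count, discarded_count)`` where the
    counts partition the scorable variants exactly.
    """
    if isinstance(policy, str):
        if policy not in THRESHOLD_POLICIES:
            raise PanelError(f"unknown threshold policy {policy!r}")
        policy = THRESHOLD_POLICIES[policy]
    scorable = acc[acc["excluded_reason"] == "none"]
    keep = policy.keep(scorable["rsq"].to_numpy())
    retained = scorable[keep]
    return retained.reset_index(drop=True), int(keep.sum()), int((~keep).sum())


# --------------------------------------------------------------------------- #
# stratified summaries
# --------------------------------------------------------------------------- #

MAF_BANDS_DEFAULT = [
    (0.01, 0.02), (0.02, 0.03), (0.03, 0.04), (0.04, 0.05), (0.05, 0.06),
    (0.06, 0.07), (0.07, 0.08), (0.08, 0.10), (0.10, 0.50),
]

# Alternative reporting ladder (non-contiguous, with one overlapping band
# pair) kept as a preset for lining results up against published tables.
MAF_BANDS_PRINTED = [
    (0.01, 0.02), (0.02, 0.03), (0.03, 0.04), (0.05, 0.06),
    (0.06, 0.07), (0.06, 0.08), (0.08, 0.10), (0.10, 0.50),
]

STRATIFIERS = ("maf_bands", "rsq_bins", "windows_1mb", "annotation_class", "chromosome")


def stratified_summary(
    acc: pd.DataFrame,
    stratifier: str,
    maf_bands: list[tuple[float, float]] | None = None,
    min_count: int = 0,
) -> pd.DataFrame:
    """Mean empirical accuracy, variant count and mean rsq per stratum.

    Strata: ``maf_bands`` (half-open bands, final band closed at 0.5),
    ``rsq_bins`` (100 half-open bins of width 0.01 on the clamped rsq, final
    bin closed at 1.0), ``windows_1mb`` (half-open 1-Mb windows), and the
    categorical ``annotation_class`` / ``chromosome``.  Exclusion counts and
    any out-of-stratum count are recorded in ``result.attrs['accounting']``
    so that stratum counts + exclusions reconcile with the total.
    """
    if len(acc) == 0:
        raise PanelError("accuracy table is empty")
    if stratifier not in STRATIFIERS:
        raise PanelError(f"unknown stratifier {stratifier!r}; one of {STRATIFIERS}")
    excl_counts = acc["excluded_reason"].value_counts().to_dict()
    scorable = acc[acc["excluded_reason"] == "none"].copy()

    out_of_stratum = 0
    if stratifier == "maf_bands":
        bands = maf_bands or MAF_BANDS_DEFAULT
        rows = []
        covered = np.zeros(len(scorable), dtype=bool)
        maf = scorable["maf"].to_numpy()
        for lo, hi in bands:
            closed_hi = hi >= 0.5
            mask = (maf >= lo) & ((maf <= hi) if closed_hi else (maf < hi))
            covered |= mask
            rows.append(_stratum_row(f"{lo:g}-{hi:g}", scorable[mask]))
        out_of_stratum = int((~covered).sum())
        summary = pd.DataFrame(rows)
    elif stratifier == "rsq_bins":
        rsq = np.clip(scorable["rsq"].to_numpy(), 0.0, 1.0)
        binned = np.minimum(np.floor(rsq * 100).astype(int), 99)
        rows = []
        for b in range(100):
            sub = scorable[binned == b]
            rows.append(
                _stratum_row(f"{b / 100:.2f}-{(b + 1) / 100:.2f}", sub, midpoint=(b + 0.5) / 100)
            )
        summary = pd.DataFrame(rows)
    elif stratifier == "windows_1mb":
        rows = []
        for wid, sub in scorable.groupby("window_id", sort=False):
            chrom, w = wid.rsplit(":", 1)
            rows.append(
                _stratum_row(wid, sub)
                | {"chrom": chrom, "window_start": int(w) * 1_000_000,
                   "window_end": (int(w) + 1) * 1_000_000}
            )
        summary = pd.DataFrame(rows)
        summary = summary.sort_values(["chrom", "window_start"]).reset_index(drop=True)
    elif stratifier == "annotation_class":
        if "annotation_class" not in scorable.columns:
            raise PanelError("accuracy table has no annotation_class column")
        rows = [
            _stratum_row(cls, sub)
            for cls, sub in scorable.groupby("annotation_class", sort=True)
        ]
        summary = pd.DataFrame(rows)
    else:  # chromosome
        rows = [_stratum_row(c, sub) for c, sub in scorable.groupby("chrom", sort=False)]
        summary = pd.DataFrame(rows)

    if min_count:
        summary = summary[summary["n"] >= min_count].reset_index(drop=True)
    summary.attrs["accounting"] = {
        "total_variants": int(len(acc)),
        "scorable": int(len(scorable)),
        "excluded": {k: int(v) for k, v in excl_counts.items() if k != "none"},
        "out_of_stratum": out_of_stratum,
    }
    return summary


def _stratum_row(label: str, sub: pd.DataFrame, **extra) -> dict:
    row = {
        "stratum": label,
        "n": int(len(sub)),
        "mean_r": float(sub["empirical_r"].mean()) if len(sub) else np.nan,
        "mean_rsq": float(sub["rsq"].mean()) if len(sub) else np.nan,
    }
    row.update(extra)
    return row
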