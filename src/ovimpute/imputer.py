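"""Reference-panel haplotype-copying imputation.

A target haplotype observed only at array positions is modelled as an
imperfect mosaic of the reference haplotypes (the Li-Stephens model): the
hidden state is the reference haplotype being copied, transitions between
adjacent variants allow a recombination switch with probability growing in
map distance, and emissions at typed sites match the observed allele with
probability ``1 - error_rate``.  Untyped sites carry uninformative emissions,
so their posteriors interpolate between the flanking typed sites.  The
forward-backward posterior expectation of the alternative allele is the
haplotype dosage; summing an individual's two haplotype dosages gives the
familiar 0-2 genotype dosage, and rounding it gives the most-likely genotype.

Each imputed variant also receives the dosage-variance quality statistic
``rsq``: the ratio of the observed dosage variance across target haplotypes
to the binomial variance expected from perfectly called alleles at the
estimated frequency.  Poorly imputed variants shrink towards the allele
frequency, deflating that ratio towards zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import ls_forward_backward_dosages
from .types import ArrayPanel, HaplotypePanel, PanelError

__all__ = [
    "HmmParams",
    "ImputedSet",
    "RawReference",
    "LiStephensImputer",
    "filter_reference",
    "li_stephens_posteriors",
    "impute_panel",
    "rsq_statistic",
    "stepwise_impute",
]

logger = logging.getLogger(__name__)


@dataclass
class HmmParams:
    """Copying-model parameters.

    error_rate
        Per-site allele mismatch probability (emission), in (0, 0.5).
    switch_scale
        Expected haplotype switches per Morgan; with the default map scale of
        1 cM/Mb, the default of 100 gives about one expected switch per Mb.
    cm_per_mb
        Map-scale constant converting physical to map distance.
    """

    error_rate: float = 1e-3
    switch_scale: float = 100.0
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise PanelError("error_rate must be in (0, 0.5)")
        if self.switch_scale <= 0 or self.cm_per_mb <= 0:
            raise PanelError("switch_scale and cm_per_mb must be positive")

    def stay_probabilities(self, variants: pd.DataFrame) -> np.ndarray:
        """P(no switch) between adjacent variants; 0 across chromosomes."""
        pos = variants["pos"].to_numpy(dtype=float)
        chrom = variants["chrom"].to_numpy()
        d_bp = np.diff(pos)
        d_morgan = d_bp * 1e-6 * self.cm_per_mb / 100.0
        stay = np.exp(-self.switch_scale * d_morgan)
        stay[chrom[1:] != chrom[:-1]] = 0.0
        return stay


@dataclass
class ImputedSet:
    """Imputation output over the full reference variant scope."""

    variants: pd.DataFrame
    hap_dosages: np.ndarray  # (2N, M) in [0, 1]
    geno_dosages: np.ndarray  # (N, M) in [0, 2]
    most_likely: np.ndarray  # (N, M) in {0, 1, 2}
    rsq: np.ndarray  # (M,) raw statistic, may marginally exceed 1
    typed_mask: np.ndarray  # (M,) bool, True at array positions
    individual_ids: list[str] = field(default_factory=list)

    @property
    def rsq_clamped(self) -> np.ndarray:
        """rsq clipped to [0, 1] for binning/reporting."""
        return np.clip(self.rsq, 0.0, 1.0)

    @property
    def n_individuals(self) -> int:
        return self.geno_dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.geno_dosages.shape[1]


# --------------------------------------------------------------------------- #
# reference filtering
# --------------------------------------------------------------------------- #


def filter_reference(panel: HaplotypePanel, min_mac: int = 5) -> HaplotypePanel:
    """Restrict a reference panel to variants with MAC >= ``min_mac``.

    Variants are biallelic by construction here (multi-allelic records are
    rejected at VCF load time); the removal log is stored under
    ``metadata['filter_log']`` and logged at INFO level.
    """
    panel.refresh_frequencies()
    mac = panel.variants["mac"].to_numpy()
    keep = mac >= min_mac
    out = panel.take_variants(np.flatnonzero(keep))
    log = {
        "input_variants": int(len(keep)),
        "removed_mac_below_min": int((~keep).sum()),
        "min_mac": int(min_mac),
        "retained": int(keep.sum()),
    }
    out.metadata = {**panel.metadata, "filter_log": log}
    if log["retained"] == 0:
        logger.warning("reference filter removed every variant (min_mac=%d)", min_mac)
    logger.info(
        "reference filter: %d -> %d variants (removed %d with MAC < %d)",
        log["input_variants"], log["retained"], log["removed_mac_below_min"], min_mac,
    )
    return out


# --------------------------------------------------------------------------- #
# forward-backward
# --------------------------------------------------------------------------- #


@dataclass
class RawReference:
    """Bare copying source: any (H, M) 0/1 matrix plus variant coordinates.

    Unlike :class:`~ovimpute.types.HaplotypePanel` this places no diploid
    pairing constraint on the rows, which is occasionally useful when probing
    the HMM with an odd number of reference haplotypes.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


def _observation_vector(
    n_variants: int, typed_idx: np.ndarray, alleles: np.ndarray
) -> np.ndarray:
    obs = np.full(n_variants, -1, dtype=np.int8)
    obs[typed_idx] = alleles
    return obs


def li_stephens_posteriors(
    target_alleles: np.ndarray,
    typed_idx: np.ndarray,
    ref: HaplotypePanel | RawReference,
    params: HmmParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Full copying-state posteriors for one target haplotype.

    Parameters
    ----------
    target_alleles
        0/1 alleles observed at the typed sites.
    typed_idx
        Column indices of the typed sites within the reference panel.

    Returns
    -------
    posteriors : (M, H) array, rows summing to 1
    hap_dosages : (M,) posterior expectation of the alternative allele

    Notes
    -----
    This is a plain NumPy implementation kept deliberately simple (scaled
    forward-backward); :func:`impute_panel` runs the same recursion through a
    compiled kernel.
    """
    H = ref.n_haplotypes
    M = ref.n_variants
    if H < 2:
        raise PanelError("reference panel needs at least 2 haplotypes")
    typed_idx = np.asarray(typed_idx, dtype=np.int64)
    if typed_idx.size and (typed_idx.min() < 0 or typed_idx.max() >= M):
        raise PanelError("typed position index outside reference scope")
    obs = _observation_vector(M, typed_idx, np.asarray(target_alleles, dtype=np.int8))
    stay = params.stay_probabilities(ref.variants)
    eps = params.error_rate
    refmat = ref.haplotypes  # (H, M)

    def emission(j: int) -> np.ndarray:
        if obs[j] < 0:
            return np.ones(H)
        return np.where(refmat[:, j] == obs[j], 1.0 - eps, eps)

    alpha = np.empty((M, H))
    a = emission(0) / H
    alpha[0] = a / a.sum()
    for j in range(1, M):
        st = stay[j - 1]
        pred = st * alpha[j - 1] + (1.0 - st) / H
        a = pred * emission(j)
        alpha[j] = a / a.sum()

    posteriors = np.empty((M, H))
    beta = np.ones(H)
    post = alpha[M - 1] * beta
    posteriors[M - 1] = post / post.sum()
    for j in range(M - 2, -1, -1):
        st = stay[j]
        btmp = beta * emission(j + 1)
        beta = st * btmp + (1.0 - st) * btmp.mean()
        beta /= beta.max()
        post = alpha[j] * beta
        posteriors[j] = post / post.sum()

    hap_dosages = np.einsum("mh,hm->m", posteriors, refmat.astype(float))
    return posteriors, hap_dosages


# --------------------------------------------------------------------------- #
# panel imputation
# --------------------------------------------------------------------------- #


def _typed_indices(ref: HaplotypePanel, array: ArrayPanel) -> np.ndarray:
    lookup = ref.variant_indexer()
    idx = []
    for c, p in zip(array.positions["chrom"], array.positions["pos"]):
        key = (c, int(p))
        if key not in lookup:
            raise PanelError(f"typed position {key} absent from reference panel")
        idx.append(lookup[key])
    return np.asarray(idx, dtype=np.int64)


def impute_panel(
    targets: HaplotypePanel,
    ref: HaplotypePanel,
    array: ArrayPanel,
    params: HmmParams | None = None,
) -> ImputedSet:
    """Impute phased targets observed at ``array`` positions up to the full
    reference scope.

    The targets must already be restricted to the array positions (see
    :func:`ovimpute.evaluate.mask_to_panel`) and the reference should already
    be MAC-filtered.
    """
    params = params or HmmParams()
    if ref.n_haplotypes < 2:
        raise PanelError("reference panel needs at least 2 haplotypes")
    typed_idx = _typed_indices(ref, array)
    if targets.n_variants != len(typed_idx):
        raise PanelError(
            f"targets carry {targets.n_variants} variants but the array has "
            f"{len(typed_idx)}; mask targets to the array first"
        )
    # target variant positions must line up with the array
    t_keys = list(zip(targets.variants["chrom"], targets.variants["pos"].astype(int)))
    a_keys = list(zip(array.positions["chrom"], array.positions["pos"].astype(int)))
    if t_keys != a_keys:
        raise PanelError("target variant positions do not match the array positions")

    M = ref.n_variants
    T = targets.n_haplotypes
    obs = np.full((T, M), -1, dtype=np.int8)
    obs[:, typed_idx] = targets.haplotypes
    stay = params.stay_probabilities(ref.variants)
    dosages = np.empty((T, M))
    ls_forward_backward_dosages(
        np.ascontiguousarray(ref.haplotypes),
        obs,
        stay.astype(np.float64),
        float(params.error_rate),
        dosages,
    )
    hap_dosages = np.clip(dosages, 0.0, 1.0)
    geno_dosages = hap_dosages[0::2] + hap_dosages[1::2]
    most_likely = np.clip(np.round(geno_dosages), 0, 2).astype(np.int8)
    rsq = rsq_statistic_matrix(hap_dosages)
    typed_mask = np.zeros(M, dtype=bool)
    typed_mask[typed_idx] = True
    return ImputedSet(
        variants=ref.variants.copy(),
        hap_dosages=hap_dosages,
        geno_dosages=geno_dosages,
        most_likely=most_likely,
        rsq=rsq,
        typed_mask=typed_mask,
        individual_ids=list(targets.individual_ids),
    )


class LiStephensImputer:
    """Model-object facade: bind a reference panel and parameters once, then
    impute any number of masked target panels against it."""

    def __init__(self, ref: HaplotypePanel, params: HmmParams | None = None,
                 min_mac: int | None = 5):
        self.params = params or HmmParams()
        self.ref = filter_reference(ref, min_mac) if min_mac is not None else ref

    def impute(self, targets: HaplotypePanel, array: ArrayPanel) -> ImputedSet:
        return impute_panel(targets, self.ref, array, self.params)


# --------------------------------------------------------------------------- #
# quality statistic
# --------------------------------------------------------------------------- #


def rsq_statistic(hap_dosages: np.ndarray) -> float:
    """Dosage-variance imputation quality statistic for one variant.

    ``rsq = PopVar(d) / (p(1-p))`` with ``p = mean(d)`` over all target
    haplotype dosages ``d`` (population variance, dividing by the haplotype
    count).  Returns 0 when the estimated frequency is 0 or 1.  The raw value
    may marginally exceed 1; clamping is applied only downstream.
    """
    d = np.asarray(hap_dosages, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise PanelError("need at least 2 haplotype dosages")
    if d.min() < 0.0 or d.max() > 1.0:
        raise PanelError("haplotype dosages must lie in [0, 1]")
    if d.max() == d.min():
        return 0.0  # constant dosages: fully shrunk, and exactly so
    p = d.mean()
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(d.var() / (p * (1.0 - p)))


def rsq_statistic_matrix(hap_dosages: np.ndarray) -> np.ndarray:
    """Vectorised :func:`rsq_statistic` over variants (columns)."""
    d = np.asarray(hap_dosages, dtype=float)
    p = d.mean(axis=0)
    var = d.var(axis=0)
    denom = p * (1.0 - p)
    out = np.zeros(d.shape[1])
    ok = (denom > 0) & (d.max(axis=0) > d.min(axis=0))
    out[ok] = var[ok] / denom[ok]
    return out


# --------------------------------------------------------------------------- #
# stepwise imputation
# --------------------------------------------------------------------------- #


def _harden_to_panel(imp: ImputedSet, ids: list[str], breed_labels: list[str]) -> HaplotypePanel:
    """Round haplotype dosages to best-guess alleles for the next stage."""
    hard = np.round(imp.hap_dosages).astype(np.uint8)
    variants = imp.variants.copy()
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=hard,
        individual_ids=list(ids),
        breed_labels=list(breed_labels),
    )
    panel.refresh_frequencies()
    return panel


def stepwise_impute(
    targets_ld: HaplotypePanel,
    ref_50k: HaplotypePanel,
    ref_hd: HaplotypePanel,
    ref_wgs: HaplotypePanel,
    arrays: dict[str, ArrayPanel],
    params: HmmParams | None = None,
) -> ImputedSet:
    """Three-stage imputation LD -> 50k -> HD -> WGS.

    Between stages the haplotype dosages are hardened to best-guess alleles,
    mirroring how chained runs of imputation tools consume hard genotypes.
    The final ``typed_mask`` marks the HD positions, so downstream accuracy
    evaluation excludes them exactly as it does for direct HD -> WGS runs.
    """
    params = params or HmmParams()
    for smaller, larger in (("LD", "50k"), ("50k", "HD")):
        if not arrays[smaller].is_subset_of(arrays[larger]):
            raise PanelError(f"array {smaller} is not nested inside {larger}")
    wgs_keys = set(zip(ref_wgs.variants["chrom"], ref_wgs.variants["pos"].astype(int)))
    if not arrays["HD"].key_set() <= wgs_keys:
        raise PanelError("HD array positions are not a subset of the WGS reference")

    ids = list(targets_ld.individual_ids)
    labels = list(targets_ld.breed_labels)
    stage1 = impute_panel(targets_ld, ref_50k, arrays["LD"], params)
    stage1_panel = _harden_to_panel(stage1, ids, labels)
    stage2 = impute_panel(stage1_panel, ref_hd, arrays["50k"], params)
    stage2_panel = _harden_to_panel(stage2, ids, labels)
    final = impute_panel(stage2_panel, ref_wgs, arrays["HD"], params)
    return final
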