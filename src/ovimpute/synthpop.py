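"""Synthetic multi-breed population generator.

Everything downstream (masking, imputation, accuracy evaluation, genomic
prediction) is exercised against panels produced here, so the generator aims
for the *phenomenology* that matters to those stages rather than coalescent
realism:

* a shared ancestral haplotype pool with a rare-skewed site-frequency
  spectrum, so the sequence-level MAF distribution is dominated by rare
  alleles while array ascertainment flattens it;
* per-breed bottlenecks followed by generations of recombination-mosaic
  descent, so breeds drift apart (Fst grows with divergence time) while
  retaining the long shared haplotypes that haplotype-copying imputation
  exploits;
* F1 crosses that carry one haplotype from each parental breed;
* annotation labels with class-specific MAF skew, and an optional
  low-fidelity region where haplotype sharing is deliberately broken.

All operations are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ANNOTATION_CLASSES, ArrayPanel, HaplotypePanel, PanelError, PhenotypeTable

__all__ = [
    "BreedSpec",
    "CrossSpec",
    "SimConfig",
    "default_config",
    "simulate_population",
    "ascertain_array_panel",
    "ascertain_nested_panels",
    "assign_annotation_classes",
    "simulate_phenotypes",
    "inject_low_fidelity_region",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class BreedSpec:
    """One pure breed: bottleneck size, divergence time, and pool size.

    founder_haplotypes is the bottleneck draw from the ancestral pool;
    generations is the number of rounds of recombination-mosaic descent
    (more generations = more drift away from the other breeds);
    ne_haplotypes is the per-generation haplotype pool size (a stand-in for
    2*Ne; larger pools drift less, emulating the ordering of effective
    population sizes between breeds).
    """

    n_individuals: int
    founder_haplotypes: int = 40
    generations: int = 30
    ne_haplotypes: int = 150


@dataclass
class CrossSpec:
    """F1 cross between two pure breeds; one haplotype from each parent."""

    name: str
    parents: tuple[str, str]
    n_individuals: int


DEFAULT_CLASS_PROPORTIONS = {
    "intergenic": 0.63,
    "intronic": 0.30,
    "updownstream5kb": 0.064,
    "missense": 0.003,
    "utr": 0.003,
}

# Multiplier applied to the sampling weight of variants with MAF < 0.05 when a
# class picks its members: functional classes are enriched for rare alleles.
DEFAULT_CLASS_MAF_BIAS = {
    "missense": 8.0,
    "utr": 4.0,
    "updownstream5kb": 1.5,
    "intronic": 1.0,
    "intergenic": 1.0,
}


@dataclass
class SimConfig:
    seed: int = 0
    n_variants: int = 40_000
    chrom_length_bp: int = 20_000_000
    n_chroms: int = 2
    breeds: dict[str, BreedSpec] = field(default_factory=dict)
    crosses: list[CrossSpec] = field(default_factory=list)
    ancestral_haplotypes: int = 400
    recomb_rate_per_bp_per_gen: float = 1e-8
    mutation_spectrum_skew: float = 1.0
    # fraction of sites whose allele arises as a single new mutation during a
    # breed's descent (young, breed-private, rare-skewed variants) rather than
    # segregating in the ancestral pool
    young_variant_fraction: float = 0.4
    array_sizes: dict[str, int] = field(default_factory=dict)
    array_maf_floor: float = 0.05
    class_proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    class_maf_bias: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAF_BIAS))
    # (chrom, start_bp, end_bp, error_rate, density_multiplier)
    problem_regions: list[tuple] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_variants <= 0 or self.chrom_length_bp <= 0 or self.n_chroms <= 0:
            raise ConfigError("genome dimensions must be positive")
        if self.ancestral_haplotypes < 2:
            raise ConfigError("need at least 2 ancestral haplotypes")
        if not self.breeds:
            raise ConfigError("at least one breed required")
        for name, b in self.breeds.items():
            if min(b.n_individuals, b.founder_haplotypes, b.ne_haplotypes) <= 0:
                raise ConfigError(f"breed {name}: counts must be positive")
            if b.generations < 0:
                raise ConfigError(f"breed {name}: generations must be >= 0")
        for cr in self.crosses:
            if len(set(cr.parents)) < 2:
                raise ConfigError(f"cross {cr.name}: needs two distinct parent breeds")
            for p in cr.parents:
                if p not in self.breeds:
                    raise ConfigError(f"cross {cr.name}: unknown parent breed {p}")
        if self.crosses and len(self.breeds) < 2:
            raise ConfigError("crossbreds requested with fewer than 2 breeds")
        if self.array_sizes:
            biggest = max(self.array_sizes.values())
            if self.n_variants < biggest:
                raise ConfigError(
                    f"n_variants ({self.n_variants}) smaller than largest array ({biggest})"
                )
        if not 0.0 <= self.young_variant_fraction < 1.0:
            raise ConfigError("young_variant_fraction must be in [0, 1)")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        for region in self.problem_regions:
            chrom, start, end = region[0], region[1], region[2]
            if not self._chrom_known(chrom) or start < 1 or end > self.chrom_length_bp or start >= end:
                raise ConfigError(f"problem region {region} lies outside the genome")

    def _chrom_known(self, chrom: str) -> bool:
        return chrom in {f"chr{i}" for i in range(1, self.n_chroms + 1)}


def default_config(seed: int = 0) -> SimConfig:
    """Desk-scale default emulating the reference/target design:
    117 Merino-like, 29 Poll-Dorset-like, 30 Border-Leicester-like purebreds
    plus 59 BLxMER F1 crosses, with per-breed pool sizes ordered like the
    breeds' published effective population sizes (MER > PD > BL)."""
    cfg = SimConfig(
        seed=seed,
        n_variants=100_000,
        breeds={
            "MER": BreedSpec(117, founder_haplotypes=250, generations=20, ne_haplotypes=250),
            "PD": BreedSpec(29, founder_haplotypes=120, generations=20, ne_haplotypes=120),
            "BL": BreedSpec(30, founder_haplotypes=100, generations=20, ne_haplotypes=100),
        },
        crosses=[CrossSpec("F1", ("BL", "MER"), 59)],
        array_sizes={"LD": 400, "50k": 1600, "HD": 6000},
    )
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------- #
# population simulation
# --------------------------------------------------------------------------- #


def _draw_positions(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chroms, cfg.n_variants // cfg.n_chroms)
    per_chrom[: cfg.n_variants % cfg.n_chroms] += 1
    frames = []
    for i, n in enumerate(per_chrom):
        pos = rng.choice(cfg.chrom_length_bp, size=int(n), replace=False) + 1
        pos.sort()
        frames.append(pd.DataFrame({"chrom": f"chr{i + 1}", "pos": pos}))
    out = pd.concat(frames, ignore_index=True)
    alleles = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=len(out))
    alt = (ref + rng.integers(1, 4, size=len(out))) % 4
    out["ref_allele"] = alleles[ref]
    out["alt_allele"] = alleles[alt]
    return out


def _ancestral_pool(rng: np.random.Generator, n_hap: int, n_var: int, skew: float) -> np.ndarray:
    """Haplotype pool whose per-site alt counts follow a truncated i**-skew
    spectrum, i = 1..n_hap-1 (every site polymorphic in the pool)."""
    counts = np.arange(1, n_hap)
    weights = counts.astype(float) ** (-skew)
    weights /= weights.sum()
    alt_counts = rng.choice(counts, size=n_var, p=weights)
    pool = np.zeros((n_hap, n_var), dtype=np.uint8)
    # random permutation per column, carriers are the first alt_counts[j] rows
    order = np.argsort(rng.random((n_hap, n_var)), axis=0)
    pool[order < alt_counts[None, :]] = 1
    return pool


def _meiosis(
    rng: np.random.Generator,
    pool: np.ndarray,
    chrom_bounds: list[tuple[int, int]],
    positions: np.ndarray,
    rate: float,
    chrom_length: int,
) -> np.ndarray:
    """One recombinant haplotype from two random parents in ``pool``."""
    i, j = rng.integers(0, pool.shape[0], size=2)
    child = pool[i].copy()
    for lo, hi in chrom_bounds:
        n_xo = rng.poisson(rate * chrom_length)
        if n_xo == 0:
            # whole chromosome from a random one of the two parents
            if rng.random() < 0.5:
                child[lo:hi] = pool[j, lo:hi]
            continue
        breaks = np.sort(rng.integers(1, chrom_length + 1, size=n_xo))
        parity = np.searchsorted(breaks, positions[lo:hi], side="right") % 2
        if rng.random() < 0.5:
            parity = 1 - parity
        seg = np.where(parity == 0, pool[i, lo:hi], pool[j, lo:hi])
        child[lo:hi] = seg
    return child


def _chrom_bounds(variants: pd.DataFrame) -> list[tuple[int, int]]:
    bounds = []
    start = 0
    codes = variants["chrom"].to_numpy()
    for chrom in pd.unique(codes):
        n = int((codes == chrom).sum())
        bounds.append((start, start + n))
        start += n
    return bounds


def simulate_population(config: SimConfig) -> HaplotypePanel:
    """Simulate the full phased panel: purebreds plus any requested crosses.

    A ``young_variant_fraction`` of sites starts monomorphic and receives its
    first (and only) mutation on a single haplotype at a random point of a
    random breed's descent, weighted by that breed's mutation opportunity
    (generations x pool size).  Young variants are therefore rare, often
    breed-private, and sit on a single haplotype background — the variants
    that are genuinely hard to impute.  Per-breed sub-panels are recovered
    with :meth:`HaplotypePanel.subset_breed`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants = _draw_positions(rng, config)
    M = len(variants)
    positions = variants["pos"].to_numpy()
    bounds = _chrom_bounds(variants)

    # split sites into ancestral and young
    breed_names = list(config.breeds)
    opportunity = np.array(
        [config.breeds[b].generations * config.breeds[b].ne_haplotypes for b in breed_names],
        dtype=float,
    )
    n_young = int(round(config.young_variant_fraction * M))
    if opportunity.sum() == 0:
        n_young = 0
    young_sites = (
        np.sort(rng.choice(M, size=n_young, replace=False)) if n_young else np.empty(0, int)
    )
    is_young = np.zeros(M, dtype=bool)
    is_young[young_sites] = True

    pool0 = np.zeros((config.ancestral_haplotypes, M), dtype=np.uint8)
    pool0[:, ~is_young] = _ancestral_pool(
        rng, config.ancestral_haplotypes, int((~is_young).sum()), config.mutation_spectrum_skew
    )

    # schedule each young site: which breed, which generation, which haplotype
    young_by_breed_gen: dict[tuple[str, int], list[int]] = {}
    if n_young:
        breed_pick = rng.choice(len(breed_names), size=n_young, p=opportunity / opportunity.sum())
        for site, b_i in zip(young_sites, breed_pick):
            b = breed_names[b_i]
            g = int(rng.integers(0, config.breeds[b].generations))
            young_by_breed_gen.setdefault((b, g), []).append(int(site))

    def descend(name: str, spec: BreedSpec) -> np.ndarray:
        take = rng.choice(
            config.ancestral_haplotypes,
            size=spec.founder_haplotypes,
            replace=spec.founder_haplotypes > config.ancestral_haplotypes,
        )
        pool = pool0[take].copy()
        for g in range(spec.generations):
            for site in young_by_breed_gen.get((name, g), ()):
                pool[rng.integers(0, pool.shape[0]), site] = 1
            nxt = np.empty((spec.ne_haplotypes, pool.shape[1]), dtype=np.uint8)
            for h in range(spec.ne_haplotypes):
                nxt[h] = _meiosis(
                    rng, pool, bounds, positions,
                    config.recomb_rate_per_bp_per_gen, config.chrom_length_bp,
                )
            pool = nxt
        return pool

    breed_pools = {name: descend(name, spec) for name, spec in config.breeds.items()}

    haplotypes: list[np.ndarray] = []
    ids: list[str] = []
    breeds: list[str] = []
    for name, spec in config.breeds.items():
        for k in range(spec.n_individuals):
            for _ in range(2):
                haplotypes.append(
                    _meiosis(rng, breed_pools[name], bounds, positions,
                             config.recomb_rate_per_bp_per_gen, config.chrom_length_bp)
                )
            ids.append(f"{name}_{k:04d}")
            breeds.append(name)
    for cr in config.crosses:
        a, b = cr.parents
        for k in range(cr.n_individuals):
            for parent in (a, b):
                haplotypes.append(
                    _meiosis(rng, breed_pools[parent], bounds, positions,
                             config.recomb_rate_per_bp_per_gen, config.chrom_length_bp)
                )
            ids.append(f"{cr.name}_{k:04d}")
            breeds.append(cr.name)

    hap = np.vstack(haplotypes)
    panel = HaplotypePanel(
        variants=variants.assign(maf=0.0, mac=0),
        haplotypes=hap,
        individual_ids=ids,
        breed_labels=breeds,
        metadata={
            "seed": config.seed,
            "n_chroms": config.n_chroms,
            "chrom_length_bp": config.chrom_length_bp,
            "generator": "ancestral-pool + recombination-mosaic descent",
        },
    )
    panel.refresh_frequencies()
    return panel


# --------------------------------------------------------------------------- #
# array ascertainment
# --------------------------------------------------------------------------- #


class ShortfallError(PanelError):
    """Not enough eligible variants to fill a request; carries the deficit."""

    def __init__(self, message: str, deficit: int):
        super().__init__(message)
        self.deficit = deficit


def ascertain_array_panel(
    panel: HaplotypePanel,
    target_size: int,
    maf_floor: float = 0.05,
    scheme: str = "uniform_maf",
    seed: int = 0,
    name: str = "array",
    eligible_mask: np.ndarray | None = None,
) -> ArrayPanel:
    """Pick ``target_size`` SNPs with MAF >= ``maf_floor`` for an array.

    scheme="uniform_maf" balances the pick across MAF deciles of
    [maf_floor, 0.5] as far as each decile's supply allows, flattening the
    array's MAF spectrum the way commercial chip ascertainment does;
    scheme="random_common" draws uniformly from all eligible variants.
    """
    if scheme not in ("uniform_maf", "random_common"):
        raise ConfigError(f"unknown ascertainment scheme: {scheme}")
    rng = np.random.default_rng(seed)
    maf = panel.variants["maf"].to_numpy()
    eligible = maf >= maf_floor
    if eligible_mask is not None:
        eligible &= eligible_mask
    idx_eligible = np.flatnonzero(eligible)
    if len(idx_eligible) < target_size:
        deficit = target_size - len(idx_eligible)
        raise ShortfallError(
            f"array {name!r}: requested {target_size} SNPs with MAF >= {maf_floor} "
            f"but only {len(idx_eligible)} are eligible (deficit {deficit})",
            deficit,
        )
    if scheme == "random_common":
        chosen = rng.choice(idx_eligible, size=target_size, replace=False)
    else:
        edges = np.linspace(maf_floor, 0.5, 11)
        bins = np.clip(np.searchsorted(edges, maf[idx_eligible], side="right") - 1, 0, 9)
        by_bin = [idx_eligible[bins == b] for b in range(10)]
        quota = _balanced_quota([len(g) for g in by_bin], target_size)
        parts = [
            rng.choice(g, size=q, replace=False)
            for g, q in zip(by_bin, quota)
            if q > 0
        ]
        chosen = np.concatenate(parts)
    chosen.sort()
    pos = panel.variants.iloc[chosen][["chrom", "pos"]]
    return ArrayPanel(name=name, positions=pos, target_size=target_size,
                      maf_floor=maf_floor, scheme=scheme)


def _balanced_quota(supply: list[int], total: int) -> list[int]:
    """Spread ``total`` across bins as evenly as supply permits."""
    n = len(supply)
    quota = [0] * n
    remaining = total
    open_bins = [i for i in range(n) if supply[i] > 0]
    while remaining > 0 and open_bins:
        share = max(1, remaining // len(open_bins))
        progressed = False
        for i in list(open_bins):
            give = min(share, supply[i] - quota[i], remaining)
            if give > 0:
                quota[i] += give
                remaining -= give
                progressed = True
            if quota[i] == supply[i]:
                open_bins.remove(i)
            if remaining == 0:
                break
        if not progressed:
            break
    return quota


def ascertain_nested_panels(
    panel: HaplotypePanel,
    sizes: dict[str, int] | None = None,
    maf_floor: float = 0.05,
    scheme: str = "uniform_maf",
    seed: int = 0,
) -> dict[str, ArrayPanel]:
    """Build the LD/50k/HD hierarchy with exact nesting LD c 50k c HD."""
    sizes = sizes or {"LD": 400, "50k": 1600, "HD": 6000}
    order = sorted(sizes, key=sizes.get, reverse=True)  # largest first
    panels: dict[str, ArrayPanel] = {}
    mask = None
    for k, name in enumerate(order):
        arr = ascertain_array_panel(
            panel, sizes[name], maf_floor, scheme, seed=seed + k, name=name,
            eligible_mask=mask,
        )
        panels[name] = arr
        mask = arr.member_mask(panel.variants)
    return panels


# --------------------------------------------------------------------------- #
# annotation labels
# --------------------------------------------------------------------------- #


def assign_annotation_classes(
    variants: pd.DataFrame,
    class_proportions: dict[str, float] | None = None,
    class_maf_bias: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Label every variant with one of the five annotation classes.

    Class counts are fixed exactly from the requested proportions (largest
    remainder), so realized marginal proportions match the request; *which*
    variants land in each class is a weighted draw where the bias multiplies
    the weight of rare (MAF < 0.05) variants, giving functional classes a
    rare-skewed MAF profile.
    """
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    bias = dict(class_maf_bias or DEFAULT_CLASS_MAF_BIAS)
    unknown = set(props) - set(ANNOTATION_CLASSES)
    if unknown:
        raise ConfigError(f"unknown annotation classes: {sorted(unknown)}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"class proportions sum to {total}, expected 1")

    n = len(variants)
    rng = np.random.default_rng(seed)
    classes = [c for c in ANNOTATION_CLASSES if props.get(c, 0) > 0]
    exact = {c: props[c] * n for c in classes}
    counts = {c: int(np.floor(exact[c])) for c in classes}
    leftover = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True)[:leftover]:
        counts[c] += 1

    maf = variants["maf"].to_numpy()
    rare = maf < 0.05
    labels = np.empty(n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    # assign the most rare-biased classes first so their weighting bites
    for c in sorted(classes, key=lambda c: bias.get(c, 1.0), reverse=True):
        k = counts[c]
        if k == 0:
            continue
        pool = np.flatnonzero(unassigned)
        w = np.where(rare[pool], bias.get(c, 1.0), 1.0)
        # Efraimidis-Spirakis weighted sampling without replacement
        keys = rng.random(len(pool)) ** (1.0 / w)
        take = pool[np.argsort(keys)[-k:]]
        labels[take] = c
        unassigned[take] = False
    return variants.assign(annotation_class=labels)


# --------------------------------------------------------------------------- #
# phenotypes
# --------------------------------------------------------------------------- #


def simulate_phenotypes(
    panel: HaplotypePanel,
    n_causal: int,
    target_h2: float,
    seed: int = 0,
) -> PhenotypeTable:
    """Additive phenotypes: TBV from random causal variants, residual scaled
    (after orthogonalising against the TBV) so the realised Var(TBV)/Var(y)
    equals ``target_h2``."""
    if not 0.0 <= target_h2 <= 1.0:
        raise ConfigError(f"target_h2 must be in [0, 1], got {target_h2}")
    if n_causal > panel.n_variants:
        raise ConfigError("n_causal exceeds number of variants")
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    if target_h2 == 0.0:
        tbv = np.zeros(n)
        y = rng.standard_normal(n)
    else:
        causal = rng.choice(panel.n_variants, size=n_causal, replace=False)
        X = panel.genotypes()[:, causal].astype(float)
        beta = rng.standard_normal(n_causal)
        tbv = X @ beta
        tbv -= tbv.mean()
        var_g = tbv.var()
        if var_g == 0:
            raise ConfigError("causal variants are monomorphic; no genetic variance")
        if target_h2 == 1.0:
            y = tbv.copy()
        else:
            e = rng.standard_normal(n)
            e -= e.mean()
            e -= tbv * (e @ tbv) / (tbv @ tbv)  # orthogonalise so the ratio is exact
            e *= np.sqrt(var_g * (1 - target_h2) / target_h2) / e.std()
            y = tbv + e
    frame = pd.DataFrame(
        {"individual_id": panel.individual_ids, "y_adj": y, "true_breeding_value": tbv}
    )
    return PhenotypeTable(frame=frame, target_h2=target_h2)


# --------------------------------------------------------------------------- #
# low-fidelity region injection
# --------------------------------------------------------------------------- #


def inject_low_fidelity_region(
    panel: HaplotypePanel,
    region: tuple[str, int, int],
    error_rate: float,
    density_multiplier: float,
    seed: int = 0,
) -> HaplotypePanel:
    """Make a genomic region hard to impute.

    Within ``region = (chrom, start, end)`` (closed interval, bp) the variant
    density is multiplied by ``density_multiplier`` — new variants are
    inserted with random haplotype assignment, so they carry no LD — and
    existing haplotype entries are flipped independently at ``error_rate``,
    which breaks local haplotype sharing.  Outside the region the panel is
    unchanged.  This emulates regions where assembly problems produce a low
    density of reliable array SNPs and a high density of noisy sequence
    variants.
    """
    chrom, start, end = region
    if not 0.0 <= error_rate <= 0.5:
        raise ConfigError("error_rate must be in [0, 0.5]")
    if density_multiplier < 1:
        raise ConfigError("density_multiplier must be >= 1")
    chroms = set(panel.variants["chrom"])
    if chrom not in chroms:
        raise ConfigError(f"region chromosome {chrom!r} not in panel")
    length = panel.metadata.get("chrom_length_bp")
    if start < 1 or start >= end or (length is not None and end > length):
        raise ConfigError(f"region {region} lies outside the genome")
    if error_rate == 0.0 and density_multiplier == 1.0:
        return HaplotypePanel(
            variants=panel.variants.copy(),
            haplotypes=panel.haplotypes.copy(),
            individual_ids=list(panel.individual_ids),
            breed_labels=list(panel.breed_labels),
            metadata=dict(panel.metadata),
        )

    rng = np.random.default_rng(seed)
    v = panel.variants
    in_region = (v["chrom"] == chrom).to_numpy() & (v["pos"].to_numpy() >= start) & (
        v["pos"].to_numpy() <= end
    )
    hap = panel.haplotypes.copy()
    if error_rate > 0 and in_region.any():
        cols = np.flatnonzero(in_region)
        flips = rng.random((hap.shape[0], len(cols))) < error_rate
        hap[:, cols] = np.where(flips, 1 - hap[:, cols], hap[:, cols])

    n0 = int(in_region.sum())
    n_new = int(rng.poisson(n0 * (density_multiplier - 1.0)))
    new_variants = v
    if n_new > 0:
        existing = set(v.loc[in_region, "pos"].astype(int))
        new_pos: set[int] = set()
        while len(new_pos) < n_new:
            draw = rng.integers(start, end + 1, size=n_new - len(new_pos))
            new_pos.update(int(p) for p in draw if int(p) not in existing)
        new_pos_arr = np.array(sorted(new_pos))
        n_hap = hap.shape[0]
        counts = np.arange(1, n_hap)
        w = counts.astype(float) ** -1.5
        w /= w.sum()
        alt_counts = rng.choice(counts, size=n_new, p=w)
        new_cols = np.zeros((n_hap, n_new), dtype=np.uint8)
        order = np.argsort(rng.random((n_hap, n_new)), axis=0)
        new_cols[order < alt_counts[None, :]] = 1

        alleles = np.array(list("ACGT"))
        ref = rng.integers(0, 4, size=n_new)
        alt = (ref + rng.integers(1, 4, size=n_new)) % 4
        extra = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": new_pos_arr,
                "ref_allele": alleles[ref],
                "alt_allele": alleles[alt],
                "maf": 0.0,
                "mac": 0,
            }
        )
        if "annotation_class" in v.columns:
            cls = v["annotation_class"].value_counts(normalize=True)
            extra["annotation_class"] = rng.choice(
                cls.index.to_numpy(), size=n_new, p=cls.to_numpy()
            )
        merged = pd.concat([v, extra], ignore_index=True)
        hap = np.concatenate([hap, new_cols], axis=1)
        order_idx = np.lexsort(
            (merged["pos"].to_numpy(), merged["chrom"].to_numpy())
        )
        # keep original chromosome order, sort positions within chrom
        chrom_order = {c: i for i, c in enumerate(pd.unique(v["chrom"]))}
        order_idx = np.lexsort(
            (merged["pos"].to_numpy(), merged["chrom"].map(chrom_order).to_numpy())
        )
        new_variants = merged.iloc[order_idx].reset_index(drop=True)
        hap = hap[:, order_idx]

    out = HaplotypePanel(
        variants=new_variants.reset_index(drop=True),
        haplotypes=hap,
        individual_ids=list(panel.individual_ids),
        breed_labels=list(panel.breed_labels),
        metadata={**panel.metadata, "low_fidelity_region": (chrom, int(start), int(end))},
    )
    out.refresh_frequencies()
    return out
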