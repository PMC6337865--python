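import numpy as np
import pandas as pd
import pytest

from ovimpute.evaluate import cross_validate_impute, make_fold_plan, per_variant_accuracy
from ovimpute.synthpop import (
    BreedSpec,
    CrossSpec,
    SimConfig,
    ascertain_nested_panels,
    simulate_population,
)
from ovimpute.types import HaplotypePanel


def tiny_sim_config(seed: int = 7) -> SimConfig:
    cfg = SimConfig(
        seed=seed,
        n_variants=4_000,
        chrom_length_bp=2_000_000,
        n_chroms=2,
        breeds={
            "MER": BreedSpec(30, founder_haplotypes=60, generations=8, ne_haplotypes=60),
            "PD": BreedSpec(10, founder_haplotypes=40, generations=8, ne_haplotypes=40),
            "BL": BreedSpec(10, founder_haplotypes=40, generations=8, ne_haplotypes=40),
        },
        crosses=[CrossSpec("F1", ("BL", "MER"), 6)],
        array_sizes={"LD": 40, "50k": 150, "HD": 500},
    )
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_panel(tiny_cfg) -> HaplotypePanel:
    return simulate_population(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_arrays(tiny_panel, tiny_cfg):
    return ascertain_nested_panels(
        tiny_panel, tiny_cfg.array_sizes, maf_floor=tiny_cfg.array_maf_floor, seed=11
    )


@pytest.fixture(scope="session")
def tiny_cv(tiny_panel, tiny_arrays):
    plan = make_fold_plan(tiny_panel.individual_ids, k=5, seed=13)
    mer = [
        i for i, b in zip(tiny_panel.individual_ids, tiny_panel.breed_labels) if b == "MER"
    ]
    imputed = cross_validate_impute(tiny_panel, tiny_arrays["HD"], plan, target_ids=mer)
    return {"plan": plan, "imputed": imputed}


@pytest.fixture(scope="session")
def tiny_acc(tiny_cv, tiny_panel) -> pd.DataFrame:
    return per_variant_accuracy(
        tiny_cv["imputed"], tiny_panel, tiny_cv["plan"], use_dosage=True
    )


def make_panel(haplotypes: np.ndarray, positions=None, chrom="chr1", breed="B") -> HaplotypePanel:
    """Hand-build a panel from a raw (2N, M) 0/1 matrix."""
    hap = np.asarray(haplotypes, dtype=np.uint8)
    n2, m = hap.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "ref_allele": "A",
            "alt_allele": "C",
            "maf": 0.0,
            "mac": 0,
        }
    )
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=hap,
        individual_ids=[f"ind{i}" for i in range(n2 // 2)],
        breed_labels=[breed] * (n2 // 2),
    )
    panel.refresh_frequencies()
    return panel
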