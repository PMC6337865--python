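"""VCF 4.2 and TSV interfaces.

Panels travel as phased VCF (GT with ``|``); imputation output mirrors the
conventions of reference-panel imputation tools: per-sample GT (most-likely
genotype) and DS (dosage, 3 decimals), per-variant INFO keys R2 (raw quality
statistic), MAF and the TYPED flag.  Arrays are two-column TSVs.  Provenance
(seed, generator parameters) rides in ``##`` header lines.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .imputer import ImputedSet
from .types import ArrayPanel, HaplotypePanel, PanelError

__all__ = [
    "write_panel_vcf",
    "load_phased_vcf",
    "write_imputed_vcf",
    "load_imputed_vcf",
    "write_array_tsv",
    "load_array_tsv",
]


class VcfFormatError(PanelError):
    """Malformed or contract-violating VCF content."""


def write_panel_vcf(panel: HaplotypePanel, path: str | os.PathLike) -> None:
    """Write a phased panel as uncompressed VCF 4.2."""
    path = Path(path)
    v = panel.variants
    chroms = list(pd.unique(v["chrom"]))
    length = panel.metadata.get("chrom_length_bp")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            ln = length or int(v.loc[v["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        for key, val in sorted(panel.metadata.items()):
            fh.write(f"##ovimpute_{key}={val}\n")
        fh.write(f"##ovimpute_breeds={','.join(panel.breed_labels)}\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        hap = panel.haplotypes
        for j in range(panel.n_variants):
            row = v.iloc[j]
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(panel.n_individuals)
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref_allele']}\t"
                f"{row['alt_allele']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def load_phased_vcf(path: str | os.PathLike, require_phased: bool = True) -> HaplotypePanel:
    """Load a phased VCF into a :class:`HaplotypePanel`.

    Multiallelic records are rejected (and counted in
    ``metadata['removal_log']``); an unphased genotype raises an error naming
    the first offending record when ``require_phased`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises C-level errors
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    breed_line = None
    metadata: dict = {}
    for raw in vcf.raw_header.splitlines():
        if raw.startswith("##ovimpute_breeds="):
            breed_line = raw.split("=", 1)[1]
        elif raw.startswith("##ovimpute_"):
            key = raw[len("##ovimpute_"):].split("=", 1)
            if len(key) == 2:
                metadata[key[0]] = key[1]
    rows = []
    haps: list[np.ndarray] = []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        g = np.array(rec.genotypes, dtype=object)
        if require_phased and len(g) and not all(trip[2] for trip in rec.genotypes):
            raise VcfFormatError(
                f"unphased genotype at {rec.CHROM}:{rec.POS}; a phased panel is required"
            )
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, trip in enumerate(rec.genotypes):
            a0, a1 = trip[0], trip[1]
            if a0 < 0 or a1 < 0:
                raise VcfFormatError(f"missing genotype at {rec.CHROM}:{rec.POS}")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        haps.append(col)
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref_allele", "alt_allele"])
    variants["maf"] = 0.0
    variants["mac"] = 0
    hap = (
        np.stack(haps, axis=1)
        if haps
        else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    )
    if breed_line is not None and breed_line:
        breeds = breed_line.split(",")
    else:
        breeds = ["unknown"] * len(samples)
    metadata["removal_log"] = {"multiallelic": n_multiallelic}
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=hap,
        individual_ids=samples,
        breed_labels=breeds,
        metadata=metadata,
    )
    if panel.n_variants:
        panel.refresh_frequencies()
    return panel


def write_imputed_vcf(imputed: ImputedSet, path: str | os.PathLike) -> None:
    """Write imputed genotypes with GT/DS per sample and R2/MAF/TYPED INFO."""
    path = Path(path)
    v = imputed.variants
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Most likely genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage 0-2">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Dosage-variance imputation quality">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Reference minor allele frequency">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Array (observed) position">\n')
        for c in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={c},length={int(v.loc[v['chrom'] == c, 'pos'].max())}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(imputed.individual_ids)
            + "\n"
        )
        for j in range(imputed.n_variants):
            row = v.iloc[j]
            info = f"R2={imputed.rsq[j]:.6g};MAF={row['maf']:.6g}"
            if imputed.typed_mask[j]:
                info += ";TYPED"
            fields = "\t".join(
                f"{gt_codes[int(imputed.most_likely[i, j])]}:{imputed.geno_dosages[i, j]:.3f}"
                for i in range(imputed.n_individuals)
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref_allele']}\t"
                f"{row['alt_allele']}\t.\tPASS\t{info}\tGT:DS\t{fields}\n"
            )


def load_imputed_vcf(path: str | os.PathLike) -> ImputedSet:
    """Read back an imputed VCF (GT/DS + R2/MAF/TYPED)."""
    vcf = VCF(str(Path(path)))
    samples = list(vcf.samples)
    rows, ds_cols, gt_cols, rsq, typed = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise VcfFormatError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.INFO.get("MAF", 0.0), 0))
        ds_cols.append(np.asarray(rec.format("DS"), dtype=float).ravel())
        gt = np.array([t[0] + t[1] for t in rec.genotypes], dtype=np.int8)
        gt_cols.append(gt)
        rsq.append(float(rec.INFO.get("R2", 0.0)))
        typed.append(rec.INFO.get("TYPED") is not None)
    vcf.close()
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref_allele", "alt_allele", "maf", "mac"]
    )
    geno = np.stack(ds_cols, axis=1) if ds_cols else np.zeros((len(samples), 0))
    most = np.stack(gt_cols, axis=1) if gt_cols else np.zeros((len(samples), 0), dtype=np.int8)
    hap = np.clip(np.repeat(geno / 2.0, 2, axis=0), 0.0, 1.0)
    return ImputedSet(
        variants=variants,
        hap_dosages=hap,
        geno_dosages=geno,
        most_likely=most,
        rsq=np.asarray(rsq),
        typed_mask=np.asarray(typed, dtype=bool),
        individual_ids=samples,
    )


def write_array_tsv(array: ArrayPanel, path: str | os.PathLike) -> None:
    array.positions.to_csv(path, sep="\t", index=False)


def load_array_tsv(path: str | os.PathLike, name: str = "array") -> ArrayPanel:
    pos = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"} <= set(pos.columns):
        raise VcfFormatError(f"array TSV {path} needs 'chrom' and 'pos' columns")
    return ArrayPanel(name=name, positions=pos, target_size=len(pos))
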