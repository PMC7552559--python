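"""Readers and writers: phenotype/genotype TSV, minimal VCF 4.2, run config.

Dialects: tab-delimited tables with a header row and ``NA`` for missing;
genotype TSV is subjects x SNPs with alternate-allele counts 0/1/2.  VCF input
goes through cyvcf2 (biallelic SNP records with GT; ``./.`` is a missing
category, not an error).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, SNPRecord

NA = "NA"


def write_phenotypes(cohort: Cohort, path) -> Path:
    path = Path(path)
    df = cohort.phenotypes.reset_index()
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.10g")
    return path


def write_genotypes_tsv(cohort: Cohort, path) -> Path:
    path = Path(path)
    g = cohort.genotypes.copy()
    out = g.reset_index()
    for c in g.columns:  # integers where present, NA where missing
        out[c] = out[c].map(lambda v: NA if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)
    return path


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(cohort: Cohort, path) -> Path:
    """Minimal VCF 4.2 with one biallelic SNP record per genotype column."""
    path = Path(path)
    samples = list(cohort.phenotypes.index.astype(str))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=telomr",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for i, snp in enumerate(cohort.snp_ids):
        rec = cohort.snps.get(snp, SNPRecord(snp))
        pos = rec.position or (i + 1) * 1000
        gts = [
            _GT.get(v, "./.") if not pd.isna(v) else "./."
            for v in cohort.genotypes[snp].to_numpy(dtype=float)
        ]
        lines.append(
            f"{rec.chromosome}\t{pos}\t{snp}\t{rec.ref_allele}\t{rec.alt_allele}"
            "\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_cohort(cohort: Cohort, out_dir, genotype_format: str = "tsv") -> dict[str, Path]:
    """Write phenotype table, genotypes (TSV or VCF) and a metadata sidecar.

    The metadata records the simulation seed (when present) so every written
    cohort is traceable to its generator state.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"phenotypes": write_phenotypes(cohort, out_dir / "phenotypes.tsv")}
    if genotype_format == "tsv":
        paths["genotypes"] = write_genotypes_tsv(cohort, out_dir / "genotypes.tsv")
    elif genotype_format == "vcf":
        paths["genotypes"] = write_genotypes_vcf(cohort, out_dir / "genotypes.vcf")
    else:
        raise ValueError("genotype_format must be 'tsv' or 'vcf'")
    meta = {k: v for k, v in cohort.meta.items() if k in ("seed", "draws_used", "source")}
    meta["n_cases"] = cohort.n_cases
    meta["n_controls"] = cohort.n_controls
    (out_dir / "cohort_meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    paths["meta"] = out_dir / "cohort_meta.yaml"
    return paths


def _read_genotypes_vcf(path, required_snps: Optional[Sequence[str]]):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    records: dict[str, SNPRecord] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"malformed or multi-allelic VCF record at {variant.ID}")
        g = variant.gt_types.astype(float)  # gts012: 0,1,2; 3 = unknown
        g[g == 3] = np.nan
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        data[snp_id] = g
        records[snp_id] = SNPRecord(
            snp_id, str(variant.CHROM), None, variant.REF, variant.ALT[0], variant.POS
        )
    df = pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))
    _check_required(df, required_snps)
    return df, records


def _read_genotypes_tsv(path, required_snps):
    df = pd.read_csv(path, sep="\t", na_values=[NA], dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "subject_id"
    df = df.astype(float)
    _check_required(df, required_snps)
    return df, {}


def _check_required(df, required_snps):
    if required_snps:
        missing = [s for s in required_snps if s not in df.columns]
        if missing:
            raise KeyError(f"genotype source lacks listed SNP(s): {missing}")


def read_cohort(
    phenotype_path,
    genotype_path,
    required_snps: Optional[Sequence[str]] = None,
) -> Cohort:
    """Join a phenotype table with a genotype source on subject id.

    Subjects present in only one file are dropped with a warning (and listed
    in ``cohort.meta['unmatched']``).  Duplicate subject ids and a non-binary
    outcome column are errors.
    """
    pheno = pd.read_csv(phenotype_path, sep="\t", na_values=[NA], dtype={0: str})
    pheno = pheno.set_index(pheno.columns[0])
    pheno.index.name = "subject_id"
    if pheno.index.has_duplicates:
        raise ValueError("duplicate subject ids in phenotype table")
    if str(genotype_path).endswith((".vcf", ".vcf.gz")):
        geno, records = _read_genotypes_vcf(genotype_path, required_snps)
    else:
        geno, records = _read_genotypes_tsv(genotype_path, required_snps)
    if geno.index.has_duplicates:
        raise ValueError("duplicate subject ids in genotype source")
    common = pheno.index.intersection(geno.index)
    unmatched = sorted(set(pheno.index.symmetric_difference(geno.index)))
    if unmatched:
        warnings.warn(f"{len(unmatched)} subject(s) present in only one input; dropped",
                      stacklevel=2)
    cohort = Cohort(pheno.loc[common], geno.loc[common], snps=records)
    cohort.meta["unmatched"] = unmatched
    cohort.meta["source"] = {"phenotypes": str(phenotype_path),
                             "genotypes": str(genotype_path)}
    return cohort


def load_run_config(path) -> dict:
    """Load the structured key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg
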