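"""Configuration files, tabular output, and minimal VCF support.

Run configuration is a single YAML document::

    format_version: 1
    n_replicates: 100
    base_seed: 1000
    gene_model:                  # either a synthetic spec ...
      spec: {total_length: 1678, n_exons: 2, exon_fraction: 0.5, seed: 7}
      # ... or files:  {model: model.json, fasta: segment.fa}
    sets:
      Set1: {mu: 1.0e-8, r0: 1.0e-6, c: 0.03, pop_chromosomes: 100,
             generations: 100000}

All tables are tab-separated with a ``# zwturnover ... v1`` format tag as
the first line; readers reject unknown major versions.  Positions are
0-based half-open everywhere except at the VCF boundary (1-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .locus import GeneModel
from .simulate import BatchResult, ReplicateResult, SimParams
from .synth import Cohort, LocusSpec, generate_gene_model

REPLICATE_TAG = "# zwturnover replicate table v1"
TABLE1_TAG = "# zwturnover table1 v1"


@dataclass
class RunConfig:
    gene_model: GeneModel
    sets: dict[str, SimParams]
    n_replicates: int
    base_seed: int


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run-configuration YAML file."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    major = int(doc.get("format_version", 0))
    if major != 1:
        raise ValueError(f"{path}: unsupported config format_version {major}")
    gm_doc = doc.get("gene_model", {"spec": {}})
    if "spec" in gm_doc:
        gene_model = generate_gene_model(LocusSpec(**(gm_doc["spec"] or {})))
    elif "model" in gm_doc and "fasta" in gm_doc:
        base = path.parent
        gene_model = GeneModel.load(base / gm_doc["model"], base / gm_doc["fasta"])
    else:
        raise ValueError(f"{path}: gene_model needs 'spec' or 'model'+'fasta'")
    sets_doc = doc.get("sets")
    if not sets_doc:
        raise ValueError(f"{path}: no parameter sets defined")
    sets = {}
    for label, pd_ in sets_doc.items():
        known = {"mu", "r0", "c", "pop_chromosomes", "generations", "record_every"}
        extra = set(pd_) - known
        if extra:
            raise ValueError(f"{path}: set {label!r}: unknown keys {sorted(extra)}")
        params = SimParams(gene_model=gene_model, **pd_)
        params.validate()
        sets[label] = params
    return RunConfig(
        gene_model=gene_model,
        sets=sets,
        n_replicates=int(doc.get("n_replicates", 100)),
        base_seed=int(doc.get("base_seed", 0)),
    )


# --------------------------------------------------------------------- #
# simulation tables


def replicate_frame(batch: BatchResult, set_label: str) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(batch.replicates):
        c, d = r.census, r.diversity
        rows.append(
            {
                "set": set_label,
                "replicate": i,
                "seed": r.seed,
                "status": r.termination_status,
                "generations": r.generations_run,
                "turnover": int(c.turnover),
                "n_fixed": len(c.fixed_lof),
                "n_nonfixed": len(c.nonfixed_lof),
                "w_count": c.w_class_count,
                "z_count": c.z_class_count,
                "pi_all": d.pi_all,
                "pi_w": d.pi_w,
                "pi_z": d.pi_z,
                "dxy": d.dxy,
                "fst": d.fst,
            }
        )
    return pd.DataFrame(rows)


def write_replicate_tsv(batch: BatchResult, set_label: str, path: str | Path) -> None:
    frame = replicate_frame(batch, set_label)
    with open(path, "w") as fh:
        fh.write(REPLICATE_TAG + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_replicate_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        tag = fh.readline().strip()
        if not tag.startswith("# zwturnover replicate table v"):
            raise ValueError(f"{path}: not a replicate table")
        if tag != REPLICATE_TAG:
            raise ValueError(f"{path}: unsupported replicate-table version: {tag}")
        return pd.read_csv(fh, sep="\t")


def table1_frame(rows: dict[str, tuple[SimParams, dict]]) -> pd.DataFrame:
    """Summary-table layout: one row per set, TS% and census histograms."""
    out = []
    for label, (params, agg) in rows.items():
        row = {
            "set": label,
            "mu": params.mu,
            "r0": params.r0,
            "pop_chromosomes": params.pop_chromosomes,
            "n_replicates": agg["n_replicates"],
            "ts_percent": agg["ts_percent"],
        }
        for i, v in enumerate(agg["fixed_hist"]):
            row[f"fixed_{i}" if i < 4 else "fixed_4plus"] = v
        for i, v in enumerate(agg["nonfixed_hist"]):
            row[f"nonfixed_{i}" if i < 5 else "nonfixed_5plus"] = v
        out.append(row)
    return pd.DataFrame(out)


def table1_from_replicate_frames(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate previously written per-replicate tables into summary rows."""
    data = pd.concat(frames, ignore_index=True)
    rows = []
    for label, grp in data.groupby("set", sort=False):
        done = grp[grp["status"] == "completed"]
        n = len(done)
        if n == 0:
            raise ValueError(f"set {label!r}: no completed replicates")
        row = {
            "set": label,
            "n_replicates": n,
            "ts_percent": 100.0 * done["turnover"].sum() / n,
        }
        for i in range(5):
            sel = done["n_fixed"] >= 4 if i == 4 else done["n_fixed"] == i
            row[f"fixed_{i}" if i < 4 else "fixed_4plus"] = int(sel.sum())
        for i in range(6):
            sel = done["n_nonfixed"] >= 5 if i == 5 else done["n_nonfixed"] == i
            row[f"nonfixed_{i}" if i < 5 else "nonfixed_5plus"] = int(sel.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def write_table1_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(TABLE1_TAG + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_run_metadata(
    path: str | Path, config_like: dict, seeds: list[int]
) -> None:
    meta = {
        "format_version": 1,
        "package": "zwturnover",
        "version": __version__,
        "seeds": seeds,
        **config_like,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


def write_final_haplotypes_fasta(result: ReplicateResult, path: str | Path) -> None:
    """FASTA dump of a replicate's final distinct haplotypes.

    One record per distinct haplotype; the id encodes functional class
    (W/Z) and chromosome count.
    """
    gm = result.params.gene_model
    seq = list(gm.reference_sequence)
    with open(path, "w") as fh:
        for i, (diffs, functional, count) in enumerate(result.haplotypes):
            s = seq.copy()
            for p, b in diffs.items():
                s[p] = b
            cls = "W" if functional else "Z"
            fh.write(f">hap{i}|class={cls}|count={count}\n")
            body = "".join(s)
            for j in range(0, len(body), 70):
                fh.write(body[j : j + 70] + "\n")


# --------------------------------------------------------------------- #
# minimal VCF (v4.2 subset: biallelic, GT only)


def write_cohort_vcf(cohort: Cohort, path: str | Path) -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    samples = list(cohort.genotypes.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zwturnover\n")
        for chrom in dict.fromkeys(cohort.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, var in cohort.variants.iterrows():
            gts = "\t".join(gt_str[int(g)] for g in cohort.genotypes.iloc[i])
            fh.write(
                f"{var.chrom}\t{var.pos + 1}\t.\t{var.ref}\t{var.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic VCF into (variants, genotypes) frames.

    Genotypes are alt-allele counts with -1 for missing; positions are
    converted to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    var_rows, gt_rows = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        var_rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        gts = []
        for g in v.genotypes:
            a, b = g[0], g[1]
            gts.append(-1 if a < 0 or b < 0 else int(a) + int(b))
        gt_rows.append(gts)
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = pd.DataFrame(gt_rows, columns=samples, dtype=np.int16)
    return variants, genotypes


def write_cohort_tsv(cohort: Cohort, geno_path: str | Path, sex_path: str | Path) -> None:
    """Native TSV: genotype matrix (variants x samples) and a sex table."""
    with open(geno_path, "w") as fh:
        fh.write("# zwturnover genotype table v1\n")
        out = pd.concat(
            [cohort.variants[["chrom", "pos", "ref", "alt"]], cohort.genotypes], axis=1
        )
        out.to_csv(fh, sep="\t", index=False)
    with open(sex_path, "w") as fh:
        fh.write("# zwturnover sex table v1\n")
        cohort.sex.rename("sex").rename_axis("sample").reset_index().to_csv(
            fh, sep="\t", index=False
        )


def read_sex_tsv(path: str | Path) -> pd.Series:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(0)
        frame = pd.read_csv(fh, sep="\t")
    return frame.set_index("sample")["sex"]
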