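"""Readers and writers for the package's plain-text interchange formats.

* genotypes: tab-delimited dialect of PLINK ``.raw`` — header ``FID IID``
  then one ``<snp>_<allele>`` column per SNP (standard ``.raw`` headers with
  PAT/MAT/SEX/PHENOTYPE columns are also accepted on read);
* SNP map: whitespace table ``CHR SNP BP A1`` (extended with ``A2 MAF`` on
  write, tolerated on read);
* summary statistics: whitespace table ``SNP CHR BP A1 BETA P`` (optional
  ``A2``);
* ESM data: long-format CSV;
* ground-truth record: JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prs import GenotypeDosageMatrix, GwasSummaryStats, PrsProfile
from .synth import TrueParamRecord

__all__ = [
    "write_genotypes_raw",
    "read_genotypes_raw",
    "write_snp_map",
    "read_snp_map",
    "write_summary_stats",
    "read_summary_stats",
    "write_esm_csv",
    "read_esm_csv",
    "write_true_params",
    "write_prs_tsv",
]

_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def write_genotypes_raw(geno: GenotypeDosageMatrix, path: str | Path) -> None:
    cols = {
        "FID": geno.subject_ids,
        "IID": geno.subject_ids,
    }
    df = pd.DataFrame(cols)
    for j, snp in enumerate(geno.snp_ids):
        a1 = geno.snp_map.loc[snp, "a1"]
        df[f"{snp}_{a1}"] = geno.dosages[:, j]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_raw(path: str | Path, snp_map: pd.DataFrame) -> GenotypeDosageMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in df.columns if c in _RAW_META]
    snp_cols = [c for c in df.columns if c not in _RAW_META]
    snp_ids, dosages = [], []
    for col in snp_cols:
        snp, _, allele = col.rpartition("_")
        if snp not in snp_map.index:
            raise ValueError(f"SNP {snp!r} from genotype file absent from map")
        if str(snp_map.loc[snp, "a1"]) != allele:
            raise ValueError(
                f"counted allele {allele!r} of {snp!r} does not match map a1"
            )
        snp_ids.append(snp)
        dosages.append(df[col].to_numpy(dtype=float))
    subjects = df["IID"].astype(str).tolist() if "IID" in meta else [
        str(i) for i in range(len(df))
    ]
    return GenotypeDosageMatrix(
        subject_ids=subjects,
        snp_ids=snp_ids,
        dosages=np.column_stack(dosages),
        snp_map=snp_map.loc[snp_ids],
    )


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "CHR": snp_map["chrom"].to_numpy(),
            "SNP": snp_map.index,
            "BP": snp_map["bp"].to_numpy(),
            "A1": snp_map["a1"].to_numpy(),
        }
    )
    if "a2" in snp_map.columns:
        out["A2"] = snp_map["a2"].to_numpy()
    if "maf" in snp_map.columns:
        out["MAF"] = snp_map["maf"].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str})
    out = pd.DataFrame(
        {
            "chrom": df["CHR"].astype(str).to_numpy(),
            "bp": df["BP"].astype(int).to_numpy(),
            "a1": df["A1"].astype(str).to_numpy(),
        },
        index=pd.Index(df["SNP"].astype(str), name="snp_id"),
    )
    if "A2" in df.columns:
        out["a2"] = df["A2"].astype(str).to_numpy()
    if "MAF" in df.columns:
        out["maf"] = df["MAF"].to_numpy(dtype=float)
    return out


def write_summary_stats(stats: GwasSummaryStats, path: str | Path) -> None:
    t = stats.table
    out = pd.DataFrame(
        {
            "SNP": t["snp_id"],
            "CHR": t["chrom"],
            "BP": t["bp"],
            "A1": t["a1"],
            "BETA": t["beta"],
            "P": t["p"],
        }
    )
    if "a2" in t.columns:
        out["A2"] = t["a2"]
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> GwasSummaryStats:
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str})
    table = pd.DataFrame(
        {
            "snp_id": df["SNP"].astype(str),
            "chrom": df["CHR"].astype(str),
            "bp": df["BP"].astype(int),
            "a1": df["A1"].astype(str),
            "beta": df["BETA"].astype(float),
            "p": df["P"].astype(float),
        }
    )
    if "A2" in df.columns:
        table["a2"] = df["A2"].astype(str).to_numpy()
    return GwasSummaryStats(table)


def write_esm_csv(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, index=False)


def read_esm_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["observed"] = df["observed"].astype(bool)
    return df


def write_true_params(record: TrueParamRecord, path: str | Path) -> None:
    payload = {
        "params": dataclasses.asdict(record.params),
        "model": dataclasses.asdict(record.model),
        "target_outcome": record.target_outcome,
        "context": record.context,
        "g": {k: float(v) for k, v in record.g.items()},
        "u": {k: float(v) for k, v in record.u.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_prs_tsv(profile: PrsProfile, path: str | Path) -> None:
    profile.scores.reset_index().to_csv(path, sep="\t", index=False)
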