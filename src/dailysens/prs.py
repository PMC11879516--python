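"""Clumping + thresholding polygenic scores.

Implements the classical C+T pipeline: greedy LD clumping of GWAS summary
statistics against a genotype reference, followed by allele-aligned weighted
allele-count scoring at a ladder of p-value thresholds.  The LD reference is
the analysis genotype matrix itself; r² is the squared Pearson correlation of
dosage vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeDosageMatrix",
    "GwasSummaryStats",
    "PrsProfile",
    "ld_r2",
    "clump",
    "score",
]


@dataclass
class GenotypeDosageMatrix:
    """Subjects × SNPs dosage table with a SNP map.

    Dosages count copies of the effect allele (``a1`` in ``snp_map``) and lie
    in [0, 2]; NaN marks a missing call.  ``snp_map`` is indexed by SNP id
    with columns ``chrom`` (label), ``bp`` (int), ``a1`` (effect allele),
    ``a2`` (other allele) and optionally ``maf``.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.subject_ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        missing = set(self.snp_ids) - set(self.snp_map.index)
        if missing:
            raise ValueError(f"{len(missing)} SNPs absent from snp_map")
        self._col = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._col[snp_id]]

    def imputed(self) -> np.ndarray:
        """Dosages with per-SNP mean imputation of missing calls."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d


@dataclass
class GwasSummaryStats:
    """Per-SNP GWAS records: effect size on the ``a1`` allele and p-value."""

    table: pd.DataFrame  # columns: snp_id, chrom, bp, a1, a2, beta, p

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "bp", "a1", "beta", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"summary stats missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in summary stats")
        p = self.table["p"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("snp_id")


@dataclass
class PrsProfile:
    """Polygenic scores at a ladder of p-value thresholds.

    ``scores`` is indexed by subject with one column per threshold; SNP sets
    are nested across thresholds by construction.
    """

    thresholds: list[float]
    scores: pd.DataFrame
    n_snps_used: dict[float, int]
    retained_snps: dict[float, list[str]]
    n_dropped_alleles: int = 0
    _zcache: dict = field(default_factory=dict, repr=False)

    def column(self, threshold: float) -> str:
        return f"prs_{threshold:g}"

    def values(self, threshold: float) -> pd.Series:
        return self.scores[self.column(threshold)]

    def zscores(self, threshold: float) -> pd.Series:
        """Score standardized across subjects (the scale used in models)."""
        s = self.values(threshold)
        sd = s.std(ddof=0)
        if sd == 0:
            raise ValueError(f"PRS at threshold {threshold} is constant")
        return (s - s.mean()) / sd


def ld_r2(geno: GenotypeDosageMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Monomorphic SNPs cannot tag anything, so a zero-variance vector yields
    r² = 0 with a warning rather than an error.
    """
    a = geno.dosage_vector(snp_a)
    b = geno.dosage_vector(snp_b)
    a = np.where(np.isnan(a), np.nanmean(a), a)
    b = np.where(np.isnan(b), np.nanmean(b), b)
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        warnings.warn(
            f"zero-variance SNP in LD computation ({snp_a}, {snp_b}); r2 set to 0",
            stacklevel=2,
        )
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def _standardized_dosages(geno: GenotypeDosageMatrix) -> np.ndarray:
    """Mean-imputed, centered, unit-norm columns (zero-variance cols -> 0)."""
    d = geno.imputed()
    d = d - d.mean(axis=0)
    norm = np.sqrt((d * d).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, d / np.where(norm > 0, norm, 1.0), 0.0)
    return z


def clump(
    stats: GwasSummaryStats,
    geno: GenotypeDosageMatrix,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> list[str]:
    """Greedy LD clumping: keep index SNPs, remove their LD neighbourhood.

    SNPs are visited in ascending p (ties broken by chromosome, position,
    id).  A visited SNP not yet removed becomes an index SNP; every other
    not-yet-kept SNP on the same chromosome within ±``window_kb`` and with
    r² ≥ ``r2_max`` to it is removed.  The kept set is returned in genomic
    order and does not depend on the input row order.
    """
    if len(stats) == 0:
        return []
    tab = stats.table
    unknown = set(tab["snp_id"]) - set(geno.snp_ids)
    if unknown:
        raise ValueError(f"{len(unknown)} summary-stat SNPs absent from genotypes")

    order = tab.sort_values(
        ["p", "chrom", "bp", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    z = _standardized_dosages(geno)
    col = geno._col
    chrom = order["chrom"].to_numpy()
    bp = order["bp"].to_numpy(dtype=np.int64)
    ids = order["snp_id"].to_numpy()
    window_bp = int(window_kb * 1000)

    removed = np.zeros(len(order), dtype=bool)
    kept = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        if removed[i]:
            continue
        kept[i] = True
        near = (
            ~removed
            & ~kept
            & (chrom == chrom[i])
            & (np.abs(bp - bp[i]) <= window_bp)
        )
        if not near.any():
            continue
        zi = z[:, col[ids[i]]]
        cand = np.where(near)[0]
        zc = z[:, [col[s] for s in ids[cand]]]
        r2 = (zi @ zc) ** 2
        removed[cand[r2 >= r2_max]] = True

    kept_tab = order.loc[kept, ["snp_id", "chrom", "bp"]]
    kept_tab = kept_tab.sort_values(["chrom", "bp", "snp_id"], kind="mergesort")
    return kept_tab["snp_id"].tolist()


def score(
    geno: GenotypeDosageMatrix,
    stats: GwasSummaryStats,
    retained: list[str],
    thresholds: list[float],
) -> PrsProfile:
    """Weighted allele-count scores: Σ dosage·beta over retained SNPs with p < τ.

    When the genotype's effect allele is the summary-stat other allele, the
    dosage is flipped to 2−dosage so both count the same allele.  SNPs whose
    allele labels match neither orientation are dropped (logged).  Missing
    dosages are mean-imputed per SNP before scoring; threshold comparison is
    strict (p < τ).
    """
    st = stats.indexed()
    missing = [s for s in retained if s not in st.index]
    if missing:
        raise ValueError(f"retained SNPs absent from summary stats: {missing[:5]}")
    thresholds = sorted(float(t) for t in thresholds)
    d = geno.imputed()
    gmap = geno.snp_map
    stats_has_a2 = "a2" in st.columns

    usable: list[tuple[str, float, float]] = []  # (snp, p, beta) with aligned dosage
    dose_cols: list[np.ndarray] = []
    n_dropped = 0
    for snp in retained:
        g_a1 = gmap.loc[snp, "a1"]
        s_a1 = st.loc[snp, "a1"]
        beta = float(st.loc[snp, "beta"])
        p = float(st.loc[snp, "p"])
        v = d[:, geno._col[snp]]
        g_a2 = gmap.loc[snp, "a2"] if "a2" in gmap.columns else None
        s_a2 = st.loc[snp, "a2"] if stats_has_a2 else None
        if g_a1 == s_a1 and (s_a2 is None or g_a2 is None or g_a2 == s_a2):
            dose = v
        elif g_a2 is not None and g_a2 == s_a1 and (s_a2 is None or s_a2 == g_a1):
            dose = 2.0 - v
        else:
            n_dropped += 1
            continue
        usable.append((snp, p, beta))
        dose_cols.append(dose)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} SNPs dropped: allele labels match neither orientation",
            stacklevel=2,
        )

    n = geno.n_subjects
    scores = pd.DataFrame(index=pd.Index(geno.subject_ids, name="subject_id"))
    n_used: dict[float, int] = {}
    kept_sets: dict[float, list[str]] = {}
    dmat = (
        np.column_stack(dose_cols) if dose_cols else np.zeros((n, 0))
    )
    pvals = np.array([p for _, p, _ in usable])
    betas = np.array([b for _, _, b in usable])
    names = [s for s, _, _ in usable]
    for tau in thresholds:
        mask = pvals < tau
        scores[f"prs_{tau:g}"] = dmat[:, mask] @ betas[mask] if mask.any() else 0.0
        n_used[tau] = int(mask.sum())
        kept_sets[tau] = [names[j] for j in np.where(mask)[0]]
    logger.info(
        "scored %d subjects at thresholds %s; SNPs used: %s",
        n, thresholds, n_used,
    )
    return PrsProfile(
        thresholds=thresholds,
        scores=scores,
        n_snps_used=n_used,
        retained_snps=kept_sets,
        n_dropped_alleles=n_dropped,
    )
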