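import numpy as np
import pandas as pd
import pytest

from dailysens.prs import GenotypeDosageMatrix


def make_geno(dosages, bp=None, chrom=None, a1="A", a2="G", snp_ids=None):
    """Small hand-built genotype matrix for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_ids = snp_ids or [f"rs{j}" for j in range(m)]
    bp = bp if bp is not None else [1000 + 100 * j for j in range(m)]
    chrom = chrom if chrom is not None else ["1"] * m
    a1 = [a1] * m if isinstance(a1, str) else list(a1)
    a2 = [a2] * m if isinstance(a2, str) else list(a2)
    snp_map = pd.DataFrame(
        {"chrom": chrom, "bp": bp, "a1": a1, "a2": a2},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeDosageMatrix(
        subject_ids=[f"P{i}" for i in range(n)],
        snp_ids=snp_ids,
        dosages=dosages,
        snp_map=snp_map,
    )


def simulate_lagged(
    n_subjects,
    n_pairs,
    b0=1.0,
    s0=-0.1,
    s1=0.15,
    c=4.0,
    sigma_u=0.2,
    sigma_e=0.4,
    e_dist="uniform",
    seed=0,
    covariates=0,
    cov_betas=(),
):
    """Directly simulate a lagged pair table under the crossover regime."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_subjects)
    u = rng.normal(0, sigma_u, n_subjects)
    rows = n_subjects * n_pairs
    subj = np.repeat(np.arange(n_subjects), n_pairs)
    if e_dist == "uniform":
        e = rng.uniform(1, 7, rows)
    else:
        e = np.clip(np.rint(1 + 6 * rng.beta(3.4, 1.3, rows)), 1, 7)
    y = b0 + u[subj] + (s0 + s1 * g[subj]) * (e - c) + rng.normal(0, sigma_e, rows)
    out = pd.DataFrame(
        {
            "subject_id": subj,
            "day": np.tile(np.arange(n_pairs) // 7 + 1, n_subjects),
            "E": e,
            "y": y,
            "G": g[subj],
        }
    )
    for j in range(covariates):
        x = rng.standard_normal(n_subjects)[subj]
        beta = cov_betas[j] if j < len(cov_betas) else 0.0
        out[f"PC{j + 1}"] = x
        out["y"] = out["y"] + beta * x
    out["GxE"] = out["G"] * out["E"]
    return out


@pytest.fixture
def lagged_fixture():
    return simulate_lagged(60, 20, seed=42)
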