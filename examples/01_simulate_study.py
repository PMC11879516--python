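"""Generate a complete synthetic study and write its interchange files.

Produces genotypes with block LD, GWAS-like summary statistics, and a week
of experience-sampling data in which the positive-context appraisal at one
beep drives paranoia at the next beep through a crossover-form G×E regime.
"""

from pathlib import Path

import numpy as np

from dailysens import SynthConfig, io, simulate_esm, simulate_genotypes, simulate_summary_stats

cfg = SynthConfig(seed=7, n_subjects=60, n_blocks=6, snps_per_block=8)
geno = simulate_genotypes(cfg)
stats = simulate_summary_stats(geno.snp_map, cfg)
esm, truth = simulate_esm(np.random.default_rng(1).standard_normal(60), cfg)

out = Path("scratch/example_study")
out.mkdir(parents=True, exist_ok=True)
io.write_genotypes_raw(geno, out / "genotypes.raw")
io.write_snp_map(geno.snp_map, out / "snps.map")
io.write_summary_stats(stats, out / "sumstats.tsv")
io.write_esm_csv(esm, out / "esm.csv")
io.write_true_params(truth, out / "true_params.json")

obs = esm[esm.observed]
completed = obs.groupby("subject_id").size()
print(f"subjects: {cfg.n_subjects}, SNPs: {geno.n_snps}")
print(f"issued beeps/subject: {cfg.n_days * cfg.signals_per_day}")
print(f"completed beeps/subject: mean {completed.mean():.1f}, SD {completed.std():.1f}")
print(f"stressful context mean: {obs.item_situation_stressful.mean():.2f} (floor-heavy)")
print(f"positive context mean:  {obs.item_situation_positive.mean():.2f} (ceiling-leaning)")
print(f"files written to {out}/")
# The two context means mirror the usual asymmetry of daily life: most
# moments are rated not at all stressful and fairly positive.
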