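"""Marker QC, population structure and LD decay.

Degrades a simulated panel with missing and heterozygous calls, runs the
MAF / missing / heterozygosity filters with mean imputation, then summarizes
population structure (PCA scree) and linkage disequilibrium decay over
genetic distance.
"""

from qgpanel import ld_decay_profile, pca, qc_filter, simulate_genotypes
from qgpanel.synth import SimConfig

geno = simulate_genotypes(
    SimConfig(n_lines=300, n_markers=2000, n_chromosomes=10, n_subpops=2,
              fst=0.05, het_rate=0.01, missing_rate=0.02, seed=21)
)
clean, report = qc_filter(geno, maf_min=0.05, max_missing=0.05, max_het=0.05)
print(f"QC: {report.surviving}/{report.n_input} markers retained "
      f"({report.removed_maf} failed MAF, {report.removed_missing} missing-rate, "
      f"{report.removed_het} heterozygosity); {report.imputed_calls} calls imputed")

res = pca(clean, k=10)
pct = res.explained_variance_ratio * 100
print(f"PCA: first two PCs explain {pct[0]:.1f}% + {pct[1]:.1f}% = "
      f"{pct[:2].sum():.1f}% of marker variance -> weak, continuous structure")

ld = ld_decay_profile(clean, max_distance_cM=30, bin_width_cM=5)
first, last = ld.bin_summary.iloc[0], ld.bin_summary.iloc[-1]
print(f"LD decay: median r2 {first['median_r2']:.3f} at {first['bin_mid_cM']:.1f} cM "
      f"-> {last['median_r2']:.3f} at {last['bin_mid_cM']:.1f} cM "
      f"({len(ld.pairs)} within-chromosome pairs)")
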