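"""Simulate a dioecious population and scan for sex-linked SNPs.

Builds a population with a 12-marker XY-type sex-determining region plus
clinally structured background SNPs, then runs the trend-test association
scan with and without principal-component correction.
"""

from dioecy import SimConfig, simulate_population, run_scan

cfg = SimConfig(n_individuals=126, n_background_snps=5000, n_sdr_snps=12,
                sdr_error_rate=0.0, recombinant_fraction=0.0, seed=1)
G, samples, truth = simulate_population(cfg)
print(f"{G.n_samples} samples x {G.n_snps} SNPs; "
      f"{(samples.sex == 'M').sum()} males, {(samples.sex == 'F').sum()} females")

for pca in (0, 2):
    res = run_scan(G, samples, test="trend", pca_correction=pca)
    sig = res[res.significant_bonferroni]
    top = res.head(12)
    print(f"\npca_correction={pca}: {res.attrs['n_tested']} SNPs tested, "
          f"Bonferroni threshold {res.attrs['bonferroni_threshold']:.3g}")
    print(f"  {len(sig)} significant; SDR markers in the top 12: "
          f"{top.id.str.startswith('sdr').sum()}/12")
    print(top[["chrom", "pos", "id", "maf", "stat", "p"]].head(5).to_string(
        index=False))

# The top hits are the simulated sex-determining-region markers: with full
# sex linkage the trend statistic reaches its ceiling (the sample size) and
# p-values sit far below the family-wise threshold, unchanged by the
# population-structure correction.
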