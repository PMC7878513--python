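"""Context-resolved gene-body methylation of a nurse methylome.

Simulates a transcriptome plus per-cytosine bisulfite calls with the CG
site availability of the bumblebee (23.14% of C sites), filters sites under
10x coverage, and reports: the context census, the context composition of
methylated cytosines, the CG-enrichment resampling test, a z-test of the
most highly expressed transcripts' mean mC against the transcriptome, and
Spearman coupling between methylation and expression per context.
"""

import numpy as np

from beecaste.methylation import (cg_enrichment_test, context_census,
                                  filter_coverage,
                                  methylation_context_composition,
                                  methylation_expression_correlation,
                                  subset_mean_ztest, transcript_mC)
from beecaste.synthetic import MethylomeSimParams, simulate_methylome

fasta, cgmap, truth = simulate_methylome(MethylomeSimParams(seed=4))
records = filter_coverage(cgmap, min_cov=10)

census = context_census(fasta)
print(f"context census ({census['n_defined']} C sites, both strands): "
      f"CG {census['CG']:.2%}  CW {census['CW']:.2%}  CC {census['CC']:.2%}")

comp = methylation_context_composition(records)
print(f"methylated-cytosine composition ({comp['n_methylated']} mC sites): "
      f"CG {comp['CG']:.1f}%  CW {comp['CW']:.1f}%  CC {comp['CC']:.1f}%")

enrich = cg_enrichment_test(records, census, reps=10_000, seed=5)
print(f"CG enrichment vs availability: observed CG share "
      f"{enrich['observed_cg_fraction']:.2%} vs expected "
      f"{enrich['expected_cg_fraction']:.2%}, p = {enrich['p_value']:.2g} "
      "(methylation concentrates in CG far beyond site availability)")

per_t = transcript_mC(records)
counts = truth["norm_count"].to_dict()
mean_mc = {sid: t.mean_mC for sid, t in per_t.items()}
print(f"transcriptome mean mC: {np.mean(list(mean_mc.values())):.2f}%")

top = sorted(mean_mc, key=lambda s: counts[s], reverse=True)[: len(mean_mc) // 10]
z = subset_mean_ztest([mean_mc[s] for s in top], list(mean_mc.values()))
print(f"top-decile expression subset: mean mC {z.subset_mean:.2f}% vs global "
      f"{z.global_mean:.2f}% ({z.percent_difference:+.1f}%), one-tailed "
      f"p = {z.p_value:.2g}")

corr = methylation_expression_correlation(per_t, counts)
print(f"Spearman methylation~expression: CG r_s = {corr['CG'].r_s:+.2f}, "
      f"CW r_s = {corr['CW'].r_s:+.2f} — expression tracks CG methylation, "
      "not CW, matching the planted coupling.")
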