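"""End-to-end method comparison on two synthetic marker panels.

Generates an FLP panel (binary presence/absence) and an SNP panel over
the same clones, harmonizes both into character matrices, and prints the
per-method summary: characters, ambiguity, error and genotype counts.
"""

from clonotyper import (
    SimulationConfig,
    render_summary_text,
    resolution_report,
    simulate_panel,
    summaries_to_frame,
)

flp_cfg = SimulationConfig(
    n_genotypes=7,
    clones_per_genotype=[5, 4, 4, 3, 3, 2, 2],
    n_characters=13,
    marker_type="FLP",
    divergence=0.5,
    heterozygosity=0.0,
    replicate_clones=["7498"],
    seed=1,
)
snp_cfg = SimulationConfig(seed=1, error_rate=0.0)  # 1292 chars, 29% ambiguity

summaries = []
for name, cfg in [("flp_panel", flp_cfg), ("snp_panel", snp_cfg)]:
    matrix, samples, truth = simulate_panel(cfg)
    summary = resolution_report(matrix, name=name)
    summaries.append(summary)
    print(render_summary_text(summary))
    print()

table = summaries_to_frame(summaries)
print(table[["method", "n_characters", "percent_ambiguous_display",
             "error_display", "n_genotypes_zero"]].to_string(index=False))
# the 13-character fragment panel resolves far fewer genotypes than the
# 1292-character SNP panel over the same 23 clones — resolution tracks
# the number of informative characters
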