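"""Assembly summary statistics and published worked-example arithmetic."""

from sexdepth import (
    SimulationConfig,
    fold_ratio,
    generate_genome,
    nx_stat,
    summarize_assembly,
)

genome = generate_genome(SimulationConfig(seed=11))
stats = summarize_assembly(genome.contigs, class_map=genome.truth)
print(stats.to_text())

n90, l90 = nx_stat([c.length for c in genome.contigs], 90)
print(f"N90 (bp)               {n90:,}   L90  {l90}")

# Worked examples on published pseudochromosome sizes and repeat contents:
# the predicted X (116.4 Mbp) vs Y (69.3 Mbp), DNA (34.7%) vs retro (19.3%)
# transposon contents, and the repeat-class sum.
print("\nX:Y size fold ratio        :", fold_ratio(116.4, 69.3, 1))
print("DNA:retro transposon ratio :", fold_ratio(34.7, 19.3, 1))
print("total repeat content (%)   :", round(19.3 + 34.7 + 3.3, 1))
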