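"""Generate a small synthetic genome with known X/Y contigs and depth tracks.

The generator encodes the sex-chromosome dosage asymmetry: females carry two
X copies and no Y, males one X and one Y, autosomes are diploid in both.
"""

from sexdepth import SimulationConfig, generate_genome, simulate_depth

cfg = SimulationConfig(
    n_autosomes=4,
    n_x_contigs=1,
    n_y_contigs=1,
    contig_length_range=(200_000, 400_000),
    gc_segment_length=20_000,
    window_size=20_000,
    mean_depth=30.0,
    noise="none",
    gc_bias_strength=0.0,
    seed=1,
)
genome = generate_genome(cfg)

print(f"{len(genome.contigs)} contigs, {genome.total_bp / 1e6:.2f} Mbp total")
print("bias curve:", cfg.describe()["gc_bias_formula"])
print(f"{'contig':<8} {'class':<9} {'male depth':>10} {'female depth':>12}")
male = dict((c, d) for c, s, _e, d in simulate_depth(genome, "male", cfg) if s == 0)
female = dict((c, d) for c, s, _e, d in simulate_depth(genome, "female", cfg) if s == 0)
for contig in genome.contigs:
    cls = genome.truth[contig.id]
    print(f"{contig.id:<8} {cls:<9} {male[contig.id]:>10.1f} {female[contig.id]:>12.1f}")

# Noise- and bias-free, depth is mean_depth * copies / 2 exactly: autosomes
# sit at 30x in both sexes, the X at 15x in males only, and the Y at 15x in
# males and 0x in females -- the signal the classifier reads.
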