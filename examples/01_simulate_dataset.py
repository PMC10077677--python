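"""Generate a small paired two-species dataset with planted ground truth.

Builds two synthetic genomes (zebrafish-like and mouse-like) with genes, an
orthology map, planted enhancers carrying AP-1/ETS motifs, and orthologous
enhancer copies, then writes the standard files (FASTA, GTF, BED, TSV) to
./sim_out and prints what was planted.
"""

from irekit.simulate import SimConfig, simulate_genome_pair

config = SimConfig(
    seed=1,
    n_chromosomes=2,
    chrom_length=400_000,
    n_genes=40,
    n_enhancers=60,
    tss_distance=(4_000, 30_000),
)
truth = simulate_genome_pair(config)
truth.write("sim_out")

for species in config.species:
    enh = truth.species_enhancers(species)
    ires = [e for e in enh if e.is_ire]
    print(f"{species}: {len(enh)} enhancers, {len(ires)} planted IREs")

zf_ires = truth.ires(config.species[0])
classes = {c: sum(e.cross_class == c for e in zf_ires)
           for c in ("shared", "species-specific", "unmapped")}
print("planted cross-species classes for", config.species[0], "IREs:", classes)
print("files written to sim_out/ (genomes, gene models, enhancer BEDs, truth)")
# "shared" IREs have a conserved orthologous copy in the other genome;
# "species-specific" copies had their AP-1/ETS motifs scrambled, modelling
# the motif-frequency loss seen in non-responsive orthologous sequences.
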