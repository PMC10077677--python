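# irekit

Tools for the comparative analysis of **injury-responsive enhancers
(IREs)** — distal *cis*-regulatory elements whose H3K27ac signal rises
after tissue injury, as studied in regenerating zebrafish and neonatal
mouse hearts. The package is aimed at regulatory genomicists who want the
full chain of that analysis as a tested, importable library:

1. **Differential enhancer calling** from replicated injured/control
   region counts. A region is an IRE when its fold change is ≥ 1.5 and its
   FDR < 0.05 (or p < 0.01, the zebrafish-style rule), using a conditional
   exact negative-binomial test with a method-of-moments common dispersion
   and Benjamini–Hochberg correction, followed by a ±2 kb promoter
   exclusion around TSSs.
2. **IUPAC degenerate motif statistics** for the AP-1 (`TKASTMA`) and ETS
   (`VVGGAWVY`) transcription-factor families, plus 21 per-factor codes:
   overlap-aware scanning on both strands, the per-kilobase motif
   frequency *f* = 1000·*c*/*s*, four-way motif-group classification,
   presence enrichment against a GC-matched background, and the relative
   overlapping ratio *r<sub>i</sub>* = *n<sub>i</sub>*/*n*₀ of motif-binned
   sequences against TF peaks.
3. **Cross-species orthologous-enhancer mapping**: for each IRE, the
   ±100 kb window around its associated gene's best ortholog is searched
   by affine-gap alignment (gap cost 10 + 0.5·L, match +5 / mismatch −4,
   the EMBOSS-Needle parameterization); the aligned core is the
   orthologous segment, and IREs are classified *shared* or
   *species-specific* by whether that segment is itself injury-responsive
   in the other species.
4. **Expression analyses**: TPM (column sums of 10⁶), a simplified
   DESeq-style differential test, enhancer–gene linking by nearest TSS or
   a 100 kb window, and the single-cell procedure that assigns each
   induced gene to the cell type with the largest injured-vs-uninjured
   change of its log1p(10⁴·count/total) expression.
5. **Reporter-assay arithmetic**: dual-luciferase activation fold change
   FC = (s<sub>i</sub>(H)/s<sub>i</sub>(N)) / (s<sub>c</sub>(H)/s<sub>c</sub>(N))
   and qPCR ΔΔCT relative expression.
6. A **synthetic-data generator** that builds paired two-species genomes
   with planted enhancers, motifs, orthologous copies (with controlled
   divergence and optional motif ablation), NB ChIP counts, bulk RNA
   counts, and single-cell matrices — with complete ground truth, so every
   stage is testable without downloading anything.

## Worked example

`examples/` holds one short script per capability. For instance,
calling IREs on a simulated dataset (`examples/02_call_ires.py`):

```bash
$ python examples/02_call_ires.py
estimated common NB dispersion: 0.084
called 17 IREs of 18 planted (94.4% sensitivity)
false calls: 0
call
non-IRE    43
IRE        17
```

The generator planted 18 enhancers with 3–6-fold injury responses among 60;
the differential test recovers 17 of them with no false calls, estimates
the simulated NB dispersion (0.1) from the replicates, and files the rest
as non-IREs (active in both conditions, no increase). Cross-species mapping
(`examples/04_cross_species_mapping.py`) prints:

```
mapped 20 zebrafish IREs into the mouse genome
mean alignment identity 89.3% (planted divergence 10%)
classes: {'shared': 13, 'species-specific': 7}
```

— copies planted at 10% per-base divergence are found at ~90% identity,
and the IREs whose motifs were ablated in the other genome come out
species-specific, exactly as planted.

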