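# protosex

Discovery toolkit for single-SNP sex-determining (SD) loci on
undifferentiated ("proto") sex chromosomes in XX/XY systems where
heterozygotes at one causal SNP are male, homozygotes female, and the X and
Y haplotypes recombine freely everywhere else.

The package implements the full discovery workflow as reusable, tested
components:

| module | what it does |
| --- | --- |
| `protosex.data_model` | genotype matrices, marker maps, intervals; TSV/VCF/FASTA I/O |
| `protosex.synthetic_data` | forward-time XY wild-population simulator, F1 family simulator (Haldane crossovers, sex-specific cM), X/Y clone-pair and multi-species panel generators |
| `protosex.linkage_mapping` | paternal X/Y phasing, recombinant screening between flanking markers, SD-interval refinement from recombinants + phenotypic sex |
| `protosex.variant_screening` | X/Y clone comparison, sequence identity, XY-pattern variant screen (het in every male, hom in every female), codon-level missense annotation |
| `protosex.association` | marker filters (MAF > 0.1, call rate > 0.99), exact 2x2 Fisher tests under a recessive penetrance collapse, recessive-model discordance, Bonferroni and max-T permutation corrections |
| `protosex.linkage_disequilibrium` | two-locus EM haplotype frequencies from unphased genotypes; D, D', r2, LOD; all-pairs LD matrices |
| `protosex.trans_species` | shared-polymorphism detection across species panels, per-species and pooled exact association, conservation verdicts |
| `protosex.pipeline` / `protosex.cli` | end-to-end orchestration with a run manifest and a `protosex` CLI |

The two-sided Fisher p-value uses the point-probability rule (sum over all
tables with fixed margins whose point probability does not exceed the
observed table's, relative tie tolerance 1e-7), computed in log space.
`protosex.fixtures` expands the published wild-panel genotype counts
(58 females / 47 males at two SNPs 141 bp apart) into a full matrix so the
published statistics can be recomputed from first principles.

## CLI

```bash
# simulate inputs
protosex simulate wild    --seed 1 --out wild.tsv
protosex simulate family  --n-offspring 400 --seed 1 --out fam.tsv
protosex simulate clones  --length 14000 --identity 0.994 --out clones.fasta
protosex simulate species --sizes 8:8,8:8,6:7 --out-dir panels/

# analyses
protosex assoc   --genotypes wild.tsv --model recessive --permutations 10000 --seed 1 --out assoc.tsv
protosex ld      --genotypes wild.tsv --out ld.tsv
protosex linkage screen  --genotypes fam.tsv --flank-left m1 --flank-right m8 --anchor m4 --out rec.tsv
protosex linkage refine  --genotypes fam.tsv --flank-left m1 --flank-right m8 --anchor m4 --out interval.json
protosex trans-species --panels panels/panel_species1.tsv --panels panels/panel_species2.tsv --out cons.tsv

# whole pipeline from one YAML config (see protosex.pipeline.DEFAULT_CONFIG)
protosex run --config cfg.yaml --seed 1 --out outdir/
```

All generators and analyses are deterministic given their integer seed;
re-running a pipeline with the same config produces byte-identical outputs,
and `manifest.json` records config hashes and per-output checksums.

## File formats

* **Genotype TSV** — optional `##marker=<id> <chrom> <pos_bp> <kind> <alleles>`
  metadata lines, then a header
  `#individual_id sex population role <marker_id>...` (tab-separated);
  sex is F/M/U, genotype cells are `A/B` (alleles sorted) or `./.`.
* **Marker map TSV** — `marker_id chrom pos_bp kind alleles cM_female cM_male`.
* **VCF v4.2** export for SNP genotypes (unphased GT only).
* Coordinates are 1-based from the 5' end of the named reference clone;
  intervals are closed (`length = end - start + 1`).
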