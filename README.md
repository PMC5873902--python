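# motifhotspot

Flanking-sequence motif hotspot analysis for gene mutation catalogues.

## The problem

Pathogenic point mutations in a disease gene often look randomly scattered:
no visible clustering at the nucleotide or protein-domain level.  Yet
site-specific mutation rates depend on local sequence context, and short DNA
motifs (CpG dinucleotides, homopolymer runs, splice-site cores) can mark
mutation-prone positions.  The motivating case is *STXBP1*, a synaptic gene
whose de novo mutations cause early-onset epileptic encephalopathies: its
catalogued mutations cluster near a `GTA` trinucleotide, and the
motif-proximal mutations are strongly enriched for splice-site annotation.

`motifhotspot` packages that analysis for any gene region:

1. **Catalogue** — parse, validate and deduplicate a mutation table (TSV or
   VCF), keeping both the full (per-report) and unique (per-DNA-change)
   totals.
2. **Context windows** — extract the ±f bp reference window around each
   mutation (default f = 5, an 11-bp window) after auditing catalogue ref
   alleles against the loaded FASTA.
3. **Motif scan** — for every k-mer m of length l (default l = 3, all
   4³ = 64 motifs), compute the observed statistic
   T(m) = #{windows containing ≥ 1 occurrence of m}, and compare it against
   N randomized draws (default N = 10,000) of the same number of mutation
   positions placed uniformly on the gene region.  The empirical p-value is
   the tail fraction p(m) = #{draws with T\* ≥ T(m)} / N, Bonferroni-corrected
   across the 64 motifs; a zero tail count is reported as `< 1/N`.
4. **Enrichment** — a 2×2 Fisher exact test of motif flag × splice-site
   annotation, with both the sample odds ratio ad/bc and a Haldane–Anscombe
   variant, plus sex and inheritance tabulations and an optional
   case-vs-control (e.g. ExAC rare-variant) comparison with a
   label-permutation p-value.
5. **Synthetic data** — a generator that plants motif copies in an i.i.d.
   background and samples mutation positions with weight (1+β) near planted
   copies, with an independently tunable motif→splicing label association
   (γ vs baseline p₀).  Everything above is testable against known ground
   truth with no downloads.

## Worked example

Simulate a study-scale dataset (136 catalogue rows collapsing to 92 unique
mutations on a 5,000 bp region with 12 planted `GTA` copies), run the
pipeline on the unique set, and print the report:

```sh
hotspot simulate --out fx --seed 7
# wrote 136 records (92 unique) and a 5000 bp reference with 12 planted 'GTA' copies to fx

cat > cfg.yaml <<EOF
catalog:   {path: fx/catalog.tsv}
reference: {path: fx/reference.fa}
perm:      {iterations: 10000, seed: 1}
output:    {dir: out}
EOF

hotspot run --config cfg.yaml --dedup
# analyzed 92 mutations (92 unique of 136); top motif GTA observed=27 p=< 0.0001 (corrected 0)

hotspot report --run out
# motifhotspot 0.1.0 run (seed 1)
#   catalogue: 136 records, 92 unique (92 SNV / 0 indel); analyzed unique set
#   top motifs:
#     GTA  observed=27   p=< 0.0001   corrected=0 *
#     TAC  observed=27   p=0.0013     corrected=0.0832
#     GGA  observed=18   p=0.0062     corrected=0.3968
#     GAA  observed=24   p=0.0066     corrected=0.4224
#     AGT  observed=19   p=0.0533     corrected=1
#   focal motif GTA: 27 flagged mutations; splicing 2x2 = [7,20;6,59], Fisher p = 0.05002, OR = 3.44
```

Reading the output: 27 of the 92 unique mutations carry `GTA` within ±5 bp;
none of the 10,000 uniform-null draws reached that count, so the empirical
p is below 1/10,000 and survives the 64-motif Bonferroni correction (the
planted motif is recovered).  `TAC` — the reverse complement of `GTA`, which
overlaps it in sequence — trails it, as expected.  The flagged mutations are
splicing-annotated at 7/27 versus 6/65 of the unflagged (OR ≈ 3.4), the
planted label association.  All outputs are also written as TSV
(`motif_scan.tsv`, `enrichment.tsv`, `sex_inheritance.tsv`) next to a JSON
manifest recording the config, seed and input digests.

The same pipeline runs on a real catalogue: a TSV with columns
`id contig position ref alt class annotation inheritance sex source`
(1-based positions, `.` for missing) or a VCF with `ANNOT`/`INH`/`SEX` INFO
keys, plus a FASTA slice of the gene region with its genomic `offset` given
in the config.

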