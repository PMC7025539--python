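# olivemap

Pseudo-testcross linkage mapping and diallelic self-incompatibility (DSI)
genotyping for olive crosses.

An F1 full-sib family of two heterozygous olive cultivars segregates for two
incompatibility groups, G1 (Ss) and G2 (ss), under a single dominant-S locus.
`olivemap` provides a tested, fully offline pipeline around that design:

- **simcross** — synthetic cross simulator: 23 chromosomes by default,
  sex-specific recombination (female map ~1.6x the male map), Poisson
  crossovers without interference, three pseudo-testcross marker segregation
  classes (maternal, paternal, fully informative ABxCD), a dominant Ss x ss
  incompatibility locus segregating 1:1, negative-binomial read depths,
  sequencing/genotyping error, and ~5% non-true-to-type offspring from open
  pollination. Full ground truth (haplotypes, crossovers, injected errors,
  contaminant flags) is retained for validation.
- **genocall** — read counts to genotype calls: minimum coverage 8, het call
  window 0.15–0.85 on the reference read fraction, loci retained when called
  in more than 150 progeny; marker segregation classification and
  Mendelian-exclusion parentage validation on multi-allelic markers.
- **linkmap** — per-parent maps: two-point r/LOD estimation, single-linkage
  grouping (LOD > 10, r <= 0.20), genetic-bin collapsing, MST-seeded
  ordering with 2-opt refinement, neighbour-consensus error smoothing,
  Kosambi distances (d = 25 ln[(1+2r)/(1-2r)] cM), chi-square segregation
  distortion scan, and anchor-based synteny comparison between the two
  parental maps (inversion / translocation candidates).
- **traitmap** — maps the binary G1/G2 phenotype as a Mendelian testcross
  pseudo-marker: 1:1 segregation test, zero-recombinant co-segregating bins,
  flanking-recombinant interval delimitation with per-border supporting
  individuals, and a text rendering of recombinant chromosomes.
- **stshap** — the 476-bp STS amplicon haplotype catalog (5 haplotypes over
  14 variant positions: 12 SNPs + 2 indels) and the G1/G2 classifier based
  on phase resolution against the catalog; positions 63 and 283 alone are
  diagnostic. Reads FASTA amplicons (consensus with IUPAC ambiguity codes,
  or cloned haplotype pairs) or diagnostic-genotype CSVs.
- **io / cli** — plain-text formats (TSV/CSV/JSON/FASTA) with provenance
  headers, YAML configuration, and the `olivemap` command-line interface.

## Command-line usage

```sh
olivemap simulate --config cross.yaml --out sim/ --seed 1
olivemap call --reads sim/read_counts.tsv --out calls.tsv
olivemap check-parents --genotypes sim/parentage_genotypes.csv \
    --mother m1=1/2 --father m1=3/4 --out parentage.csv
olivemap map --genotypes calls.tsv --parent mother --out map_mother.tsv
olivemap map-stats --parent female          # packaged reference statistics
olivemap compare-maps --map-a map_mother.tsv --map-b map_father.tsv --out syn.csv
olivemap trait-map --phenotypes sim/phenotypes.csv --genotypes calls.tsv \
    --out trait.json
olivemap classify --csv diagnostics.csv --out groups.csv
olivemap run-all --out demo/ --seed 1       # full pipeline end to end
```

A YAML config may override any block (`cross`, `calling`, `mapping`) plus
`seed`; unknown keys are rejected. All randomness flows from the single seed
and reruns are byte-identical.

## Notes

- The simulator draws crossovers without interference (Poisson); map
  distances use the Kosambi function, which assumes partial interference, so
  rebuilt map lengths under-shoot the simulated truth slightly. Tests
  account for this.
- The packaged per-chromosome map-statistics table reproduces its source as
  printed, including an internal inconsistency on the male side (the
  per-chromosome lengths sum to 100 cM more than the published total); both
  values are preserved and the published totals are used for summary
  statistics.
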