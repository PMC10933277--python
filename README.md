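# bloomclone

Population-genetic analysis of multiannual diatom bloom samples, built
around two complementary data streams:

- **Strain fingerprinting** — diploid microsatellite genotype tables from
  isolated strains: multilocus genotype (MLG) assignment, genotypic
  richness `R_MLG = (MLG−1)/(N−1)`, unbiased expected heterozygosity,
  MLG recurrence across years, a standardized index of association
  `I_A^S` with a Monte-Carlo locus-permutation test, and mating-type
  ratio statistics.
- **Pooled amplicon barcoding** — deep sequencing of microsatellite loci
  on whole environmental DNA: amplicon contingency tables, singleton and
  repeat-unit filters, homoplasy-aware allele naming (`114.1`, `114.2`,
  ...), median library normalisation, per-sample abundance thresholds,
  replicate merging, and 5′/3′ flank typing with recombinant detection.

Both streams feed a shared differentiation layer: pairwise F_ST
(Nei-style multilocus G_ST) matrices, classical PCoA, percolation-
threshold networks, and Evanno ΔK post-processing of external clustering
ln-likelihood tables. A forward simulator generates clonal vs. sexually
recombining populations (skewed clonal offspring distributions, MT+/MT−
mating, stepwise microsatellite mutation, PCR slippage and substitution
errors) so every stage is testable against known truth without any
downloads.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(oracle equivalence of the permutation test, type-I error calibration,
clonal/panmictic regime contrast, F_ST/PCoA/percolation/ΔK oracles, and
pooled-pipeline recovery bounds). Tests that reproduce the published
dataset numbers are skipped unless the original supplementary tables are
placed under `data/` (see below).

## CLI

```bash
bloomclone genotypes summarize --input genotypes.csv --out out/
bloomclone linkage ia --input genotypes.csv --iterations 1000 --seed 42 --out ia.csv
bloomclone mt ratio --input mt.csv --allele-a 230 --from 2013-08-20 --out ratio.csv
bloomclone popdiff fst|pcoa|network|evanno ...
bloomclone mpb --config loci.yaml --samples reads/ --out out/
bloomclone simulate population|reads|mixture --seed 42 --out sim/
bloomclone run-fingerprinting --input genotypes.csv --out report/
bloomclone run-mpb --config loci.yaml --samples reads/ --out report/
```

Genotype tables are CSV with `strain_id`, `date` (ISO-8601), optional
`mt`, then two columns per locus (`PNm1.a1`, `PNm1.a2`, ...); missing
genotypes are coded `0,0`. Pooled reads are accepted as dereplicated
FASTA (`;size=N` headers) or `sequence / sample / count` TSV. Locus
configuration (motif, minimum repeat units, abundance threshold %) is
YAML.

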