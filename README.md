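# allopipe

Directional amino-acid mismatch scoring for transplant donor/recipient
pairs, from VEP-annotated exome VCFs to candidate minor-histocompatibility
peptides.

The pipeline has two sequential stages plus a simulator:

1. **count** — clean genotypes with user-settable quality filters (FILTER
   status, depth, genotype quality, heterozygous allelic balance, gnomAD
   allele-frequency gate), join the two samples' sites, and count the
   directional amino-acid mismatches: the **AMS** (Allogenomics Mismatch
   Score). Direction `sot` counts amino acids present in the donor but
   absent from the recipient; `hct` the reverse. Missing genotypes are
   either masked (`stringent`, default) or imputed as homozygous reference
   (`impute`).
2. **affinity** — rebuild each mismatch-bearing protein from a transcript-
   keyed protein FASTA, enumerate every window of the requested lengths
   covering the mismatched residue, drop windows shared with the other
   sample, optionally filter by predicted proteasomal cleavage, score the
   remainder against HLA class I alleles through a pluggable predictor
   adapter (external NetMHCpan-4.1 / MixMHCpred wrappers, or a
   deterministic offline mock), and count the binders: the **af-AMS**.
3. **simulate** — toy proteome + Mendelian families (two parents, N
   siblings, Poisson crossovers, genotype error and missingness models)
   serialised as internally consistent VEP-style VCFs, with ground truth
   from an independent brute-force evaluator.

## CLI

```sh
# simulate a family of 2 siblings
allopipe simulate --seed 7 --n-sites 500 --n-children 2 --out sim/

# AMS for a pair (two single-sample VCFs, or a joint VCF)
allopipe count --donor sim/sib01.vcf --recipient sim/sib02.vcf \
    --direction sot --missing stringent --min-af 0 --out out/pair
allopipe count --joint sim/family.vcf --donor-sample sib01 \
    --recipient-sample sib02 --min-af 0 --out out/pair

# af-AMS from the AMS table
allopipe affinity --ams-table out/pair.ams_table.tsv \
    --proteins sim/proteome.fa --hla HLA-A*02:01,HLA-B*07:02 \
    --lengths 8,9,10,11 --predictor mock --rank-threshold 2.0 \
    --out out/aff
```

`count` writes `<prefix>.ams.txt`, `<prefix>.ams_table.tsv` and
`<prefix>.filter_report.tsv`; `affinity` writes
`<prefix>.af_ams_table.tsv`, `<prefix>.af_ams.txt` and a plain
`<prefix>.peptides.txt` list consumable as-is by any affinity prediction
tool. Every run directory gets a `manifest.json` echoing the fully
resolved configuration (precedence: CLI flag > `--config` YAML file >
built-in default). Restriction options: `--bed` (0-based half-open),
`--rsids`, `--transcripts` (one ID per line).

Default filters: PASS required, depth >= 10, GQ >= 20, het allelic balance
in [0.2, 0.8], minimum gnomAD exome AF 1% (`--min-af 0` disables the AF
gate; variants absent from gnomAD are kept unless `--drop-af-absent`).

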