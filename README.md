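# stepsig

Step-threshold expression normalization and composite gene-signature
scoring for two-arm transcriptomics cohorts.

The pipeline fits a one-step adaptive regression to each gene's sorted
log2(TPM+1) values (the step minimizing sum-of-square error defines a
per-gene expression threshold), recenters expression on that threshold in
units of three standard deviations, and sums the normalized values over a
signature gene list into a per-sample composite score. Scores order
samples, classify cohorts by ROC AUC (Mann-Whitney, ties at 0.5), and
feed Welch group comparisons. Supporting stages: TPM/log2 summarization
from counts, a two-arm differential-expression filter (Welch t on log
expression, raw P <= 0.05 and linear fold-change >= 2; BH-adjusted p
reported), hypergeometric gene-set enrichment against GMT collections,
multivariate OLS of a marker on clinical covariates, and Kaplan-Meier /
log-rank survival stratified by the signature metagene (median split of
mean signature expression). A synthetic-data module generates seeded
negative-binomial cohorts with planted upregulated genes, covariates, and
score-linked survival so every stage is testable by parameter recovery.

Note: the differential-expression stage is deliberately a light-weight
Welch-t stand-in for a negative-binomial GLM engine; it preserves the
downstream filter contract, not the exact engine. Technical replicates
should be collapsed (summed) per biological sample before DE.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (brute-force
oracle equivalence for the step fit, AUC and BH adjustments, normalization
identities, parameter-recovery and calibration simulations); the other
files are per-module unit and property tests.

## CLI

```sh
stepsig simulate  --out-dir cohort --seed 1            # synthetic cohort
stepsig threshold --matrix cohort/counts.tsv --counts \
                  --gene-lengths cohort/gene_lengths.tsv --out fits.tsv
stepsig deg       --matrix cohort/counts.tsv --counts \
                  --gene-lengths cohort/gene_lengths.tsv \
                  --metadata cohort/metadata.tsv --test-group case \
                  --out deg.tsv --signature-out sig.txt
stepsig score     --matrix cohort/counts.tsv --counts \
                  --gene-lengths cohort/gene_lengths.tsv \
                  --signature sig.txt --out scores.tsv
stepsig classify  --scores scores.tsv --metadata cohort/metadata.tsv \
                  --positive case --out classify.json
stepsig enrich    --hits sig.txt --universe universe.txt \
                  --gene-sets sets.gmt --out enrich.tsv
stepsig survival  --matrix cohort/counts.tsv --counts \
                  --gene-lengths cohort/gene_lengths.tsv \
                  --signature sig.txt --survival-table surv.tsv \
                  --out-prefix surv_out
stepsig run       --config pipeline.yaml --seed 1      # full pipeline
```

`stepsig run` reads a YAML `PipelineConfig` (paths, thresholds, optional
`synthetic:` block), executes deg -> threshold -> normalize -> score ->
classify (-> survival), and writes every output next to a `manifest.json`
(config hash, seed, versions) sufficient to regenerate it byte-for-byte.

Formats: TSV/CSV matrices (gene ids in the first column, sample ids in the
header), two-column gene-length TSV, plain-text signatures (one gene per
line, `#` comments), GMT gene sets, TSV survival tables
(`sample_id, time, event`).

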