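#!/bin/sh
# Generate a small simulated grid, then classify the samples from the
# shell. Every number is reproducible from the seed.
set -e

sigcat simulate --out-dir /tmp/sigcat-demo \
    --models sigmoidal --regimes equidistant --noise-types additive \
    --amplitudes 0.0,0.3 --replicates 2 --seed 11

# one CSV per sample plus a manifest with the true parameters
ls /tmp/sigcat-demo | head

# classify a single sample file: prints the category and the fitted
# parameters in both normalized and raw units
sigcat categorize /tmp/sigcat-demo/sigmoidal-equidistant-additive-a0.00-r000.csv \
    --seed 0 --n-starts 10

# run the benchmark over the whole grid and write summary tables
sigcat benchmark --manifest /tmp/sigcat-demo/manifest.csv \
    --out-records /tmp/sigcat-demo-records.csv \
    --out-aggregates /tmp/sigcat-demo-aggregates.csv \
    --seed 0 --n-starts 10
head -3 /tmp/sigcat-demo-aggregates.csv
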