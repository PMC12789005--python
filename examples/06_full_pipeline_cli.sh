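#!/usr/bin/env bash
# Full shell workflow: simulate a panel, fit both models, run a recovery.
# Writes everything under ./scratch/pipeline (safe to delete).
set -euo pipefail
out=scratch/pipeline
mkdir -p "$out"

# 1. a synthetic 23-country balanced panel (survey.csv, country_meta.csv, schema.yaml)
ordsurvey simulate --seed 1 --out "$out/data"

# 2. rural/urban group model + population-weighted country estimates
#    (one question, three countries, light sampler settings for a demo)
ordsurvey fit-group \
  --survey "$out/data/survey.csv" \
  --country-meta "$out/data/country_meta.csv" \
  --schema "$out/data/schema.yaml" \
  --question recovery --country ES --country SE --country SK \
  --chains 4 --iterations 3000 --burnin 1500 --seed 2 \
  --out "$out/group"

# 3. covariate model for the same question in Spain
ordsurvey fit-covariate \
  --survey "$out/data/survey.csv" \
  --schema "$out/data/schema.yaml" \
  --question recovery --country ES \
  --chains 4 --iterations 3000 --burnin 1500 --seed 3 \
  --out "$out/covariate"

# 4. a small parameter-recovery experiment on the built-in scenario
ordsurvey recover --replicates 3 --n 500 \
  --chains 4 --iterations 2000 --burnin 1000 --seed 4 \
  --out "$out/recovery"

echo "artifacts:"
find "$out" -name '*.csv' -o -name '*.json' | sort
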