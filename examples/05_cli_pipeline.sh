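#!/bin/sh
# Full pipeline from the shell: simulate a small study, then run every stage
# from a YAML config. All tables are written under out/.
set -e

mitopool simulate --n-species 6 --n-samples 4 --total-reads 200000 \
    --seed 3 --out out/study

cat > out/pipeline.yaml <<EOF
references: out/study/references.fasta
metadata: out/study/metadata.tsv
reads:
  sample01: out/study/reads_sample01.fastq
  sample02: out/study/reads_sample02.fastq
  sample03: out/study/reads_sample03.fastq
  sample04: out/study/reads_sample04.fastq
output_dir: out/run
truth_presence: out/study/truth_counts.tsv
truth_biomass: out/study/truth_biomass.tsv
n_permutations: 999
EOF

mitopool run --config out/pipeline.yaml
echo "--- confusion matrix ---"
cat out/run/confusion.tsv
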