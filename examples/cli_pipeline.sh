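#!/usr/bin/env bash
# The same screen from the shell: simulate a dataset, then run the full
# pipeline on its TSV artifacts.  Each subcommand reads/writes plain TSV,
# so real count tables drop in wherever the simulated ones appear.
set -euo pipefail
workdir=$(mktemp -d)

acscreen simulate --seed 3 --out "$workdir/sim"

acscreen screen \
    --counts "$workdir/sim_counts.tsv" \
    --lengths "$workdir/sim_lengths.tsv" \
    --totals "$workdir/sim_totals.tsv" \
    --group-a A1,A2 --group-b B1,B2 \
    --min-fold 2 --max-fdr 0.001 \
    --out "$workdir/report.tsv"

head -3 "$workdir/report.tsv"
echo "report: $workdir/report.tsv"
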