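"""Compare selection methods over replicated simulations (reduced scale).

Runs the full generate -> select -> score loop for the e-value procedure and
the two baselines and reports strict and block-relaxed detection rates.
Replications are kept small here so the script finishes in about a minute;
scripts/acceptance.py runs the 100-replication version.
"""

from snpevals import MethodSpec, SimConfig, benchmark

config = SimConfig(h=10.0)
REPS = 10

specs = {
    "e-value E2 (t=0.8)": MethodSpec(method="evalue-E2", t=0.8),
    "single-SNP + BH": MethodSpec(method="singlesnp-BH"),
    "mBIC2 (linear model)": MethodSpec(method="mbic2"),
}

print(f"h = {config.h}, m = {config.m} MZ families, {REPS} replications\n")
print(f"{'method':<22} {'TP':>6} {'TN':>6} {'RTP':>6} {'RTN':>6}")
for label, spec in specs.items():
    report = benchmark(config, spec, reps=REPS, seed=8)
    d = report.as_dict()
    print(
        f"{label:<22} {d['tp']:6.2f} {d['tn']:6.2f} {d['rtp']:6.2f} {d['rtn']:6.2f}"
    )

# TP: share of the 4 causal SNPs found; TN: share of the 46 null SNPs left
# alone; RTP/RTN relax these to the block level (any hit inside a causal
# block counts, misses in the null block count against RTN).
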