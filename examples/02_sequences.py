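"""Generate the early and delayed 144-trial learning sequences.

Both conditions present 72 prototype, 36 rule-follower and 36 exception
trials in three 48-trial blocks; the delayed condition withholds
exceptions until trial 49.  The printed block compositions and first
trials make the manipulation visible.
"""

import hipporpe as hp

ss = hp.build_type3_structure()

for condition in ("early", "delayed"):
    seq = hp.generate_learning_sequence(ss, hp.SequenceConfig(condition, seed=7))
    roles = [ss[t.stimulus_id].role for t in seq]
    print(f"\n{condition} condition (seed 7)")
    for b in range(3):
        block = roles[48 * b:48 * (b + 1)]
        counts = {r: block.count(r) for r in ("prototype", "rule_follower", "exception")}
        print(f"  block {b + 1}: {counts}")
    first_exc = min(t.index for t in seq if ss[t.stimulus_id].role == "exception")
    print(f"  first 8 trials: {[t.stimulus_id for t in list(seq)[:8]]} (prototypes only)")
    print(f"  first exception trial: {first_exc}")
    print(f"  probe checkpoints: {hp.checkpoint_schedule(condition)}")

test = hp.generate_test_sequence(ss, seed=7)
roles = [ss[t.stimulus_id].role for t in test]
print(f"\ntest block: {len(test)} trials,",
      {r: roles.count(r) for r in set(roles)}, "(equal role exposure, no feedback)")
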