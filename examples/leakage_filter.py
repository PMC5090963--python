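"""Purge validation drugs structurally too close to the training set.

Builds toy binary fingerprints and removes every validation drug with a
Tanimoto similarity strictly above 0.7 to any training drug.
"""

from cpirank import FingerprintSet, filter_leakage, tanimoto

fps = FingerprintSet(
    bit_length=100,
    bits={
        "train_A": frozenset(range(100)),
        "valid_near": frozenset(range(71)),   # 71 shared bits of 100 -> 0.71
        "valid_edge": frozenset(range(70)),   # exactly 0.70 -> retained
        "valid_far": frozenset(range(60, 80)),
    },
)

print("similarity valid_near vs train_A:", tanimoto(fps["valid_near"], fps["train_A"]))
kept, removed = filter_leakage(
    ["valid_near", "valid_edge", "valid_far"], ["train_A"], fps, cutoff=0.7
)
print("retained:", kept)
for r in removed:
    print(f"removed {r.drug_id}: max similarity {r.max_similarity:.2f} "
          f"to {r.nearest_training_drug}")

# The rule is strict (> 0.7): a drug exactly at the cutoff stays, so reported
# validation performance is not inflated by structural near-duplicates.
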