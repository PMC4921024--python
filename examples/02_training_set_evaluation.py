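"""Score a call set against curated training sets.

Rebuilds the curated-evaluation arithmetic: a 121-gene confirmed set with
98 genes captured, a 131-gene set with 126 captured, and the combined
false-negative rate over all 252 confirmed fusions.
"""

from domfuse import TrainingEntry, TrainingStatus, evaluate, percent
from domfuse.caller import FusionCall, Stage


def confirmed(n, prefix):
    return [TrainingEntry(f"{prefix}{i}", TrainingStatus.confirmed_fusion) for i in range(n)]


def final(ids):
    return [FusionCall(g, "G1", Stage.final_fusion) for g in ids]


ecoli = confirmed(121, "e")
bvit = confirmed(131, "b")
calls_e = final(f"e{i}" for i in range(98))
calls_b = final(f"b{i}" for i in range(126))

s = evaluate(calls_e, ecoli)
print(f"single-genome set: {s.n_captured}/{s.n_truth} captured "
      f"= {percent(s.capture_fraction)}%")
s = evaluate(calls_b, bvit)
print(f"pathway set:       {s.n_captured}/{s.n_truth} captured "
      f"= {percent(s.capture_fraction)}%")
s = evaluate(calls_e + calls_b, ecoli + bvit)
print(f"combined FN rate:  {s.n_truth - s.n_captured}/{s.n_truth} "
      f"= {percent(s.fn_rate)}%")
# Capture is the fraction of curated fusions the detector finds; the
# false-negative rate is its complement over the pooled truth sets.
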