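"""Biomarker selection and sensitivity analysis on a synthetic cohort.

Generates a cohort with two planted biomarkers (x1, x2) driving all three
endpoint types, then runs PRCC, forward/backward stepwise selection with
likelihood-ratio tests, resampling robustness, a median-split subgroup
summary and the responder-vs-nonresponder rank test.
"""
import numpy as np

from spatialqsp.biomarkers import (
    backward_select,
    forward_select,
    resample_selection,
    responder_vs_nonresponder_test,
    subgroup_summary,
)
from spatialqsp.io import fixture_cohort
from spatialqsp.trial import prcc

table = fixture_cohort(n=400, n_decoys=6, effects={"x1": 2.0, "x2": -1.0}, seed=7)
candidates = [c for c in table.columns
              if c not in ("diameter", "responder", "ttp", "ttp_event")]

res = prcc(table[candidates].to_numpy(), table["diameter"].to_numpy())
res.insert(0, "biomarker", candidates)
print("PRCC vs continuous endpoint (|r| > 0.3 shown):")
print(res[res.prcc.abs() > 0.3].to_string(index=False))

for family, endpoint in (("linear", "diameter"), ("logistic", "responder"), ("cox", "ttp")):
    fwd, _ = forward_select(table, endpoint, candidates, family)
    bwd, _ = backward_select(table, endpoint, candidates, family)
    print(f"\n{family:>8} endpoint {endpoint!r}: forward {fwd}  backward {bwd}")

freq = resample_selection(table, "diameter", candidates, "linear", n_rep=50, seed=0)
print("\nselection frequency over 50 resamples (%):")
print(freq[freq > 0].to_string())

print("\nmedian-split ORR with Wilson 95% CI for x1:")
print(subgroup_summary(table, "x1", "responder", "logistic").to_string(index=False))

p = responder_vs_nonresponder_test(table, "x1")
print(f"\nMann-Whitney responder vs non-responder on x1: p = {p:.2e}")
print("Planted biomarkers are recovered by every route; decoys appear")
print("only sporadically in resamples.")
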