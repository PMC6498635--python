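"""Immune memory: a repeated infection is eliminated much faster.

Runs a small batch of the repeated-infection experiment (same pathogen at
days 300 and 315) and compares the two elimination times.  Memory B cells
formed during the first response re-activate on antigen contact without the
critical waiting period, so the second response skips the slow polyclonal
phase.
"""

from humoralsim import run_memory_experiment

res = run_memory_experiment(reps=10, seed=4)

print(f"runs clearing both infections: {res['cleared_both']}/{res['reps']}")
print(f"first  infection: mean elimination {res['mean1']:.1f} steps "
      f"(sd {res['sd1']:.1f})")
print(f"second infection: mean elimination {res['mean2']:.1f} steps "
      f"(sd {res['sd2']:.1f})")
print(f"Welch two-tailed p for equal means: {res['p_value']:.2e}")
print()
print("Reading: the second mean is several-fold smaller — the hallmark of")
print("immune memory; at larger replicate counts the p-value is astronomically")
print("small (the reference experiment used 500 runs).")
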