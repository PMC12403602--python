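"""Attention-based detectors and their threshold sweeps.

Builds an attention corpus where related entity pairs share a planted
"trigger token" peak in their attention rows, then sweeps ConEx (KL of
the localized context distribution against uniform) over its standard
threshold grid.  Recall can only fall as the threshold rises.
"""

from minsupre import AttnGenConfig, SweepSpec, gen_attention_corpus, threshold_sweep

records = gen_attention_corpus(
    AttnGenConfig(n=1000, kappa=0.06, background_conc=100, length_range=(8, 24), seed=1)
)
report = threshold_sweep(records, SweepSpec("conex"))

print("ConEx sweep on a weakly planted-peak corpus (kappa = 0.06):")
print(report.to_frame()[["threshold", "precision", "recall", "f1"]].to_string(index=False))
print()
print("Each row thresholds KL(L || uniform).  Near-uniform attention rows of")
print("unrelated pairs never reach the band, so precision holds at 1; recall")
print("decays as the threshold rises past the weakly peaked (long) sentences.")
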