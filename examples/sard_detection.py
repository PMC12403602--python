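"""Dependency-path relation detection on a synthetic parse corpus.

Generates sentences whose dependency trees plant (or omit) the syntactic
signals the detector reads — a verb or the root on the shortest
dependency path between the entities, a direct link, a conjunction — and
scores all six (assumption, heuristic) settings against the gold labels.
"""

from minsupre import ParseGenConfig, SardConfig, evaluate_predictions, gen_parse_corpus
from minsupre.experiments import sard_labels

records = gen_parse_corpus(ParseGenConfig(n=2000, pi_plus=0.5, seed=0))
gold = [r.instance.gold_label for r in records]

print("assumption  heuristic  precision  recall   F1")
for a_id in (1, 2, 3):
    for h_id in (1, 2):
        pred = sard_labels(records, SardConfig(a_id, h_id))
        m = evaluate_predictions(pred.tolist(), gold)
        print(f"    {a_id}          {h_id}       {m.precision:.3f}    {m.recall:.3f}   {m.f1:.3f}")

print()
print("Assumption 3 (any verb on the path) trades precision for recall —")
print("it fires on the most sentences; heuristic 2 (no conjunction on the")
print("path) prunes coordinated clauses and recovers precision.")
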