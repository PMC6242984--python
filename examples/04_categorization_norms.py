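"""The shipped categorization norms: hits, RTs and modal confusions.

Loads the packaged by-items confusion/RT norms for the six dynamic
expressions and reports each expression's hit rate, correct-response
RT, and most frequent confusion.
"""

import facegaze as fg

matrix, conf, rts = fg.load_categorization_norms()
by_rt = rts.set_index("expression")["rt_mean_ms"]
printed_hits = conf[conf["stimulus"] == conf["response"]] \
    .set_index("stimulus")["mean_pct"]

print(f"{'expression':<10} {'hit %':>6} {'RT ms':>6}  modal confusion")
for e in fg.EXPRESSIONS:
    labels, p = fg.modal_confusion(matrix, e)
    modal = f"{labels[0]} ({p * 100:.1f}%)" if labels else "-"
    print(f"{e:<10} {printed_hits[e]:>6.1f} {by_rt[e]:>6.0f}  {modal}")

print("\nHappiness is recognised best and fastest; fear worst and")
print("slowest, confused mainly with surprise — the classic asymmetry")
print("of basic-expression categorization.")
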