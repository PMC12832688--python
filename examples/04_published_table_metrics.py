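"""Recompute the full evaluation-metrics table from a confusion matrix.

Feeds the published test-set confusion matrix (pneumonia positive:
TP=372, FN=18, FP=39, TN=195) through the report calculator and prints
every derived score, plus a McNemar example for paired model comparison.
"""

from pneunet.evaluation import ConfusionMatrix, mcnemar, report

cm = ConfusionMatrix(tp=372, fn=18, fp=39, tn=195)
r = report(cm).rounded()
print(f"n = {cm.total} (pneumonia support {cm.support_pneumonia}, "
      f"normal support {cm.support_normal})")
print(f"accuracy: {r['accuracy']}")
for cls in ("pneumonia", "normal"):
    s = r[cls]
    print(f"{cls:>9}: precision {s['precision']}  recall {s['recall']}  "
          f"f1 {s['f1']}  support {s['support']}")
print(f"    macro: precision {r['macro'][0]}  recall {r['macro'][1]}  f1 {r['macro'][2]}")
print(f" weighted: precision {r['weighted'][0]}  recall {r['weighted'][1]}  "
      f"f1 {r['weighted'][2]}")

res = mcnemar(15, 5, corrected=True)
print(f"\nMcNemar example (b=15, c=5, corrected): chi2={res.chi2:.2f} "
      f"p={res.p:.4f} significant={res.significant}")
print("b and c are the discordant pairs: cases one model gets right and the"
      " other wrong; the test asks whether that asymmetry exceeds chance.")
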