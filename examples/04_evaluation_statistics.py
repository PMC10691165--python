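"""Ranking-agreement (DCG) and top-tranche enrichment statistics.

DCG sums |predicted rank - experimental rank| discounted by log2(i + 1) at
each predicted position, so disagreement near the top costs most; lower is
better and 0 means identical rankings.  The enrichment p-value is the
hypergeometric upper tail for observing k externally validated combinations
inside the top 10% of N predictions.
"""

import combosc as csc
from combosc.evaluation import EnrichmentQuery

# five drug combinations ranked by prediction and by experiment
predicted = [1, 2, 3, 4, 5]
experimental = [2, 1, 3, 5, 4]
print(f"DCG(predicted vs experimental) = "
      f"{csc.dcg(predicted, experimental):.3f}")
print(f"DCG(identical rankings)        = "
      f"{csc.dcg(predicted, predicted):.3f}")
print(f"DCG(reversed rankings)         = "
      f"{csc.dcg(predicted, predicted[::-1]):.3f}")

# 1000 predictions, 60 registered in trials, 14 land in the top 100
q = EnrichmentQuery(N=1000, n=60, k=14)
print(f"\nEnrichment: {q.k} of {q.n} registered combinations in the top "
      f"{q.M} of {q.N} predictions -> p = {csc.enrichment_p(q):.2e}")
print("(p < 0.05 indicates the top predictions are enriched for "
      "clinically registered combinations)")
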