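"""Optimal-scaling PCA of the risk matrix and the similarity network.

The signed dummy matrix is treated as categorical variables and reduced by
princals-style alternating least squares; the components covering 80% of
the variance define each respondent's coordinate vector, and pairs with
cosine similarity above 0.5 become edges of the respondent network.
"""

import numpy as np

import perceptrisk as pr
from perceptrisk.catpca import ScalingSpec

survey = pr.generate(pr.GeneratorConfig(n=600, seed=3))
matrix = pr.encode_risk_matrix(survey.responses)

dummies = matrix.to_dataframe()
dummies = dummies[[c for c in dummies.columns if dummies[c].nunique() > 1]]
dummies.columns = [f"{it}:{cat}" for it, cat in dummies.columns]

model = pr.fit_princals(dummies, ScalingSpec("ordinal", ndim=100, seed=0))
reduced = pr.select_components(model, variance_threshold=0.80)
print(f"{dummies.shape[1]} informative dummy variables -> "
      f"{reduced.shape[1]} components at the 80% variance cutoff")
print("leading VAF shares:", np.round(model.vaf[:5], 3))

graph = pr.build_graph(reduced, cutoff=0.5,
                       node_ids=list(survey.responses.respondent_ids))
degrees = [d for _, d in graph.degree()]
print(f"network: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} edges, mean degree {np.mean(degrees):.1f}")
# Edges join respondents whose component-score vectors point in nearly the
# same direction, i.e. whose answer patterns are alike.
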