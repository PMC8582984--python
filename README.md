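# perceptrisk

Modelling the **heterogeneity of risk perception** from categorical survey
data. The package implements a socio-mathematical pipeline for pandemic
risk-perception surveys: answers are coded against protective knowledge and
behaviour, summed into a risk score, reduced by optimal-scaling categorical
PCA, connected into a cosine-similarity respondent network, embedded with a
force-directed layout and clustered by density — exposing a homogeneous
high-risk-perception group alongside several distinct low-risk-perception
subgroups. A synthetic survey generator with ground truth makes every stage
testable without access to restricted survey data.

It is written for epidemiologists and computational social scientists who
analyse categorical risk-perception instruments and want the whole chain —
from codebook to cluster profiles — reproducible from one seed.

## The model

**Risk vector and score.** A codebook maps every response category of every
item to a sign: +1 if the answer is consistent with expected protective
knowledge/behaviour, −1 if inconsistent, 0 if neutral. Respondent *i*'s
answers become a signed dummy vector *r*ᵢ ∈ {−1, 0, +1}ᵐ (one column per
item-category; at most one nonzero per item block; missing answers leave a
zero block), and the risk score is the plain sum

&nbsp;&nbsp;&nbsp;&nbsp;*s*ᵢ = Σₖ *r*ᵢₖ ∈ [−m, m].

Respondents are grouped into quartiles QR1–QR4 of the empirical score
distribution (ties never straddle groups, so group sizes are similar, not
equal).

**Optimal-scaling PCA (princals).** The dummy matrix is treated as *m*
categorical variables. Alternating least squares minimises the Gifi loss

&nbsp;&nbsp;&nbsp;&nbsp;σ(X, z, a) = (1/m) Σⱼ ‖X − Gⱼ zⱼ aⱼ′‖²,&nbsp;&nbsp;X′X = nI,

over object scores X, category quantifications zⱼ (free, monotone or linear
according to the scaling level) and loadings aⱼ. With numeric scaling this
is exactly classical PCA on the standardised data — the module's built-in
oracle. Components are kept up to a cumulative variance-accounted-for
threshold (default 80%).

**Network, layout, clusters.** Respondents whose component-score vectors
have cosine similarity strictly above 0.5 are connected. The graph is
embedded in 2-D by ForceAtlas2-style forces — linear edge attraction *d*,
degree-weighted repulsion *k*ᵣ(deg+1)(deg+1)/*d*, classic gravity, adaptive
speed — and DBSCAN on the layout yields clusters that are profiled against
the population (gender, age bands, quartiles, nine emotion flags, six media
flags, with deltas).

## Worked example

```python
import numpy as np
import perceptrisk as pr

survey = pr.generate(pr.GeneratorConfig(n=1000, seed=7))
matrix = pr.encode_risk_matrix(survey.responses)
scores = pr.risk_score(matrix)
bimod  = pr.detect_bimodality(scores)
print(scores.min(), scores.max(), bimod.is_bimodal,
      np.round(bimod.component_means, 1))
```

prints

```
-33 40 True [-16.   34.7]
```

— 1000 synthetic respondents answered 40 items (166 signed dummy columns);
scores span −33…40 and the distribution is flagged bimodal with a
low-perception mode near −16 and a high-perception mode near 35. Running
the full chain,

```bash
python examples/05_full_pipeline_recovery.py
```

executes encode → score → reduce → network → layout → cluster → profile at
n = 2000 and reports recovery of the generator's ground truth, e.g.

```
"theta_score_correlation": 0.978      # score tracks the latent trait
"qr4_largest_cluster_share": 0.86     # high-risk quartile is homogeneous
"qr1_major_clusters": 3               # low-risk quartile splits into
"qr1_normalized_entropy": 0.94        #   several archetypal clusters
```

The `examples/` directory has one short script per capability; the
`perceptrisk` command exposes the same stages for shell use
(`perceptrisk run --n 2000 --seed 0 out/`).

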