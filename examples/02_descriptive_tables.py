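"""Quartile-by-gender contingency analysis and emotion frequency profiles.

Reproduces the shape of the survey's descriptive tables: a quartile x
gender count table with margins and percent-of-total, a chi-square test of
independence, and per-quartile emotion prevalences (which the generator
makes monotone in the latent trait, mirroring the reported gradients).
"""

import pandas as pd

import perceptrisk as pr

survey = pr.generate(pr.GeneratorConfig(n=2000, seed=0))
scores = pr.risk_score(pr.encode_risk_matrix(survey.responses))
quartiles = pr.assign_quartiles(scores)

table = pr.contingency_table(survey.responses.data["gender"], quartiles,
                             "gender", "quartile")
print(table.formatted().to_string())
chi = pr.chi_square_test(table.counts)
print(f"chi-square = {chi['statistic']:.1f}, df = {chi['df']}, "
      f"p = {chi['p_value']:.2e}")

profile = pr.frequency_profile(pd.DataFrame({"quartile": quartiles}),
                               survey.responses.flags("emotion"))
wide = profile.pivot_table(index="flag", columns="quartile", values="percent")
print(wide.round(1).to_string())
# Rows are emotions, columns quartiles (1 = lowest perceived risk); values
# are the percentage of each quartile reporting the emotion.
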