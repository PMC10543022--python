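"""Pathway over-representation of an association hit set.

Tests hits against the classified-metabolite universe with two-sided Fisher
exact tests, separately per pathway level and per effect direction.
"""

from mwaskit import association as assoc
from mwaskit import enrichment, qc, simulate

matrix, phen, ann, truth = simulate.simulate_cohort(simulate.CohortSimConfig(seed=1))
processed, _ = qc.run_qc_pipeline(matrix, qc.QcConfig(seed=1))
status = assoc.mwas(processed, phen, assoc.ModelSpec())
cur = status[status["contrast"] == assoc.CONTRAST_CURRENT]
hits = cur.loc[cur["qvalue"] < 0.05, "metabolite_id"].tolist()
betas = cur.set_index("metabolite_id")["beta"]

for direction in ("all", "down", "up"):
    table = enrichment.fisher_enrichment(hits, ann, direction=direction, betas=betas)
    top = table.head(3)[["pathway", "level", "a", "odds_ratio", "pvalue", "qvalue"]]
    print(f"\n{direction}-regulated hit set, top pathways:")
    print(top.to_string(index=False))
# 'a' is the overlap count between the hit set and the pathway inside the
# classified universe; small p with OR > 1 marks over-representation.
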