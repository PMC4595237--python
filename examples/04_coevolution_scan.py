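"""Gene-gene co-evolution from quartile rate categories.

Two gene pairs are simulated: one perfectly coupled (rho = 1), one
independent.  Matching A/C/N categories beyond the 6/16 null marks
co-evolving pairs after Bonferroni correction.
"""

from opsinevol import (categorize_omegas, coevolution_matrix,
                       simulate_omega_table)

species = [f"sp{i:02d}" for i in range(48)]
table, truth = simulate_omega_table(
    ["OPN_a", "COL_a", "OPN_b", "COL_b"], species,
    rho={("OPN_a", "COL_a"): 1.0, ("OPN_b", "COL_b"): 0.0}, seed=7)

cats = categorize_omegas(table)
opsins = type(cats)(cats.data.loc[["OPN_a", "OPN_b"]],
                    cats.thresholds.loc[["OPN_a", "OPN_b"]])
colors = type(cats)(cats.data.loc[["COL_a", "COL_b"]],
                    cats.thresholds.loc[["COL_a", "COL_b"]])

results = coevolution_matrix(opsins, colors, min_n=15)
print(f"{len(results)} pairwise tests, Bonferroni threshold "
      f"{0.05 / results[0].m:.2e}")
for r in sorted(results, key=lambda r: r.p_value):
    mark = "**" if r.significant else ("*" if r.strong else "")
    print(f"  {r.gene_a} ~ {r.gene_b}: k/n = {r.k}/{r.n} "
          f"({r.proportion:.2f} vs null 0.375), p = {r.p_value:.2e} {mark}")
# The coupled pair matches in nearly every lineage and survives the
# correction; independent pairs hover near the 0.375 null.
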