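"""Lineage outlier map and pseudogene screening.

Three lineages are displaced in the gene x lineage omega matrix (as the
penguins and the barn owl stand out in the real opsin family); robust
PCA flags them.  A premature stop planted at codon 168 (the barn-owl RH2
lesion) is then recovered by the pseudogene screen.
"""

import numpy as np
import pandas as pd

from opsinevol import (inject_pseudogene, pseudogene_screen,
                       robust_pca_outliers, simulate_codon_alignment,
                       simulate_tree)

rng = np.random.default_rng(9)
X = pd.DataFrame(rng.normal(0.15, 0.03, size=(48, 6)).clip(0.01),
                 index=[f"sp{i:02d}" for i in range(48)],
                 columns=["RH1", "RH2", "SWS1", "PIN", "RGR", "OPN4x"])
for sp in ("sp05", "sp06", "sp30"):  # e.g. two penguins and an owl
    X.loc[sp] += 0.25

result = robust_pca_outliers(X, k=2)
print(f"retained components k = {result.k}; "
      f"SD cutoff {result.sd_cutoff:.2f}, OD cutoff {result.od_cutoff:.2f}")
print(f"flagged lineage outliers: {result.outliers}")

tree = simulate_tree(6, seed=9, tree_height=0.2)
aln = simulate_codon_alignment(tree, omega=0.2, kappa=4, gc=0.5,
                               length=400, seed=9)
broken, _ = inject_pseudogene(aln, aln.taxa[0], stop_codon_positions=[168],
                              deletions=[(3 * 294 + 1, 12)])
report = pseudogene_screen(broken, aln.taxa[0], reference_taxon=aln.taxa[1])
stop = report.internal_stops[0]
indel = report.inframe_indels[0]
print(f"\npseudogene screen of {report.taxon}:")
print(f"  internal stop {stop.codon} at codon {stop.codon_index} "
      f"(reference position {stop.ref_position})")
print(f"  in-frame deletion of {indel.length} nt from reference "
      f"position {indel.ref_start} ({indel.length // 3} residues)")
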