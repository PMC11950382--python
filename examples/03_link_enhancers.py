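"""Peak-to-gene linkage and the enhancer-vs-promoter contrast.

Simulated cells have uniformly open promoters but enhancers open mainly
in the gene's own germ layer, with expression driven by enhancer
accessibility.  Background-matched linkage recovers the planted
enhancers, and per-cell Spearman correlation between expression and
accessibility is far higher at linked enhancers than at promoters.
"""

import numpy as np

from zgakit.linkage import (
    build_cre_map,
    compare_correlations,
    link_peaks,
    per_cell_correlation,
)
from zgakit.multiome import normalize_rna, tfidf
from zgakit.simulate import SyntheticConfig, simulate_multiome

cfg = SyntheticConfig(n_cell_types=4, cells_per_type=250, n_genes=100,
                      enhancer_effect=2.0, seed=11)
rna, atac, cells, genes, peaks, truth = simulate_multiome(cfg)
norm, acc = normalize_rna(rna), tfidf(atac)

links = link_peaks(norm, acc, genes, peaks, window=20_000, n_background=200)
sig = links[links["p"] < 0.05]
planted = set(truth.enhancer_of.items())
called = set(zip(sig["gene"], sig["peak"]))
tp = len(planted & called)
print(f"candidate links: {len(links)}, significant (p<0.05): {len(sig)}")
print(f"planted enhancer recovery: recall {tp / len(planted):.2f}, "
      f"precision {tp / len(called):.2f}")

cre = build_cre_map(acc, genes, peaks, links)
hvgs = [g.gene_id for g in genes]
rho_p = per_cell_correlation(norm, acc, cre, hvgs, "promoter")
rho_e = per_cell_correlation(norm, acc, cre, hvgs, "enhancer")
u, p = compare_correlations(rho_p, rho_e)
print(f"median per-cell Spearman rho: promoter {np.nanmedian(rho_p):.3f}, "
      f"enhancer {np.nanmedian(rho_e):.3f}  (Mann-Whitney p = {p:.3g})")
print()
print("Promoter accessibility is uninformative about expression (rho ~ 0)")
print("while enhancer accessibility tracks it - accessibility at distal")
print("elements, not promoters, encodes germ-layer identity.")
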