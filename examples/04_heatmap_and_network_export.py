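"""Cluster pathway scores into a heatmap and export one annotated network.

Scores a small synthetic bundle, writes a bi-dimensionally clustered heatmap
(plus its reordered text twin) and a DOT graph of the planted pathway for
one sample, in which molecule fill encodes expression probability, circle
size encodes interaction activity and edge colour encodes consistency.
Outputs land in ./scratch_example/.
"""

from pathlib import Path

import pandas as pd

from pathscore import (
    SyntheticSpec,
    bicluster,
    export_heatmap,
    export_network,
    gene_probability_table,
    generate_bundle,
    molecule_probability,
    score_interactions,
    score_pathways,
    updown_normalize,
)

outdir = Path("scratch_example")
outdir.mkdir(exist_ok=True)

bundle = generate_bundle(SyntheticSpec(seed=3, n_samples=20, n_pathways=8))
up, _ = updown_normalize(bundle.expression)
scored = score_pathways(up, bundle.networks, bundle.mapping)

both = pd.concat([
    scored.activity.rename(index=lambda i: f"activity:{i}"),
    scored.consistency.rename(index=lambda i: f"consistency:{i}"),
])
cluster = bicluster(both)
text_path = export_heatmap(both, cluster, outdir / "heatmap.png")
print(f"heatmap image: {outdir / 'heatmap.png'}")
ordered = pd.read_csv(text_path, sep="\t", index_col=0)
print(f"clustered matrix (rows x cols): {ordered.shape}")

net = bundle.networks[0]
sample = bundle.expression.sample_ids[0]
gene_probs = gene_probability_table(up, bundle.mapping)[sample].to_dict()
mol_probs = {m: molecule_probability(net, gene_probs, m) for m in net.molecules}
ia_scores = score_interactions(net, gene_probs)
dot = export_network(net, ia_scores, mol_probs, outdir / f"{net.pathway_id}_{sample}.dot")
print(f"network export: {dot} ({len(net.molecules)} molecules, {len(net.interactions)} interactions)")
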