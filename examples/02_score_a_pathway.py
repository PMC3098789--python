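"""Score activity and consistency for a small hand-built pathway.

Two interactions: (A and B) promote C while D inhibits nothing, then C
promotes E with D as an inhibitor.  Gene up-probabilities are set by hand so
every number below can be checked on paper: activity multiplies promoter
probabilities and inhibitor complements, consistency measures agreement
between that potential and the outputs, and the pathway score is the plain
mean over interactions.
"""

from pathscore import parse_pathway_text, score_interactions

PATHWAY = """\
#PATHWAY\tdemo\tdemo pathway (synthetic)
M\tA\t101\tgene A
M\tB\t102\tgene B
M\tC\t103\tgene C
M\tD\t104\tgene D
M\tE\t105\tgene E
I\ti1\tA,B\t-\tC
I\ti2\tC\tD\tE
"""

net = parse_pathway_text(PATHWAY)[0]
gene_probs = {"101": 0.9, "102": 0.8, "103": 0.7, "104": 0.25, "105": 0.6}

scores = score_interactions(net, gene_probs)
for s in scores:
    print(f"{s.interaction_id}: activity={s.activity:.4f} consistency={s.consistency:.4f}")
mean_act = sum(s.activity for s in scores) / len(scores)
mean_con = sum(s.consistency for s in scores) / len(scores)
print(f"pathway: activity={mean_act:.4f} consistency={mean_con:.4f}")
print()
print("i1: A = 0.9*0.8 = 0.72; P_out = 0.7; C = 0.72*0.7 + 0.28*0.3 = 0.588")
print("i2: A = 0.7*(1-0.25) = 0.525; P_out = 0.6; C = 0.525*0.6 + 0.475*0.4 = 0.505")
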