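"""Interaction- and pathway-level activity and consistency scores.

Given per-gene up-probabilities p(A), each interaction is scored per sample:

    activity     A = prod_promoters p(m) * prod_inhibitors (1 - p(m))
    consistency  C = A * P_out + (1 - A) * (1 - P_out),   P_out = prod_outputs p(m)

Activity measures the interaction's potential to occur — it is 1 exactly when
every promoter is certainly up and every inhibitor certainly down (inhibitors
enter as 1 - p).  Consistency is the probability that the realised output
state agrees with that potential: 1 when potential and outputs fully agree,
0 when they fully contradict, and identically 0.5 when A = 0.5.

Pathway scores are unweighted means of interaction scores: the activity mean
runs over all scoreable interactions (at least one measured input), the
consistency mean over interactions that additionally have at least one
measured output.  Because scores are plain averages, a perturbation of any
single interaction moves the pathway score by the same amount regardless of
where in the network it sits.

Measurement policy: a molecule's probability is the product of its member
genes' probabilities (a complex requires all members up); a gene's probability
is the mean posterior over its mapped probesets.  Molecules with no measured
member are "unmeasured"; inside an interaction with at least one measured
molecule in the same role group they are imputed at the neutral 0.5, while
interactions with no measured input at all are excluded from the pathway mean
rather than dragging it toward zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pathway_model import PathwayNetwork, ProbeMapping
from .updown import UpProbabilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionScores",
    "PathwayScoreMatrix",
    "UNMEASURED",
    "gene_probability_table",
    "gene_probability",
    "molecule_probability",
    "interaction_activity",
    "interaction_consistency",
    "score_interactions",
    "score_pathways",
]

UNMEASURED = None  # sentinel meaning "no probe information for this quantity"
NEUTRAL_PROB = 0.5


@dataclass
class InteractionScores:
    interaction_id: str
    activity: float
    consistency: float | None  # None when no output is measured
    n_measured_inputs: int
    n_measured_outputs: int


@dataclass
class PathwayScoreMatrix:
    """Pathway x sample activity and consistency matrices (NaN = unscoreable)."""

    activity: pd.DataFrame
    consistency: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.activity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity.columns)


def gene_probability_table(
    up: UpProbabilityMatrix, mapping: ProbeMapping
) -> pd.DataFrame:
    """Aggregate probeset posteriors to genes: mean over mapped probesets.

    Rows are Entrez ids with at least one measured probeset; genes absent
    from the result are unmeasured.
    """
    frame = up.to_frame()
    probes_present = set(frame.index)
    rows = {}
    for gene, probes in mapping.gene_to_probes.items():
        hit = sorted(probes & probes_present)
        if hit:
            rows[gene] = frame.loc[hit].to_numpy().mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=frame.columns)
    return out.sort_index()


def gene_probability(
    up: UpProbabilityMatrix, mapping: ProbeMapping, entrez_id: str, sample: str
) -> float | None:
    """p(gene up) for one sample: mean over mapped probesets, or unmeasured."""
    frame = up.to_frame()
    probes = sorted(mapping.probes_for(entrez_id) & set(frame.index))
    if not probes:
        return UNMEASURED
    return float(frame.loc[probes, sample].mean())


def molecule_probability(
    net: PathwayNetwork, gene_probs: dict[str, float], molecule_id: str
) -> float | None:
    """Probability a molecule is present: product over its measured genes.

    A complex is "up" only when all member genes are up, hence the product.
    Returns unmeasured when the molecule has no measured member gene.
    """
    mol = net.molecules[molecule_id]
    member = [gene_probs[g] for g in mol.entrez_ids if g in gene_probs]
    if not member:
        return UNMEASURED
    return float(np.prod(member))


def interaction_activity(
    promoter_probs: Sequence[float | None], inhibitor_probs: Sequence[float | None]
) -> float | None:
    """A = prod p(promoter) * prod (1 - p(inhibitor)); None if nothing measured.

    Unmeasured inputs are imputed at 0.5 provided at least one input is
    measured; with no measured input the interaction is unscoreable.
    """
    inputs = list(promoter_probs) + list(inhibitor_probs)
    if not inputs or all(p is UNMEASURED for p in inputs):
        return None
    a = 1.0
    for p in promoter_probs:
        a *= NEUTRAL_PROB if p is UNMEASURED else p
    for p in inhibitor_probs:
        a *= 1.0 - (NEUTRAL_PROB if p is UNMEASURED else p)
    return a


def interaction_consistency(
    activity: float, output_probs: Sequence[float | None]
) -> float | None:
    """C = A*P_out + (1-A)*(1-P_out); None when no output is measured."""
    if all(p is UNMEASURED for p in output_probs):
        return None
    p_out = 1.0
    for p in output_probs:
        p_out *= NEUTRAL_PROB if p is UNMEASURED else p
    return activity * p_out + (1.0 - activity) * (1.0 - p_out)


def score_interactions(
    net: PathwayNetwork, gene_probs: dict[str, float]
) -> list[InteractionScores]:
    """Score every interaction of one pathway for a single sample."""
    mol_prob = {
        mid: molecule_probability(net, gene_probs, mid) for mid in net.molecules
    }
    out = []
    for ia in net.interactions:
        promoters = [mol_prob[m] for m in ia.promoters]
        inhibitors = [mol_prob[m] for m in ia.inhibitors]
        outputs = [mol_prob[m] for m in ia.outputs]
        n_in = sum(p is not UNMEASURED for p in promoters + inhibitors)
        n_out = sum(p is not UNMEASURED for p in outputs)
        act = interaction_activity(promoters, inhibitors)
        if act is None:
            out.append(InteractionScores(ia.interaction_id, np.nan, None, 0, n_out))
            continue
        cons = interaction_consistency(act, outputs)
        out.append(InteractionScores(ia.interaction_id, act, cons, n_in, n_out))
    return out


def _score_pathway_vectorized(
    net: PathwayNetwork, gene_frame: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(activity, consistency) vectors over samples for one pathway.

    Same semantics as :func:`score_interactions`, computed for all samples at
    once; NaN marks a pathway x sample cell with no scoreable interaction.
    """
    n_samples = gene_frame.shape[1]
    measured_genes = set(gene_frame.index)
    gene_vals = {g: gene_frame.loc[g].to_numpy() for g in measured_genes}

    mol_vec: dict[str, np.ndarray | None] = {}
    for mid, mol in net.molecules.items():
        members = [gene_vals[g] for g in mol.entrez_ids if g in measured_genes]
        if not members:
            mol_vec[mid] = None
        else:
            v = members[0].copy()
            for m in members[1:]:
                v = v * m
            mol_vec[mid] = v

    act_sum = np.zeros(n_samples)
    act_n = 0
    con_sum = np.zeros(n_samples)
    con_n = 0
    neutral = np.full(n_samples, NEUTRAL_PROB)
    for ia in net.interactions:
        in_vecs = [mol_vec[m] for m in ia.promoters + ia.inhibitors]
        if all(v is None for v in in_vecs):
            continue
        a = np.ones(n_samples)
        for m in ia.promoters:
            v = mol_vec[m]
            a = a * (neutral if v is None else v)
        for m in ia.inhibitors:
            v = mol_vec[m]
            a = a * (1.0 - (neutral if v is None else v))
        act_sum += a
        act_n += 1
        out_vecs = [mol_vec[m] for m in ia.outputs]
        if all(v is None for v in out_vecs):
            continue
        p_out = np.ones(n_samples)
        for v in out_vecs:
            p_out = p_out * (neutral if v is None else v)
        con_sum += a * p_out + (1.0 - a) * (1.0 - p_out)
        con_n += 1

    activity = act_sum / act_n if act_n else np.full(n_samples, np.nan)
    consistency = con_sum / con_n if con_n else np.full(n_samples, np.nan)
    return activity, consistency


def score_pathways(
    up: UpProbabilityMatrix,
    nets: Sequence[PathwayNetwork],
    mapping: ProbeMapping,
    pathway_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> PathwayScoreMatrix:
    """Pathway x sample activity and consistency from probeset posteriors.

    Scores are computed per interaction and averaged (unweighted) over the
    pathway's scoreable interactions.  ``pathway_ids`` / ``sample_ids``
    restrict the computation to a subset; unknown names raise.
    """
    by_id = {net.pathway_id: net for net in nets}
    if pathway_ids is None:
        selected = list(by_id)
    else:
        pathway_ids = list(pathway_ids)
        if not pathway_ids:
            raise ValueError("empty pathway selection")
        unknown = [p for p in pathway_ids if p not in by_id]
        if unknown:
            raise KeyError(f"unknown pathway ids: {unknown}")
        selected = pathway_ids
    if sample_ids is None:
        samples = list(up.sample_ids)
    else:
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise ValueError("empty sample selection")
        unknown = [s for s in sample_ids if s not in up.sample_ids]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        samples = sample_ids

    gene_frame = gene_probability_table(up, mapping)[samples]
    act = np.empty((len(selected), len(samples)))
    con = np.empty_like(act)
    for i, pid in enumerate(selected):
        act[i], con[i] = _score_pathway_vectorized(by_id[pid], gene_frame)
        if np.all(np.isnan(act[i])):
            logger.warning("pathway %s: no scoreable interaction, flagged missing", pid)
    provenance = {
        "aggregation": "gene=mean(probes); molecule=product(genes)",
        "unmeasured_input": f"imputed {NEUTRAL_PROB} when any input measured",
        "pathway_score": "unweighted mean over scoreable interactions",
    }
    return PathwayScoreMatrix(
        activity=pd.DataFrame(act, index=selected, columns=samples),
        consistency=pd.DataFrame(con, index=selected, columns=samples),
        provenance=provenance,
    )
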