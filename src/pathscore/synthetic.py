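"""Seeded synthetic fixtures: expression, pathways, clinical tables.

The generator emulates the modelling assumptions of the scoring pipeline so
every module is testable without external data:

* expression — each probeset's intensities are drawn from its own
  two-gamma mixture with known component labels (the ground truth the
  up/down normaliser must recover);
* pathways — random connected promoter/inhibitor/output networks over
  synthetic Entrez ids, with a one-probe-per-gene mapping covering a
  configurable fraction of molecules;
* planted signal — one target pathway receives a per-sample "activation
  level" alpha in [0, 1]: its promoter and output genes are up with
  probability alpha, its inhibitor genes with probability 1 - alpha.
  Clinical tables are derived from alpha (class labels, a noisy continuous
  readout, exponential survival with a hazard ratio between activation
  groups) or from an alteration matrix enriched inside the target pathway,
  so each of the four association tests has a known answer.

All randomness flows from a single integer seed; identical seeds give
byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .association import ClinicalTable
from .pathway_model import Interaction, Molecule, PathwayNetwork, ProbeMapping, serialize_pathways
from .updown import ExpressionMatrix, write_matrix

__all__ = [
    "SyntheticSpec",
    "SyntheticBundle",
    "generate_pathways",
    "generate_expression",
    "generate_bundle",
    "plant_signal",
    "write_bundle",
]

_SIGNAL_KINDS = ("class_shift", "correlation", "hazard_ratio", "alteration_enrichment")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_samples: int = 60
    n_pathways: int = 21
    min_interactions: int = 5
    max_interactions: int = 15
    # mixture for every probeset: w * Gamma(k_d, t_d) + (1 - w) * Gamma(k_u, t_u)
    weight_down: float = 0.5
    shape_down: float = 2.0
    scale_down: float = 1.0
    shape_up: float = 8.0
    scale_up: float = 1.0
    coverage: float = 1.0          # fraction of genes with a measured probe
    probes_per_gene: int = 2       # measured probesets per covered gene
    target_pathway: int = 0        # index of the planted-signal pathway
    # planted effect sizes (see plant_signal)
    class_threshold: float = 0.5
    correlation_noise_sd: float = 0.10
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1
    censoring_hazard: float = 0.02
    alteration_base_rate: float = 0.05
    alteration_odds: float = 5.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_pathways <= 0:
            raise ValueError("counts must be positive")
        for p in (self.shape_down, self.scale_down, self.shape_up, self.scale_up):
            if p <= 0:
                raise ValueError("mixture parameters must be positive")
        if not 0 <= self.weight_down <= 1:
            raise ValueError("weight_down must lie in [0, 1]")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    expression: ExpressionMatrix
    mapping: ProbeMapping
    networks: list[PathwayNetwork]
    true_states: pd.DataFrame          # probe x sample, 1 = up component
    activation: pd.Series              # per-sample alpha of the target pathway
    target_pathway_id: str
    clinical: dict[str, ClinicalTable] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def _probes_for(gene: str, k: int) -> list[str]:
    return [f"p{gene}_{j}" for j in range(1, k + 1)]


def generate_pathways(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[PathwayNetwork], ProbeMapping]:
    """Random connected pathway networks plus a probe→gene mapping.

    Every molecule carries one fresh synthetic Entrez id, so decoy pathways
    share no genes with the target.  Connectivity is by construction: each
    interaction after the first promotes from the output of an earlier one.
    Inhibitor molecules are never reused, keeping gene roles unambiguous.
    """
    nets: list[PathwayNetwork] = []
    gene_counter = 1000
    all_genes: list[str] = []

    def new_molecule(molecules: dict[str, Molecule]) -> str:
        nonlocal gene_counter
        gene = str(gene_counter)
        gene_counter += 1
        all_genes.append(gene)
        mid = f"m{gene}"
        molecules[mid] = Molecule(mid, [gene], label=f"gene{gene}")
        return mid

    for p in range(spec.n_pathways):
        molecules: dict[str, Molecule] = {}
        interactions: list[Interaction] = []
        n_int = int(rng.integers(spec.min_interactions, spec.max_interactions + 1))
        outputs_pool: list[str] = []
        for j in range(n_int):
            if j == 0:
                promoters = [new_molecule(molecules)]
            else:
                promoters = [outputs_pool[rng.integers(len(outputs_pool))]]
            if rng.random() < 0.5:
                promoters.append(new_molecule(molecules))
            inhibitors = [new_molecule(molecules)] if rng.random() < 0.4 else []
            outputs = [new_molecule(molecules) for _ in range(int(rng.integers(1, 3)))]
            outputs_pool.extend(outputs)
            interactions.append(
                Interaction(f"pw{p}_i{j}", promoters, inhibitors, outputs)
            )
        nets.append(
            PathwayNetwork(
                pathway_id=f"pw{p}",
                name=f"synthetic pathway {p} (synthetic)",
                molecules=molecules,
                interactions=interactions,
            )
        )

    n_covered = int(round(spec.coverage * len(all_genes)))
    if n_covered == 0:
        raise ValueError("coverage leaves no measurable gene")
    covered = sorted(
        rng.choice(len(all_genes), size=n_covered, replace=False).tolist()
    )
    pairs = [
        (probe, all_genes[i])
        for i in covered
        for probe in _probes_for(all_genes[i], spec.probes_per_gene)
    ]
    return nets, ProbeMapping(pairs)


def generate_expression(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    probe_ids: list[str],
    up_prob: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Mixture-distributed intensities with known component labels.

    ``up_prob`` (probes x samples) gives each cell's probability of the up
    component; the default is the spec's 1 - weight_down everywhere.
    """
    n_p, n_s = len(probe_ids), spec.n_samples
    if up_prob is None:
        up_prob = np.full((n_p, n_s), 1.0 - spec.weight_down)
    states = (rng.random((n_p, n_s)) < up_prob).astype(int)
    down = rng.gamma(spec.shape_down, spec.scale_down, size=(n_p, n_s))
    up = rng.gamma(spec.shape_up, spec.scale_up, size=(n_p, n_s))
    values = np.where(states == 1, up, down)
    sample_ids = [f"s{i:03d}" for i in range(n_s)]
    expr = ExpressionMatrix(list(probe_ids), sample_ids, values)
    truth = pd.DataFrame(states, index=probe_ids, columns=sample_ids)
    return expr, truth


def _gene_roles(net: PathwayNetwork) -> tuple[set[str], set[str]]:
    """(activating genes, inhibiting genes) of a pathway by molecule role."""
    inhib_mols = {m for ia in net.interactions for m in ia.inhibitors}
    act_genes: set[str] = set()
    inh_genes: set[str] = set()
    for mid, mol in net.molecules.items():
        (inh_genes if mid in inhib_mols else act_genes).update(mol.entrez_ids)
    return act_genes - inh_genes, inh_genes


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Full fixture: pathways, mapping, expression with a planted activation.

    The target pathway's per-sample activation level alpha is switch-like:
    half the samples sit in a high regime (alpha ~ U(0.65, 0.95)), half in a
    low regime (alpha ~ U(0.05, 0.35)).  alpha sets the up-probability of the
    pathway's activating genes (1 - alpha for its inhibiting genes); all
    other genes follow the background mixture weight.
    """
    rng = np.random.default_rng(spec.seed)
    nets, mapping = generate_pathways(spec, rng)
    target = nets[spec.target_pathway]
    probe_ids = sorted({p for p, _ in mapping.pairs})
    probe_gene = {p: g for p, g in mapping.pairs}

    # switch-like activation: two regimes with within-regime variability,
    # mirroring the two-state (up/down) view of pathway behaviour
    regime = rng.random(spec.n_samples) < 0.5
    alpha = np.where(
        regime,
        rng.uniform(0.65, 0.95, size=spec.n_samples),
        rng.uniform(0.05, 0.35, size=spec.n_samples),
    )
    act_genes, inh_genes = _gene_roles(target)
    up_prob = np.full((len(probe_ids), spec.n_samples), 1.0 - spec.weight_down)
    for i, probe in enumerate(probe_ids):
        gene = probe_gene[probe]
        if gene in act_genes:
            up_prob[i] = alpha
        elif gene in inh_genes:
            up_prob[i] = 1.0 - alpha

    expr, truth = generate_expression(spec, rng, probe_ids, up_prob)
    activation = pd.Series(alpha, index=expr.sample_ids, name="activation")
    return SyntheticBundle(
        spec=spec,
        expression=expr,
        mapping=mapping,
        networks=nets,
        true_states=truth,
        activation=activation,
        target_pathway_id=target.pathway_id,
        truth={"activation": alpha.tolist(), "target_pathway": target.pathway_id},
    )


def plant_signal(bundle: SyntheticBundle, kind: str) -> SyntheticBundle:
    """Attach a clinical table with a known effect tied to the target pathway.

    * ``class_shift`` — class "B" are the samples whose activation exceeds the
      spec's threshold, i.e. the samples in which the target pathway's genes
      were pushed toward the up state.
    * ``correlation`` — continuous readout y = alpha + Gaussian noise.
    * ``hazard_ratio`` — exponential survival; the hazard of the
      high-activation regime is multiplied by the spec's hazard ratio, with
      independent exponential censoring.
    * ``alteration_enrichment`` — logical gene x sample matrix; alteration
      odds of the target pathway's genes exceed the background rate by the
      spec's odds factor.
    """
    if kind not in _SIGNAL_KINDS:
        raise ValueError(f"unknown effect kind {kind!r}; expected one of {_SIGNAL_KINDS}")
    spec = bundle.spec
    rng = np.random.default_rng([spec.seed, _SIGNAL_KINDS.index(kind) + 1])
    samples = list(bundle.expression.sample_ids)
    alpha = bundle.activation.to_numpy()

    if kind == "class_shift":
        labels = ["B" if a > spec.class_threshold else "A" for a in alpha]
        table = ClinicalTable(kind="class", sample_ids=samples, labels=labels)
    elif kind == "correlation":
        y = alpha + rng.normal(0.0, spec.correlation_noise_sd, size=len(alpha))
        table = ClinicalTable(kind="correlation", sample_ids=samples, values=y)
    elif kind == "hazard_ratio":
        high = alpha > spec.class_threshold
        hazard = spec.baseline_hazard * np.where(high, spec.hazard_ratio, 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / spec.censoring_hazard, size=len(alpha))
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        table = ClinicalTable(
            kind="survival", sample_ids=samples, times=times, events=events
        )
    else:  # alteration_enrichment
        genes = sorted(
            {g for net in bundle.networks for g in net.gene_set()}, key=int
        )
        target_genes = bundle.networks[spec.target_pathway].gene_set()
        rate = np.array(
            [
                min(spec.alteration_base_rate * spec.alteration_odds, 0.9)
                if g in target_genes
                else spec.alteration_base_rate
                for g in genes
            ]
        )
        mat = (rng.random((len(genes), len(samples))) < rate[:, None]).astype(int)
        table = ClinicalTable(
            kind="genehits",
            sample_ids=samples,
            alterations=pd.DataFrame(mat, index=genes, columns=samples),
        )

    clinical = dict(bundle.clinical)
    clinical[kind] = table
    return replace(bundle, clinical=clinical)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_note = f"seed={bundle.spec.seed}"
    paths: dict[str, Path] = {}

    paths["expression"] = outdir / "expression.tsv"
    write_matrix(bundle.expression.to_frame(), paths["expression"], seed_note)

    paths["mapping"] = outdir / "mapping.tsv"
    with paths["mapping"].open("w", encoding="utf-8") as fh:
        fh.write("probe_id\tentrez_id\n")
        for probe, gene in bundle.mapping.pairs:
            fh.write(f"{probe}\t{gene}\n")

    paths["pathways"] = outdir / "pathways.txt"
    paths["pathways"].write_text(serialize_pathways(bundle.networks), encoding="utf-8")

    for kind, table in bundle.clinical.items():
        if table.kind == "class":
            p = outdir / "clinical_class.tsv"
            with p.open("w", encoding="utf-8") as fh:
                for s, lab in zip(table.sample_ids, table.labels):
                    fh.write(f"{s}\t{lab}\n")
        elif table.kind == "correlation":
            p = outdir / "clinical_continuous.tsv"
            with p.open("w", encoding="utf-8") as fh:
                for s, v in zip(table.sample_ids, table.values):
                    fh.write(f"{s}\t{v:.10g}\n")
        elif table.kind == "survival":
            p = outdir / "clinical_survival.tsv"
            with p.open("w", encoding="utf-8") as fh:
                for s, t, e in zip(table.sample_ids, table.times, table.events):
                    fh.write(f"{s}\t{t:.10g}\t{e}\n")
        else:
            p = outdir / "alterations.tsv"
            write_matrix(table.alterations, p, seed_note)
        paths[kind] = p

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(
        json.dumps(bundle.truth, indent=2, sort_keys=True), encoding="utf-8"
    )
    return paths
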