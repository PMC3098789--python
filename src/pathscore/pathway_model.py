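"""Pathway network data model, parsing and validation.

A pathway is a connected set of interactions.  Each interaction has one or
more input molecules — promoters and/or inhibitors — and one or more output
molecules.  Molecules carry zero or more Entrez gene identifiers (zero for
small molecules or unresolved complexes); a separate probe→gene mapping links
expression measurements to molecules.

The on-disk interchange format is a plain-text, tab-delimited dialect:

    #PATHWAY<TAB>pathway_id<TAB>display name
    M<TAB>molecule_id<TAB>entrez1;entrez2;...<TAB>label
    I<TAB>interaction_id<TAB>promoters(csv)<TAB>inhibitors(csv or -)<TAB>outputs(csv)

Pathway blocks are separated by blank lines.  A lone ``-`` means "empty" in
any list field.  Parsing is loss-free: serialising a parsed collection and
re-parsing it yields structurally equal networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "Interaction",
    "PathwayNetwork",
    "ProbeMapping",
    "PathwayFormatError",
    "parse_pathway_file",
    "parse_pathway_text",
    "serialize_pathways",
    "validate_network",
    "load_probe_mapping",
    "coverage_report",
]


class PathwayFormatError(ValueError):
    """Raised when a pathway or mapping file violates the format contract."""


@dataclass
class Molecule:
    molecule_id: str
    entrez_ids: list[str] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.entrez_ids)) != len(self.entrez_ids):
            raise PathwayFormatError(
                f"molecule {self.molecule_id!r}: duplicate Entrez ids"
            )


@dataclass
class Interaction:
    interaction_id: str
    promoters: list[str] = field(default_factory=list)
    inhibitors: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for role, ids in (
            ("promoters", self.promoters),
            ("inhibitors", self.inhibitors),
            ("outputs", self.outputs),
        ):
            if len(set(ids)) != len(ids):
                raise PathwayFormatError(
                    f"interaction {self.interaction_id!r}: duplicate molecule in {role}"
                )
        if not self.promoters and not self.inhibitors:
            raise PathwayFormatError(
                f"interaction {self.interaction_id!r}: no input molecules"
            )
        if not self.outputs:
            raise PathwayFormatError(
                f"interaction {self.interaction_id!r}: no output molecules"
            )
        overlap = set(self.promoters) & set(self.inhibitors)
        if overlap:
            raise PathwayFormatError(
                f"interaction {self.interaction_id!r}: molecules "
                f"{sorted(overlap)} appear as both promoter and inhibitor"
            )

    @property
    def inputs(self) -> list[str]:
        return self.promoters + self.inhibitors

    def molecule_ids(self) -> set[str]:
        return set(self.promoters) | set(self.inhibitors) | set(self.outputs)


@dataclass
class PathwayNetwork:
    pathway_id: str
    name: str
    molecules: dict[str, Molecule]
    interactions: list[Interaction]

    def gene_set(self) -> set[str]:
        """Union of Entrez ids over all molecules in the pathway."""
        genes: set[str] = set()
        for mol in self.molecules.values():
            genes.update(mol.entrez_ids)
        return genes

    def interaction_graph(self) -> nx.Graph:
        """Interactions as nodes; an edge when two interactions share a molecule."""
        g = nx.Graph()
        g.add_nodes_from(ia.interaction_id for ia in self.interactions)
        by_molecule: dict[str, list[str]] = {}
        for ia in self.interactions:
            for mid in ia.molecule_ids():
                by_molecule.setdefault(mid, []).append(ia.interaction_id)
        for members in by_molecule.values():
            first = members[0]
            for other in members[1:]:
                g.add_edge(first, other)
        return g


@dataclass
class ProbeMapping:
    """Many-to-many probe→Entrez-gene association table."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.probe_to_genes: dict[str, set[str]] = {}
        self.gene_to_probes: dict[str, set[str]] = {}
        for probe, gene in self.pairs:
            self.probe_to_genes.setdefault(probe, set()).add(gene)
            self.gene_to_probes.setdefault(gene, set()).add(probe)

    def __len__(self) -> int:
        return len(self.pairs)

    def probes_for(self, entrez_id: str) -> set[str]:
        return self.gene_to_probes.get(entrez_id, set())


def _split_list(tok: str) -> list[str]:
    tok = tok.strip()
    if tok in ("", "-"):
        return []
    return [t for t in (s.strip() for s in tok.split(",")) if t]


def parse_pathway_text(text: str, source: str = "<string>") -> list[PathwayNetwork]:
    """Parse the tab-delimited pathway dialect from a string.

    Raises :class:`PathwayFormatError` naming the offending line on any
    malformed record, dangling molecule reference or empty pathway.
    """
    networks: list[PathwayNetwork] = []
    current: dict | None = None

    def close(block: dict | None) -> None:
        if block is None:
            return
        net = PathwayNetwork(
            pathway_id=block["id"],
            name=block["name"],
            molecules=block["molecules"],
            interactions=block["interactions"],
        )
        if not net.interactions:
            raise PathwayFormatError(
                f"{source}: pathway {net.pathway_id!r} has no interactions"
            )
        for ia in net.interactions:
            for mid in sorted(ia.molecule_ids()):
                if mid not in net.molecules:
                    raise PathwayFormatError(
                        f"{source}: interaction {ia.interaction_id!r} references "
                        f"undeclared molecule {mid!r}"
                    )
        if not nx.is_connected(net.interaction_graph()):
            logger.warning(
                "pathway %s: interaction graph is not connected", net.pathway_id
            )
        networks.append(net)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            close(current)
            current = None
            continue
        fields = line.split("\t")
        tag = fields[0]
        loc = f"{source}:{lineno}"
        if tag == "#PATHWAY":
            close(current)
            if len(fields) != 3:
                raise PathwayFormatError(f"{loc}: #PATHWAY needs id and name")
            current = {
                "id": fields[1].strip(),
                "name": fields[2].strip(),
                "molecules": {},
                "interactions": [],
            }
        elif tag == "M":
            if current is None:
                raise PathwayFormatError(f"{loc}: molecule line outside a pathway block")
            if len(fields) != 4:
                raise PathwayFormatError(f"{loc}: M line needs 4 tab-separated fields")
            mid = fields[1].strip()
            if mid in current["molecules"]:
                raise PathwayFormatError(f"{loc}: duplicate molecule id {mid!r}")
            entrez = [e for e in (s.strip() for s in fields[2].split(";")) if e and e != "-"]
            try:
                current["molecules"][mid] = Molecule(mid, entrez, fields[3].strip())
            except PathwayFormatError as exc:
                raise PathwayFormatError(f"{loc}: {exc}") from None
        elif tag == "I":
            if current is None:
                raise PathwayFormatError(f"{loc}: interaction line outside a pathway block")
            if len(fields) != 5:
                raise PathwayFormatError(f"{loc}: I line needs 5 tab-separated fields")
            try:
                ia = Interaction(
                    fields[1].strip(),
                    _split_list(fields[2]),
                    _split_list(fields[3]),
                    _split_list(fields[4]),
                )
            except PathwayFormatError as exc:
                raise PathwayFormatError(f"{loc}: {exc}") from None
            current["interactions"].append(ia)
        else:
            raise PathwayFormatError(f"{loc}: unknown record tag {tag!r}")
    close(current)
    if not networks:
        raise PathwayFormatError(f"{source}: no pathways found")
    return networks


def parse_pathway_file(path: str | Path) -> list[PathwayNetwork]:
    """Parse a pathway file into a list of validated :class:`PathwayNetwork`."""
    path = Path(path)
    return parse_pathway_text(path.read_text(encoding="utf-8"), source=str(path))


def _fmt_list(ids: Sequence[str]) -> str:
    return ",".join(ids) if ids else "-"


def serialize_pathways(nets: Iterable[PathwayNetwork]) -> str:
    """Inverse of :func:`parse_pathway_text` (up to whitespace)."""
    blocks = []
    for net in nets:
        lines = [f"#PATHWAY\t{net.pathway_id}\t{net.name}"]
        for mol in net.molecules.values():
            entrez = ";".join(mol.entrez_ids) if mol.entrez_ids else "-"
            lines.append(f"M\t{mol.molecule_id}\t{entrez}\t{mol.label}")
        for ia in net.interactions:
            lines.append(
                "I\t{}\t{}\t{}\t{}".format(
                    ia.interaction_id,
                    _fmt_list(ia.promoters),
                    _fmt_list(ia.inhibitors),
                    _fmt_list(ia.outputs),
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def validate_network(net: PathwayNetwork) -> list[str]:
    """Check all structural invariants; violations are returned, not raised.

    An empty report means the network is valid, including connectedness of
    the interaction graph (interactions joined when they share a molecule).
    """
    report: list[str] = []
    if not net.interactions:
        report.append("no interactions")
    for ia in net.interactions:
        if not ia.outputs:
            report.append(f"interaction {ia.interaction_id}: no outputs")
        if not ia.promoters and not ia.inhibitors:
            report.append(f"interaction {ia.interaction_id}: no inputs")
        overlap = set(ia.promoters) & set(ia.inhibitors)
        if overlap:
            report.append(
                f"interaction {ia.interaction_id}: promoter/inhibitor overlap "
                f"{sorted(overlap)}"
            )
        for mid in sorted(ia.molecule_ids()):
            if mid not in net.molecules:
                report.append(
                    f"interaction {ia.interaction_id}: dangling molecule reference {mid}"
                )
    for mol in net.molecules.values():
        if len(set(mol.entrez_ids)) != len(mol.entrez_ids):
            report.append(f"molecule {mol.molecule_id}: duplicate Entrez ids")
    if net.interactions:
        graph = net.interaction_graph()
        if not nx.is_connected(graph):
            n_parts = nx.number_connected_components(graph)
            report.append(f"disconnected: {n_parts} interaction components")
    return report


def load_probe_mapping(path: str | Path) -> ProbeMapping:
    """Load a two-column ``probe_id<TAB>entrez_id`` mapping file.

    A header row is detected (and skipped) when the second field is not a
    positive integer.  Rows whose Entrez field fails to parse are skipped with
    a logged warning; duplicated pairs are collapsed.  Probes mapping to
    several genes, and genes measured by several probes, are both kept.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    skipped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                skipped += 1
                logger.warning("%s:%d: expected 2 columns, skipped", path, lineno)
                continue
            probe, entrez = fields[0].strip(), fields[1].strip()
            if not (entrez.isdigit() and int(entrez) > 0):
                if lineno == 1:  # header row
                    continue
                skipped += 1
                logger.warning(
                    "%s:%d: Entrez id %r is not a positive integer, skipped",
                    path, lineno, entrez,
                )
                continue
            pair = (probe, entrez)
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if skipped:
        logger.info("%s: skipped %d unparseable rows", path, skipped)
    if not pairs:
        raise PathwayFormatError(f"{path}: no valid probe-gene rows")
    return ProbeMapping(pairs)


def coverage_report(
    net: PathwayNetwork, mapping: ProbeMapping, measured_probes: set[str]
) -> float:
    """Fraction of the pathway's molecules with at least one measured probe.

    A molecule counts as measured when any of its Entrez genes maps to a
    probe present in ``measured_probes``.  Molecules with no Entrez ids
    (small molecules, unresolved complexes) count as unmeasured.
    """
    if not net.molecules:
        return 0.0
    n_measured = 0
    for mol in net.molecules.values():
        probes: set[str] = set()
        for gene in mol.entrez_ids:
            probes |= mapping.probes_for(gene)
        if probes & measured_probes:
            n_measured += 1
    return n_measured / len(net.molecules)
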