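import numpy as np
import pytest

from pathscore.pathway_model import (
    Interaction,
    Molecule,
    PathwayNetwork,
    ProbeMapping,
    parse_pathway_text,
)

TOY_PATHWAY_TEXT = """\
#PATHWAY\tpw1\ttoy signalling (synthetic)
M\tA\t101\tgene A
M\tB\t102\tgene B
M\tC\t103;104\tcomplex BC
M\tD\t105\tgene D
M\tE\t-\tsmall molecule E
I\ti1\tA,B\t-\tC
I\ti2\tC\tD\tE
"""


@pytest.fixture
def toy_pathway_text() -> str:
    return TOY_PATHWAY_TEXT


@pytest.fixture
def toy_net() -> PathwayNetwork:
    return parse_pathway_text(TOY_PATHWAY_TEXT)[0]


@pytest.fixture
def toy_mapping() -> ProbeMapping:
    return ProbeMapping(
        [
            ("p1", "101"),
            ("p2", "102"),
            ("p3", "103"),
            ("p4", "104"),
            ("p5", "105"),
        ]
    )


def make_network(pathway_id: str, interactions: list[Interaction]) -> PathwayNetwork:
    """Build a network declaring every referenced molecule as a 1-gene entity."""
    mol_ids = sorted({m for ia in interactions for m in ia.molecule_ids()})
    molecules = {
        mid: Molecule(mid, [str(1000 + i)], label=mid)
        for i, mid in enumerate(mol_ids)
    }
    return PathwayNetwork(pathway_id, f"{pathway_id} (synthetic)", molecules, interactions)


def random_toy_network(rng: np.random.Generator, pathway_id: str = "rnd") -> PathwayNetwork:
    """Small random connected network for oracle comparisons."""
    n_int = int(rng.integers(2, 6))
    interactions = []
    pool: list[str] = []
    counter = 0

    def fresh() -> str:
        nonlocal counter
        counter += 1
        return f"{pathway_id}_m{counter}"

    for j in range(n_int):
        promoters = [pool[rng.integers(len(pool))]] if (j > 0 and rng.random() < 0.7) else [fresh()]
        if rng.random() < 0.5:
            promoters.append(fresh())
        inhibitors = [fresh()] if rng.random() < 0.5 else []
        outputs = [fresh() for _ in range(int(rng.integers(1, 3)))]
        pool.extend(outputs + promoters)
        interactions.append(Interaction(f"{pathway_id}_i{j}", promoters, inhibitors, outputs))
    return make_network(pathway_id, interactions)
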