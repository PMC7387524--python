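import numpy as np
import pytest

from aarsfp.core import InteractionRecord, InteractionType, StructureComplex
from aarsfp.synthetic import default_spec, generate_complexes, ligand_graph


def make_record(
    itype=InteractionType.HYDROGEN_BOND,
    residue="TYR",
    number=100,
    chain="A",
    atoms=("N",),
):
    return InteractionRecord(
        itype=itype,
        protein_residue_type=residue,
        protein_residue_number=number,
        chain_id=chain,
        ligand_atom_ids=frozenset(atoms),
    )


def make_complex(
    aars="AlaRS",
    records=(),
    state="pre_activation",
    volume=None,
    structure_id="TEST",
    coordinates=None,
):
    """Minimal well-formed complex over the synthetic ligand graph."""
    return StructureComplex(
        structure_id=structure_id,
        aars=aars,
        ligand_graph=ligand_graph(aars[:-2], state),
        interactions=list(records),
        reaction_state=state,
        cavity_volume=volume,
        coordinates=coordinates,
    )


@pytest.fixture(scope="session")
def generator_spec():
    return default_spec()


@pytest.fixture(scope="session")
def small_dataset(generator_spec):
    """20 structures per synthetase, the size used for design comparison."""
    return generate_complexes(generator_spec, n_per_aars=20, seed=2024)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
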