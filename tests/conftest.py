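"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import gemmi
import numpy as np
import pytest
from hypothesis import settings

from evorate.seq_io import Alignment, SequenceRecord

# property tests must behave identically on every machine and run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from evorate.simulate import SimulationSpec, simulate_dataset


def make_alignment(rows: dict[str, str], query_id: str, alphabet: str = "protein") -> Alignment:
    records = [SequenceRecord(k, v) for k, v in rows.items()]
    return Alignment(records=records, query_id=query_id, alphabet=alphabet)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The parameter-recovery study conditions: 60 taxa x 300 sites,
    protein, gamma shape 0.8, fixed seed."""
    return simulate_dataset(
        SimulationSpec(n_leaves=60, n_sites=300, alphabet="protein", alpha=0.8, seed=42)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small dataset for fast end-to-end runs."""
    return simulate_dataset(
        SimulationSpec(n_leaves=12, n_sites=60, alphabet="protein", alpha=0.8, seed=11)
    )


def build_synthetic_structure(
    seq3: list[str],
    chains: tuple[str, ...] = ("A",),
    with_water: bool = True,
    mutate_last_chain: bool = False,
) -> gemmi.Structure:
    """Synthetic multi-chain structure built in memory (no real PDB entry);
    three backbone atoms per residue, optional waters, optional one-residue
    difference on the last chain."""
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    for ci, cid in enumerate(chains):
        chain = gemmi.Chain(cid)
        seq = list(seq3)
        if mutate_last_chain and ci == len(chains) - 1:
            seq[0] = "GLY" if seq[0] != "GLY" else "ALA"
        for i, name in enumerate(seq, start=1):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(i, " ")
            res.het_flag = "H" if name in ("MSE", "SEP", "PTR", "TPO") else "A"
            for j, aname in enumerate(("N", "CA", "C")):
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element("N" if aname == "N" else "C")
                at.pos = gemmi.Position(i * 3.0 + j, ci * 10.0, 0.0)
                at.occ = 1.0
                at.b_iso = 20.0
                res.add_atom(at)
            chain.add_residue(res)
        if with_water:
            w = gemmi.Residue()
            w.name = "HOH"
            w.seqid = gemmi.SeqId(200, " ")
            w.het_flag = "H"
            at = gemmi.Atom()
            at.name = "O"
            at.element = gemmi.Element("O")
            at.pos = gemmi.Position(0.0, 0.0, 5.0 + ci)
            at.occ = 1.0
            at.b_iso = 30.0
            w.add_atom(at)
            chain.add_residue(w)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


@pytest.fixture
def structure_pair(tmp_path):
    """Equivalent synthetic PDB and mmCIF files (homo-dimer with an MSE)."""
    seq3 = ["ALA", "GLY", "MSE", "LYS", "VAL", "THR", "GLU", "LEU"]
    st = build_synthetic_structure(seq3, chains=("A", "B"))
    pdb = tmp_path / "synthetic.pdb"
    cif = tmp_path / "synthetic.cif"
    st.write_pdb(str(pdb))
    st.make_mmcif_document().write_file(str(cif))
    return pdb, cif, "AGMKVTEL"


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
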