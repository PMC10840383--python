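import numpy as np
import pytest

from intol3d import mtr_core, synthetic_data as sd


@pytest.fixture
def helix_structure():
    return sd.make_structure(60, geometry="helix", seed=11)


@pytest.fixture
def uniform_counts_setup(helix_structure):
    """A helix plus observed counts drawn exactly at expected proportions."""
    seq = helix_structure.sequences["geneA"]
    cds = sd.cds_for_protein(seq, "geneA")
    counts = mtr_core.enumerate_codon_expectations(cds)
    for c in counts:
        c.obs_missense = c.exp_missense
        c.obs_synonymous = c.exp_synonymous
    return helix_structure, cds, counts


def collinear_sites(xs, chain="A", structure_id="LINE"):
    from intol3d.structure3d import ResidueSite

    return [
        ResidueSite(
            structure_id=structure_id,
            chain_id=chain,
            residue_number=i + 1,
            amino_acid="A",
            coord=(float(x), 0.0, 0.0),
        )
        for i, x in enumerate(xs)
    ]


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three residues with Cα 3.8 Å apart, plus one altloc pair."""
    lines = [
        "HEADER    SYNTHETIC",
        "ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ATOM      3  CB  ALA A   1       0.500   1.000   0.000  1.00  0.00           C",
        "ATOM      4  CA AGLY A   2       3.800   0.000   0.000  0.70  0.00           C",
        "ATOM      5  CA BGLY A   2       3.900   0.100   0.000  0.30  0.00           C",
        "ATOM      6  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C",
        "ATOM      7  OG  SER A   3       7.600   2.000   0.000  1.00  0.00           O",
        "TER",
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
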