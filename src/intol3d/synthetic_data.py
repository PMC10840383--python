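"""Deterministic generators for every input format the pipeline consumes.

Each generator takes an explicit seed and, for a fixed seed, produces
byte-identical files on rerun.  Geometries are idealized (α-helix
constants, cubic lattices); they only need to create meaningful 3D
neighbourhoods, not realistic folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mtr_core import GENETIC_CODE, TranscriptCDS, enumerate_codon_expectations
from .structure3d import ONE_TO_THREE, ResidueSite

__all__ = [
    "SyntheticStructure",
    "make_cds",
    "make_structure",
    "make_variant_counts",
    "make_dose_response",
    "make_plate",
    "make_adhesion",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NONSTOP_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
# representative codon per amino acid, for building a CDS that encodes a
# prescribed protein sequence
_CODON_FOR_AA = {}
for _codon in _NONSTOP_CODONS:
    _CODON_FOR_AA.setdefault(GENETIC_CODE[_codon], _codon)

HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TWIST = math.radians(100.0)


@dataclass
class SyntheticStructure:
    structure_id: str
    sites: list[ResidueSite]
    sequences: dict[str, str]  # gene_id -> protein sequence
    chain_genes: dict[str, str]  # chain_id -> gene_id

    def sites_by_chain(self) -> dict[str, list[ResidueSite]]:
        out: dict[str, list[ResidueSite]] = {}
        for s in self.sites:
            out.setdefault(s.chain_id, []).append(s)
        return out

    def to_pdb(self, path) -> None:
        """Write Cα-only ATOM records in standard fixed columns."""
        with open(path, "w") as fh:
            serial = 1
            prev_chain = None
            for s in self.sites:
                if prev_chain is not None and s.chain_id != prev_chain:
                    fh.write("TER\n")
                prev_chain = s.chain_id
                resname = ONE_TO_THREE.get(s.amino_acid, "UNK")
                x, y, z = s.coord
                fh.write(
                    f"ATOM  {serial:>5d}  CA  {resname:>3s} {s.chain_id}"
                    f"{s.residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}           C\n"
                )
                serial += 1
            fh.write("TER\nEND\n")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gene_id in sorted(self.sequences):
                fh.write(f">{gene_id}\n{self.sequences[gene_id]}\n")


def make_cds(n_codons: int, seed: int, gene_id: str = "geneA") -> TranscriptCDS:
    """Random CDS of ``n_codons`` coding codons (ATG start, TAA terminal stop)."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 1)
    seq = "ATG" + "".join(body) + "TAA"
    return TranscriptCDS(gene_id=gene_id, sequence=seq)


def cds_for_protein(protein_seq: str, gene_id: str) -> TranscriptCDS:
    """A CDS encoding exactly ``protein_seq`` (one fixed codon per residue)."""
    seq = "".join(_CODON_FOR_AA[aa] for aa in protein_seq) + "TAA"
    return TranscriptCDS(gene_id=gene_id, sequence=seq)


def _helix_coords(n: int, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    i = np.arange(n)
    x = HELIX_RADIUS * np.cos(HELIX_TWIST * i) + origin[0]
    y = HELIX_RADIUS * np.sin(HELIX_TWIST * i) + origin[1]
    z = HELIX_RISE * i + origin[2]
    return np.column_stack([x, y, z])


def _lattice_coords(n: int, spacing: float) -> np.ndarray:
    side = math.ceil(n ** (1.0 / 3.0))
    pts = []
    for a in range(side):
        for b in range(side):
            for c in range(side):
                pts.append((a * spacing, b * spacing, c * spacing))
                if len(pts) == n:
                    return np.asarray(pts, dtype=float)
    return np.asarray(pts[:n], dtype=float)


def _random_sequence(n: int, rng) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


def make_structure(
    n_residues: int,
    geometry: str = "helix",
    spacing: float = 3.8,
    seed: int = 0,
    dropout: tuple[int, ...] = (),
    contact_gap: float = 6.0,
    structure_id: str = "SYN1",
) -> SyntheticStructure:
    """Synthetic Cα trace(s) with per-chain sequences.

    Geometries: ``helix`` (one chain), ``lattice`` (one chain),
    ``two-chain`` (two well-separated copies of the same protein),
    ``complex`` (two different proteins with a contact patch closer than
    8 Å).  ``dropout`` lists residue numbers omitted from every chain,
    emulating missing density.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    rng = np.random.default_rng(seed)
    seq_a = _random_sequence(n_residues, rng)
    drop = set(dropout)

    def chain_sites(chain_id: str, coords: np.ndarray, seq: str) -> list[ResidueSite]:
        sites = []
        for idx in range(len(seq)):
            resnum = idx + 1
            if resnum in drop:
                continue
            sites.append(
                ResidueSite(
                    structure_id=structure_id,
                    chain_id=chain_id,
                    residue_number=resnum,
                    amino_acid=seq[idx],
                    coord=tuple(float(v) for v in coords[idx]),
                )
            )
        return sites

    if geometry == "helix":
        sites = chain_sites("A", _helix_coords(n_residues), seq_a)
        sequences = {"geneA": seq_a}
        chain_genes = {"A": "geneA"}
    elif geometry == "lattice":
        sites = chain_sites("A", _lattice_coords(n_residues, spacing), seq_a)
        sequences = {"geneA": seq_a}
        chain_genes = {"A": "geneA"}
    elif geometry == "two-chain":
        coords_a = _helix_coords(n_residues)
        coords_b = _helix_coords(n_residues, origin=(60.0, 0.0, 0.0))
        sites = chain_sites("A", coords_a, seq_a) + chain_sites("B", coords_b, seq_a)
        sequences = {"geneA": seq_a}
        chain_genes = {"A": "geneA", "B": "geneA"}
    elif geometry == "complex":
        seq_b = _random_sequence(n_residues, rng)
        coords_a = _helix_coords(n_residues)
        coords_b = _helix_coords(n_residues, origin=(50.0, 0.0, 0.0))
        # translate protein B so the closest inter-protein Cα gap equals contact_gap
        dmin = min(
            float(np.linalg.norm(ca - cb)) for ca in coords_a for cb in coords_b
        )
        coords_b[:, 0] -= dmin - contact_gap
        sites = chain_sites("A", coords_a, seq_a) + chain_sites("B", coords_b, seq_b)
        sequences = {"geneA": seq_a, "geneB": seq_b}
        chain_genes = {"A": "geneA", "B": "geneB"}
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return SyntheticStructure(
        structure_id=structure_id, sites=sites, sequences=sequences, chain_genes=chain_genes
    )


def make_variant_counts(
    cds: TranscriptCDS,
    baseline_rate: float,
    depleted_positions: tuple[int, ...] = (),
    depletion_factor: float = 1.0,
    seed: int = 0,
    overdispersion: float | None = None,
) -> pd.DataFrame:
    """Poisson-sampled per-codon observation counts.

    obs_syn ~ Poisson(rate · exp_syn); obs_mis ~ Poisson(rate · exp_mis · d)
    with d = ``depletion_factor`` at depleted positions and 1 elsewhere.
    ``overdispersion`` switches to a negative-binomial (gamma-Poisson)
    model with the given shape parameter.
    """
    if not (0.0 <= depletion_factor <= 1.0):
        raise ValueError("depletion_factor must be in [0, 1]")
    rng = np.random.default_rng(seed)
    depleted = set(depleted_positions)
    rows = []
    for counts in enumerate_codon_expectations(cds):
        d = depletion_factor if counts.codon_index in depleted else 1.0
        mu_mis = baseline_rate * counts.exp_missense * d
        mu_syn = baseline_rate * counts.exp_synonymous
        if overdispersion is None:
            obs_mis = int(rng.poisson(mu_mis))
            obs_syn = int(rng.poisson(mu_syn))
        else:
            shape = overdispersion
            obs_mis = int(rng.poisson(rng.gamma(shape, mu_mis / shape) if mu_mis > 0 else 0.0))
            obs_syn = int(rng.poisson(rng.gamma(shape, mu_syn / shape) if mu_syn > 0 else 0.0))
        rows.append(
            {
                "gene_id": cds.gene_id,
                "codon_index": counts.codon_index,
                "obs_missense": obs_mis,
                "obs_synonymous": obs_syn,
            }
        )
    return pd.DataFrame(rows)


def write_counts_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def make_dose_response(
    model: str,
    midpoint: float,
    concentrations,
    nh: float = 1.0,
    minimum: float = 5.0,
    noise_sd: float = 3.0,
    n_cells: int = 3,
    seed: int = 0,
    construct: str = "synthetic",
    compound: str = "drug",
    i_baseline: float = -1400.0,
    i_nmdg: float = -100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-model concentration-response recordings.

    ``model`` is ``"activation"`` or ``"inhibition"``; responses carry
    Gaussian noise of ``noise_sd`` percent of the maximal response and are
    rendered as membrane currents consistent with the chosen reference
    currents.  Returns (curves, refs) DataFrames matching the CSV dialect
    the fitters consume.
    """
    from .pharmacology import hill_activation, hill_inhibition

    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not (conc.min() < midpoint < conc.max()):
        raise ValueError("concentrations must span the midpoint")
    rng = np.random.default_rng(seed)
    log_mid = math.log10(midpoint)
    if model == "activation":
        clean = hill_activation(conc, log_mid, nh)
    elif model == "inhibition":
        clean = hill_inhibition(conc, log_mid, nh, minimum)
    else:
        raise ValueError(f"unknown model {model!r}")

    span = i_baseline - i_nmdg
    curve_rows = []
    ref_rows = []
    for c in range(n_cells):
        cell = f"cell{c + 1:02d}"
        resp = clean + rng.normal(0.0, noise_sd, size=len(conc))
        current = i_nmdg + resp / 100.0 * span
        for conc_i, cur_i in zip(conc, current):
            curve_rows.append(
                {
                    "cell_id": cell,
                    "construct": construct,
                    "compound": compound,
                    "concentration_M": conc_i,
                    "current_nA": cur_i,
                }
            )
        ref_rows.append({"cell_id": cell, "I_baseline_nA": i_baseline, "I_NMDG_nA": i_nmdg})
    return pd.DataFrame(curve_rows), pd.DataFrame(ref_rows)


def make_plate(
    slope_surface: float,
    slope_total: float,
    noise: float = 0.0,
    wells_per_compartment: int = 4,
    n_timepoints: int = 31,
    seed: int = 0,
    construct: str = "WT",
    intercept: float = 0.1,
) -> pd.DataFrame:
    """Linear absorbance ramps (one reading per minute) with Gaussian noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints, dtype=float)
    rows = []
    for compartment, slope in (("surface", slope_surface), ("total", slope_total)):
        for w in range(wells_per_compartment):
            well = f"{construct}-{compartment}-{w + 1}"
            absorbance = intercept + slope * t + rng.normal(0.0, noise, size=len(t))
            for ti, ai in zip(t, absorbance):
                rows.append(
                    {
                        "well": well,
                        "construct": construct,
                        "compartment": compartment,
                        "t_min": ti,
                        "absorbance": ai,
                    }
                )
    return pd.DataFrame(rows)


def make_adhesion(
    p_adhesion: float,
    n_contacts: int = 50,
    n_pairs: int = 10,
    seed: int = 0,
    condition: str = "WT",
) -> pd.DataFrame:
    """Bernoulli contact outcomes aggregated per bead-cell pair."""
    if not (0.0 <= p_adhesion <= 1.0):
        raise ValueError("p_adhesion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pairs):
        n_adh = int(rng.binomial(n_contacts, p_adhesion))
        rows.append(
            {
                "pair_id": f"{condition}-pair{p + 1:03d}",
                "condition": condition,
                "n_contacts": n_contacts,
                "n_adhesions": n_adh,
            }
        )
    return pd.DataFrame(rows)
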