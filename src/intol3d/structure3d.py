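"""Structure handling: residue sites, spatial windows, alignment, mapping.

PDB reading/writing is deliberately line-oriented: the B-factor writer
must leave every non-B-factor byte of the input untouched, so the same
fixed-column conventions are used on the way in and the way out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueSite",
    "PairwiseAlignment",
    "ResidueAlignmentMap",
    "parse_structure",
    "knn_window",
    "align_proteins",
    "map_gene_to_structure",
    "write_bfactor_pdb",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ResidueSite:
    """One residue with a representative 3D coordinate (Å)."""

    structure_id: str
    chain_id: str
    residue_number: int
    amino_acid: str
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in self.coord):
            raise ValueError(f"non-finite coordinate for {self.chain_id}{self.residue_number}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Global alignment between two protein sequences.

    ``pairs`` holds 1-based matched positions (i in seq_a, j in seq_b),
    strictly increasing in both coordinates; gap columns never pair.
    """

    pairs: tuple[tuple[int, int], ...]
    score: float
    identity: float

    def __post_init__(self) -> None:
        last_i, last_j = 0, 0
        for i, j in self.pairs:
            if i <= last_i or j <= last_j:
                raise ValueError("alignment pairs must be strictly increasing")
            last_i, last_j = i, j

    def mapping(self) -> dict[int, int]:
        return dict(self.pairs)


@dataclass
class ResidueAlignmentMap:
    """Gene protein positions mapped to structure residues.

    Unmapped positions (gaps, residues without density) are simply absent
    from ``entries``.
    """

    gene_id: str
    entries: list[tuple[int, str, int]]  # (protein_position, chain_id, residue_number)
    coverage: float

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        self._by_residue: dict[tuple[str, int], int] = {}
        self._by_position: dict[int, list[tuple[str, int]]] = {}
        for pos, chain, resnum in self.entries:
            if (pos, chain) in seen:
                raise ValueError(f"position {pos} maps twice within chain {chain}")
            seen.add((pos, chain))
            self._by_residue[(chain, resnum)] = pos
            self._by_position.setdefault(pos, []).append((chain, resnum))

    def position_of(self, chain_id: str, residue_number: int) -> int | None:
        return self._by_residue.get((chain_id, residue_number))

    def residues_at(self, position: int) -> list[tuple[str, int]]:
        return list(self._by_position.get(position, []))

    @property
    def positions(self) -> list[int]:
        return sorted(self._by_position)


def _parse_atom_line(line: str):
    name = line[12:16].strip()
    altloc = line[16]
    resname = line[17:20].strip()
    chain = line[21]
    resnum = int(line[22:26])
    icode = line[26]
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    occ_field = line[54:60].strip()
    occ = float(occ_field) if occ_field else 1.0
    return name, altloc, resname, chain, resnum, icode, occ, (x, y, z)


def parse_structure(path, representative: str = "CA", structure_id: str | None = None) -> list[ResidueSite]:
    """Parse PDB ATOM records (first model only) into residue sites.

    ``representative`` is ``"CA"`` or ``"sidechain"`` (side-chain centroid,
    glycine and residues without side-chain atoms fall back to Cα).
    Alternate locations resolve to the highest-occupancy copy, ties to the
    lexically first altloc; residues lacking a representative atom are
    dropped with a warning.
    """
    if representative not in ("CA", "sidechain"):
        raise ValueError(f"unknown representative mode {representative!r}")
    sid = structure_id or str(path)
    residues: dict[tuple[str, int, str], dict] = {}
    order: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break  # first model only
            if not line.startswith("ATOM"):
                continue
            name, altloc, resname, chain, resnum, icode, occ, coord = _parse_atom_line(line)
            key = (chain, resnum, icode)
            if key not in residues:
                residues[key] = {"resname": resname, "atoms": {}}
                order.append(key)
            atoms = residues[key]["atoms"]
            # occupancy-major altloc resolution; lexical altloc breaks ties
            prev = atoms.get(name)
            if prev is None or occ > prev[0] or (occ == prev[0] and altloc < prev[1]):
                atoms[name] = (occ, altloc, coord)
    if not residues:
        raise ValueError(f"no ATOM records in {path}")

    sites: list[ResidueSite] = []
    for key in order:
        chain, resnum, _icode = key
        rec = residues[key]
        atoms = rec["atoms"]
        coord = None
        if representative == "sidechain":
            side = [v[2] for name, v in atoms.items() if name not in _BACKBONE]
            if side:
                coord = tuple(np.mean(np.asarray(side), axis=0))
        if coord is None:
            ca = atoms.get("CA")
            if ca is None:
                logger.warning("residue %s%s lacks a representative atom; dropped", chain, resnum)
                continue
            coord = ca[2]
        aa = THREE_TO_ONE.get(rec["resname"], "X")
        sites.append(
            ResidueSite(
                structure_id=sid,
                chain_id=chain,
                residue_number=resnum,
                amino_acid=aa,
                coord=tuple(float(c) for c in coord),
            )
        )
    return sites


def knn_window(sites: list[ResidueSite], focal: ResidueSite, k: int) -> list[ResidueSite]:
    """The focal residue plus its k−1 spatial nearest neighbours.

    Distance ties break by ascending (chain_id, residue_number).  Returns
    min(k, len(sites)) sites; the focal site is always included.
    """
    if k < 1:
        raise ValueError(f"window size k must be >= 1, got {k}")
    if focal.key not in {s.key for s in sites}:
        raise ValueError(f"focal residue {focal.key} not among sites")
    coords = np.asarray([s.coord for s in sites])
    d = np.linalg.norm(coords - np.asarray(focal.coord), axis=1)
    # focal first (distance 0), then distance, then (chain, resnum)
    keyed = sorted(range(len(sites)), key=lambda i: (d[i], sites[i].chain_id, sites[i].residue_number))
    return [sites[i] for i in keyed[: min(k, len(sites))]]


_NEG = float("-inf")


def _load_blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def align_proteins(
    seq_a: str,
    seq_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Global Needleman–Wunsch alignment under BLOSUM62 with affine gaps.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``.  Traceback
    ties prefer diagonal, then up (gap in seq_b), then left, which makes
    the reported alignment deterministic.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    matrix = _load_blosum62()
    alphabet = set(matrix.alphabet)
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        for i, ch in enumerate(seq):
            if ch not in alphabet:
                raise ValueError(f"{name}: unknown residue {ch!r} at position {i + 1}")

    n, m = len(seq_a), len(seq_b)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in seq_b (consume seq_a; "up")
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in seq_a ("left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)

    for i in range(1, n + 1):
        sa = seq_a[i - 1]
        for j in range(1, m + 1):
            s = matrix[sa, seq_b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - gap_open)

    score = max(M[n, m], Ix[n, m], Iy[n, m])
    # traceback; preference order: M (diagonal), Ix (up), Iy (left)
    if M[n, m] == score:
        state = "M"
    elif Ix[n, m] == score:
        state = "X"
    else:
        state = "Y"
    i, j = n, m
    pairs: list[tuple[int, int]] = []
    matches = 0
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i, j))
            if seq_a[i - 1] == seq_b[j - 1]:
                matches += 1
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            target = M[i, j] - s
            if M[i - 1, j - 1] == target:
                state = "M"
            elif Ix[i - 1, j - 1] == target:
                state = "X"
            else:
                state = "Y"
            i -= 1
            j -= 1
        elif state == "X":
            if i > 1 or j > 0:
                if M[i - 1, j] - gap_open == Ix[i, j]:
                    state = "M"
                elif Ix[i - 1, j] - gap_extend == Ix[i, j]:
                    state = "X"
                else:
                    state = "Y"
            i -= 1
        else:
            if j > 1 or i > 0:
                if M[i, j - 1] - gap_open == Iy[i, j]:
                    state = "M"
                elif Iy[i, j - 1] - gap_extend == Iy[i, j]:
                    state = "Y"
                else:
                    state = "X"
            j -= 1
    pairs.reverse()
    identity = matches / len(pairs) if pairs else 0.0
    return PairwiseAlignment(pairs=tuple(pairs), score=float(score), identity=identity)


def map_gene_to_structure(
    gene_seq: str,
    sites_by_chain: dict[str, list[ResidueSite]],
    alignment: PairwiseAlignment | None = None,
    gene_id: str = "",
) -> ResidueAlignmentMap:
    """Map gene protein positions onto resolved structure residues.

    Structure residue numbers are taken to carry the structure gene's
    protein positions (author numbering preserved).  With
    ``alignment=None`` the identity mapping is used: gene position *i*
    matches residue number *i* in every chain.  For a homologous gene,
    pass the gene→structure-sequence alignment; mismatched (substituted)
    columns still map, gap columns do not.  Residues absent from a chain
    (no density) yield no entry for that chain.
    """
    if alignment is None:
        pos_map = {i: i for i in range(1, len(gene_seq) + 1)}
    else:
        pos_map = alignment.mapping()

    entries: list[tuple[int, str, int]] = []
    mapped_positions: set[int] = set()
    for chain_id, sites in sorted(sites_by_chain.items()):
        resolved = {s.residue_number for s in sites}
        for pos in range(1, len(gene_seq) + 1):
            struct_pos = pos_map.get(pos)
            if struct_pos is not None and struct_pos in resolved:
                entries.append((pos, chain_id, struct_pos))
                mapped_positions.add(pos)
    if not entries:
        raise ValueError("no gene positions could be mapped onto the structure")
    coverage = len(mapped_positions) / len(gene_seq)
    return ResidueAlignmentMap(gene_id=gene_id, entries=entries, coverage=coverage)


def write_bfactor_pdb(
    file_in,
    scores: dict[tuple[str, int], float],
    file_out,
    scale: float = 100.0,
    sentinel: float = 999.0,
) -> None:
    """Rewrite a PDB with per-residue scores in the B-factor column.

    Every atom of a scored residue gets ``score * scale`` (two decimals);
    atoms of unscored residues get the sentinel.  All other bytes of
    every line are preserved exactly.
    """
    for key, value in scores.items():
        field = value * scale
        if not (-999.995 <= field <= 9999.995):
            raise ValueError(f"score {value} for {key} does not fit the B-factor field")
    with open(file_in) as fin, open(file_out, "w") as fout:
        for line in fin:
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) >= 66:
                chain = line[21]
                resnum = int(line[22:26])
                value = scores.get((chain, resnum))
                b = sentinel if value is None else value * scale
                line = line[:60] + f"{b:6.2f}" + line[66:]
            fout.write(line)
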