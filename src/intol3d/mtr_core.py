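"""Codon-level variant accounting and the missense tolerance ratio (MTR).

The MTR over a residue set is the observed missense fraction divided by
the expected missense fraction, where the expectation enumerates every
single-nucleotide substitution of each codon under the standard genetic
code.  Stop-gaining substitutions are excluded from both classes; an
undefined score propagates as ``None`` (never 0 — zero means complete
missense depletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GENETIC_CODE",
    "TranscriptCDS",
    "CodonVariantCounts",
    "MTRScore",
    "enumerate_codon_expectations",
    "load_observed_counts",
    "mtr_over_set",
    "read_cds_fasta",
]

# Standard genetic code (NCBI table 1); '*' marks stop codons.
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_BASES = "ACGT"
_STOPS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


@dataclass(frozen=True)
class TranscriptCDS:
    """A protein-coding sequence in frame.

    ``protein_length`` excludes a terminal stop codon if one is present.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(seq)} is not a positive multiple of 3"
            )
        for i, base in enumerate(seq):
            if base not in _BASES:
                raise ValueError(
                    f"{self.gene_id}: invalid base {base!r} at position {i + 1}"
                )

    @property
    def codons(self) -> list[str]:
        """Coding codons, terminal stop stripped."""
        seq = self.sequence
        cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if cods and cods[-1] in _STOPS:
            cods = cods[:-1]
        return cods

    @property
    def protein_length(self) -> int:
        return len(self.codons)


@dataclass
class CodonVariantCounts:
    """Observed and expected missense/synonymous tallies for one codon.

    ``exp_*`` counts are fully determined by the codon under the standard
    code; ``weight`` is a mutation-rate hook, present but unused (always 1).
    """

    gene_id: str
    codon_index: int  # 1-based protein position
    obs_missense: int = 0
    obs_synonymous: int = 0
    exp_missense: int = 0
    exp_synonymous: int = 0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise ValueError(f"codon_index must be 1-based positive, got {self.codon_index}")
        for name in ("obs_missense", "obs_synonymous", "exp_missense", "exp_synonymous"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exp_missense + self.exp_synonymous > 9:
            raise ValueError("exp_missense + exp_synonymous cannot exceed 9")


@dataclass(frozen=True)
class MTRScore:
    """MTR over a residue set; ``value`` is None when undefined."""

    value: float | None
    n_obs: int
    n_residues: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def classify_substitution(codon: str, pos: int, alt: str) -> str:
    """Classify a single-nucleotide codon change.

    Returns one of ``"synonymous"``, ``"missense"``, ``"stop_gained"``.
    Stop-lost changes (source codon is a stop) count as missense.
    """
    mutant = codon[:pos] + alt + codon[pos + 1 :]
    aa_ref = GENETIC_CODE[codon]
    aa_alt = GENETIC_CODE[mutant]
    if aa_alt == "*":
        return "stop_gained"
    if aa_alt == aa_ref:
        return "synonymous"
    return "missense"


def enumerate_codon_expectations(cds: TranscriptCDS) -> list[CodonVariantCounts]:
    """Expected missense/synonymous counts per codon, observations zeroed.

    All 9 single-nucleotide substitutions of each coding codon are
    classified; stop-gained changes are excluded from both classes.
    """
    out: list[CodonVariantCounts] = []
    for idx, codon in enumerate(cds.codons, start=1):
        n_mis = 0
        n_syn = 0
        for pos in range(3):
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                kind = classify_substitution(codon, pos, alt)
                if kind == "missense":
                    n_mis += 1
                elif kind == "synonymous":
                    n_syn += 1
        out.append(
            CodonVariantCounts(
                gene_id=cds.gene_id,
                codon_index=idx,
                exp_missense=n_mis,
                exp_synonymous=n_syn,
            )
        )
    return out


def load_observed_counts(path_or_frame, cds: TranscriptCDS) -> list[CodonVariantCounts]:
    """Merge an observed-count table onto the expectation skeleton.

    The table is TSV (or an equivalent DataFrame) with columns
    ``gene_id codon_index obs_missense obs_synonymous``.  Codons absent
    from the table keep zero observations.  Duplicate codon rows and
    out-of-range indices are rejected rather than silently combined.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        table = path_or_frame
    else:
        table = pd.read_csv(path_or_frame, sep="\t")
    required = {"gene_id", "codon_index", "obs_missense", "obs_synonymous"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")

    counts = enumerate_codon_expectations(cds)
    table = table[table["gene_id"] == cds.gene_id]
    if table["codon_index"].duplicated().any():
        dups = sorted(table.loc[table["codon_index"].duplicated(), "codon_index"].unique())
        raise ValueError(f"duplicate codon rows for {cds.gene_id}: {dups}")
    by_index = {c.codon_index: c for c in counts}
    for row in table.itertuples(index=False):
        idx = int(row.codon_index)
        if idx not in by_index:
            raise ValueError(
                f"codon_index {idx} out of range 1..{cds.protein_length} for {cds.gene_id}"
            )
        rec = by_index[idx]
        rec.obs_missense = int(row.obs_missense)
        rec.obs_synonymous = int(row.obs_synonymous)
        if rec.obs_missense < 0 or rec.obs_synonymous < 0:
            raise ValueError(f"negative observation count at codon {idx}")
    return counts


def mtr_over_set(counts: Sequence[CodonVariantCounts] | Iterable[CodonVariantCounts]) -> MTRScore:
    """MTR over an arbitrary residue set.

    MTR = [Σobs_mis / (Σobs_mis + Σobs_syn)] / [Σexp_mis / (Σexp_mis + Σexp_syn)].
    Undefined (value None) when no variants are observed or the expected
    missense proportion is zero.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("mtr_over_set requires a nonempty residue set")
    obs_mis = sum(c.obs_missense for c in counts)
    obs_syn = sum(c.obs_synonymous for c in counts)
    exp_mis = sum(c.exp_missense * c.weight for c in counts)
    exp_syn = sum(c.exp_synonymous * c.weight for c in counts)
    n_obs = obs_mis + obs_syn
    n_res = len(counts)
    if n_obs == 0 or exp_mis == 0 or (exp_mis + exp_syn) == 0:
        return MTRScore(value=None, n_obs=n_obs, n_residues=n_res)
    obs_prop = obs_mis / n_obs
    exp_prop = exp_mis / (exp_mis + exp_syn)
    return MTRScore(value=obs_prop / exp_prop, n_obs=n_obs, n_residues=n_res)


def read_cds_fasta(path, gene_id: str | None = None) -> TranscriptCDS:
    """Read a single-record FASTA as a CDS; record id becomes gene_id."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if gene_id is not None:
        matches = [r for r in records if r.id == gene_id]
        if not matches:
            raise ValueError(f"gene {gene_id!r} not found in {path}")
        rec = matches[0]
    else:
        if len(records) > 1:
            raise ValueError(f"{path} has {len(records)} records; pass gene_id")
        rec = records[0]
    return TranscriptCDS(gene_id=rec.id, sequence=str(rec.seq))
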