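# intol3d

Structure-aware regional missense-intolerance scoring plus quantification of
variant ion-channel electrophysiology and biophysics, in one tested pipeline
that runs entirely on synthetic inputs (no downloads).

Two pillars:

1. **3D missense tolerance ratio (MTR).** Per-codon expected
   missense/synonymous substitution counts under the standard genetic code,
   observed-count ingestion, and an MTR computed over the *k* residues
   nearest in space on a protein structure (rather than adjacent in
   sequence). Includes cross-gene projection through a global protein
   alignment, averaging of scores across identical chains, intra-complex
   scoring over pooled multi-protein site clouds, and blue-white-red
   coloring written into PDB B-factors.
2. **Variant pharmacology & biophysics.** NMDG⁺-substitution difference
   currents, percent-of-maximum drug effects, activation/inhibition Hill
   fits in log-concentration space (EC50/IC50, Hill slope, constrained
   residual minimum), potency ratios, ANOVA + Dunnett / Welch-Bonferroni
   group comparisons of log midpoints, reporter-assay kinetic slopes and
   surface/total expression ratios, and bead-contact adhesion frequencies
   with Wilson intervals and Tukey comparisons.

## Layout

| Module | Role |
| --- | --- |
| `intol3d.mtr_core` | codon expectation enumeration, observed counts, MTR statistic |
| `intol3d.structure3d` | PDB parsing, k-nearest residue windows, global alignment, gene↔structure mapping, B-factor writer |
| `intol3d.mtr3d` | per-residue 3D MTR tracks, chain averaging, complex scoring, color scales |
| `intol3d.pharmacology` | difference currents, Hill fits, potency ratios, log-potency statistics |
| `intol3d.assay_quant` | plate-kinetics slopes, surface/total ratios, adhesion frequency, Tukey report |
| `intol3d.synthetic_data` | deterministic generators for every input format above |

## CLI

```sh
# generate synthetic inputs for any stage
intol3d simulate mtr --seed 3 --out data/

# score a gene on a structure (k = focal + 30 nearest)
intol3d score --cds data/cds.fasta --counts data/counts.tsv \
    --structure data/structure.pdb --k 31 --out run

# color the structure by the averaged track (B-factor PDB + RGB sidecar)
intol3d color --track run.track.tsv --structure data/structure.pdb --out run

# intra-complex scoring from a key-value config
intol3d complex --spec complex.cfg --out run

# Hill fits + group comparison
intol3d fit --curves curves.csv --refs refs.csv --model inhibition \
    --control A654T --out fits

# assay quantification
intol3d assay --plate plate.csv --out expression.tsv
intol3d adhesion --events adhesion.csv --out pa.tsv
```

File dialects: CDS as single-record FASTA; variant counts as TSV
(`gene_id codon_index obs_missense obs_synonymous`); structures as PDB
(ATOM records, first model, occupancy-major altlocs); recordings as CSV
(`cell_id,construct,compound,concentration_M,current_nA` plus a reference
CSV `cell_id,I_baseline_nA,I_NMDG_nA`); plate kinetics and adhesion logs
as CSV (see `intol3d simulate`).

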