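"""Sequence-engineering utilities for candidate enzyme triage.

Covers the sequence side of the engineering workflow: pairwise identity
matrices for candidate diversity assessment, consensus construction from a
multiple alignment, liability-motif scanning and substitution (e.g. the
integrin-binding Arg-Gly-Asp tripeptide), C-terminal truncation, and the
standard protein calculators (average mass, 280 nm extinction coefficient
per Gill & von Hippel).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

__all__ = [
    "ProteinSequence",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "global_identity",
    "identity_matrix",
    "build_consensus",
    "scan_motif",
    "scan_and_replace_motif",
    "truncate_cterm",
    "average_mass",
    "extinction_coefficient",
]


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty protein sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residue letters in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_fasta(path) -> list[ProteinSequence]:
    return [ProteinSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_aligned_fasta(path) -> Alignment:
    recs = list(SeqIO.parse(str(path), "fasta"))
    return Alignment(tuple(r.id for r in recs), tuple(str(r.seq).upper() for r in recs))


def write_fasta(sequences: list[ProteinSequence], path=None) -> str:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")  # 60-column wrapped
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    Identity = identical aligned columns / total alignment length (gap
    columns included) x 100, rounded to one decimal.  The denominator
    convention matters: published identity tables produced with other
    programs can differ by a few percentage points.
    """
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignment = next(iter(aligner.align(a.residues, b.residues)))
    s1, s2 = str(alignment[0]), str(alignment[1])
    identical = sum(1 for x, y in zip(s1, s2) if x == y and x != GAP)
    return round(100.0 * identical / len(s1), 1)


def identity_matrix(sequences: list[ProteinSequence], **kwargs):
    """Symmetric pairwise identity matrix (DataFrame), diagonal 100.0."""
    import pandas as pd

    ids = [s.id for s in sequences]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            v = global_identity(sequences[i], sequences[j], **kwargs)
            mat.iat[i, j] = mat.iat[j, i] = v
    return mat


def build_consensus(alignment: Alignment, seq_id: str = "consensus") -> ProteinSequence:
    """Majority-rule consensus: per column the most frequent non-gap residue.

    Columns where gaps are the strict majority are dropped.  Frequency ties
    between residues resolve to the alphabetically earlier residue — an
    arbitrary but fixed rule, recorded here so outputs are reproducible.
    """
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 aligned rows")
    out = []
    n_rows = len(alignment.rows)
    for col in range(alignment.n_columns):
        column = [row[col] for row in alignment.rows]
        n_gaps = column.count(GAP)
        if n_gaps * 2 > n_rows:
            continue
        counts: dict[str, int] = {}
        for ch in column:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        best = min(counts, key=lambda ch: (-counts[ch], ch))
        out.append(best)
    if not out:
        raise ValueError("consensus is empty (all-gap alignment)")
    return ProteinSequence(seq_id, "".join(out))


def scan_motif(seq: ProteinSequence, motif: str = "RGD") -> list[int]:
    """All 1-based start positions of ``motif`` (overlaps included)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    positions = []
    start = 0
    while True:
        idx = seq.residues.find(motif, start)
        if idx == -1:
            break
        positions.append(idx + 1)
        start = idx + 1
    return positions


def scan_and_replace_motif(
    seq: ProteinSequence,
    motif: str = "RGD",
    replacement_pos: int = 0,
    new_residue: str = "S",
    occurrence: int | None = None,
) -> tuple[list[int], ProteinSequence]:
    """Find a liability motif and point-substitute within each occurrence.

    ``replacement_pos`` is the 0-based offset within the motif; by default
    every occurrence is edited (``occurrence`` selects a single 1-based one).
    Length is always preserved.  If the motif is absent the sequence is
    returned unchanged with a warning.
    """
    import warnings

    if not (0 <= replacement_pos < len(motif)):
        raise ValueError("replacement_pos outside motif")
    positions = scan_motif(seq, motif)
    if not positions:
        warnings.warn(f"motif {motif!r} not found in {seq.id!r}; sequence unchanged", stacklevel=2)
        return [], seq
    targets = positions if occurrence is None else [positions[occurrence - 1]]
    residues = list(seq.residues)
    for start in targets:
        residues[start - 1 + replacement_pos] = new_residue
    return positions, ProteinSequence(seq.id, "".join(residues))


def truncate_cterm(seq: ProteinSequence, peptide: str) -> ProteinSequence:
    """Remove an exact C-terminal peptide; no fuzzy matching."""
    if peptide == "":
        return seq
    if not seq.residues.endswith(peptide):
        raise ValueError(f"{peptide!r} is not a C-terminal suffix of {seq.id!r}")
    if len(peptide) >= len(seq.residues):
        raise ValueError("truncation would remove the entire sequence")
    return ProteinSequence(seq.id, seq.residues[: -len(peptide)])


def average_mass(seq: ProteinSequence) -> float:
    """Average (isotope-weighted) molecular mass in kDa.

    Standard average residue masses plus one water; unrounded — round to two
    decimals for tabular display, as mass tables conventionally do.
    """
    da = molecular_weight(seq.residues, seq_type="protein", monoisotopic=False)
    return da / 1000.0


def extinction_coefficient(seq: ProteinSequence, cystines: int = 0) -> int:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1).

    Gill & von Hippel composition rule: 5500 per Trp, 1490 per Tyr, 125 per
    disulfide-bonded cystine pair.  ``cystines`` counts pairs and cannot
    exceed floor(nCys / 2).
    """
    n_trp = seq.residues.count("W")
    n_tyr = seq.residues.count("Y")
    n_cys = seq.residues.count("C")
    if cystines < 0 or cystines > n_cys // 2:
        raise ValueError(f"cystine count {cystines} invalid for {n_cys} cysteines")
    return 5500 * n_trp + 1490 * n_tyr + 125 * cystines
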