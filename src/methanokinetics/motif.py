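"""MCR alpha-subunit motif scanning with reference-based residue numbering.

Methyl-coenzyme M reductase (MCR) is the terminal enzyme of methanogenesis.
Residues 444-446 of its alpha subunit — Tyr-Gly-Tyr in the reference
numbering of *Methanothermobacter marburgensis* — sit at the substrate
channel, and Tyr->Phe substitutions at positions 444 and 446 mark distinct
methanogen lineages (alpha-444 Phe in Class II methanogens, alpha-446 Phe
predominately in Methanosarcinaceae).  Given a multiple protein alignment
that contains the reference sequence, this module maps reference residue
numbers to alignment columns and classifies every sequence's motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

__all__ = [
    "Alignment",
    "MotifRecord",
    "MotifReport",
    "read_alignment",
    "map_reference_positions",
    "classify_motifs",
    "MOTIF_POSITIONS",
]

GAP = "-"
#: Reference residue numbers of the Tyr-Gly-Tyr motif (1-based).
MOTIF_POSITIONS = (444, 445, 446)
_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass
class Alignment:
    """Gapped protein multiple alignment with a designated reference sequence."""

    records: list[tuple[str, str]]  # (id, gapped sequence)
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no sequences")
        width = len(self.records[0][1])
        ids = set()
        for seq_id, seq in self.records:
            if len(seq) != width:
                raise ValueError(f"sequence {seq_id!r} length {len(seq)} != alignment width {width}")
            bad = set(seq.upper()) - _AA - {GAP}
            if bad:
                raise ValueError(f"sequence {seq_id!r} contains non-amino-acid characters {bad}")
            ids.add(seq_id)
        if self.reference_id not in ids:
            raise ValueError(f"reference {self.reference_id!r} not present in the alignment")

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def reference_seq(self) -> str:
        return next(seq for seq_id, seq in self.records if seq_id == self.reference_id)


@dataclass(frozen=True)
class MotifRecord:
    """Residues of one sequence at the reference motif positions."""

    seq_id: str
    residue_444: str
    residue_445: str
    residue_446: str
    motif: str
    label: str  # YGY | FGY | YGF | FGF | other/gapped


@dataclass
class MotifReport:
    records: list[MotifRecord]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.label] = out.get(rec.label, 0) + 1
        return out


def read_alignment(path: str | Path, reference_id: str) -> Alignment:
    """Load an aligned FASTA file (all records equal length)."""
    aln = AlignIO.read(str(path), "fasta")
    return Alignment([(rec.id, str(rec.seq)) for rec in aln], reference_id)


def map_reference_positions(aln: Alignment) -> dict[int, int]:
    """Map reference residue numbers (1-based) to alignment columns (0-based).

    The k-th non-gap character of the reference sequence defines residue k.
    """
    mapping: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(aln.reference_seq):
        if ch != GAP:
            residue += 1
            mapping[residue] = col
    if residue < MOTIF_POSITIONS[-1]:
        raise ValueError(
            f"reference {aln.reference_id!r} has only {residue} residues; "
            f"needs at least {MOTIF_POSITIONS[-1]} to anchor the motif"
        )
    return mapping


_CLASSES = {"YGY", "FGY", "YGF", "FGF"}


def classify_motifs(aln: Alignment) -> MotifReport:
    """Extract and classify the alpha-444..446 motif for every sequence.

    Comparison is case-insensitive; any gap, unknown residue ('X') or
    combination outside {Y,F} x {G} x {Y,F} is reported as 'other/gapped'
    (degenerate residues are reported, never rejected).
    """
    mapping = map_reference_positions(aln)
    cols = [mapping[p] for p in MOTIF_POSITIONS]
    records = []
    for seq_id, seq in aln.records:
        residues = tuple(seq[c].upper() for c in cols)
        motif = "".join(residues)
        label = motif if motif in _CLASSES else "other/gapped"
        records.append(MotifRecord(seq_id, *residues, motif=motif, label=label))
    return MotifReport(records)
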