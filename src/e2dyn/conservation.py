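"""Phospho-site / acidic-loop co-conservation scan.

Works on externally produced multiple sequence alignments (FASTA or
Clustal).  For each E2 family alignment it reports the conservation degree
of S/T at the columns mapped from the reference phospho-sites (Psite-1 =
Cdc34 S130, Psite-2 = S167), of D/E at the mapped CK2 acidic-consensus
positions (DE1/DE2), and whether the family carries the β4α2 acidic
insertion (a long reference-only run of columns against an insertion-free
comparator).

Global pairwise identity (Needleman–Wunsch, BLOSUM62, affine gaps, free
terminal gaps) is provided for homolog sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO, AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AlignmentSet",
    "ConservationReport",
    "read_alignment",
    "write_alignment_fasta",
    "map_reference_position",
    "conservation_degree",
    "detect_insertion",
    "ck2_consensus_match",
    "pairwise_identity",
    "family_report",
]

GAP = "-"
ACIDIC = frozenset("DE")
PHOSPHO = frozenset("ST")


@dataclass
class AlignmentSet:
    """One family's multiple sequence alignment with a named reference row."""

    family_id: str
    sequences: dict[str, str]
    reference_id: str

    def __post_init__(self) -> None:
        if self.reference_id not in self.sequences:
            raise ValueError(f"reference {self.reference_id!r} missing from alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            for sid, s in self.sequences.items():
                if len(s) != len(self.sequences[self.reference_id]):
                    raise ValueError(f"sequence {sid!r} has a different aligned length")
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[self.reference_id])

    @property
    def reference(self) -> str:
        return self.sequences[self.reference_id]


@dataclass
class ConservationReport:
    """Per-family conservation summary (percentages in [0, 100])."""

    family_id: str
    psite1_ST_pct: float
    psite2_ST_pct: float
    de1_acidic_pct: float
    de2_acidic_pct: float
    insertion_present: bool
    insertion_length: int
    flags: list[str] = field(default_factory=list)


def read_alignment(path, format: str = "fasta", family_id: str = "", reference_id: str | None = None) -> AlignmentSet:
    """Read a FASTA or Clustal alignment; ragged FASTA rows are rejected
    naming the offending sequence.  The reference defaults to the first row."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) < 2:
            raise ValueError(f"{path}: need at least 2 sequences")
        length = len(records[0].seq)
        for rec in records[1:]:
            if len(rec.seq) != length:
                raise ValueError(
                    f"{path}: sequence {rec.id!r} has length {len(rec.seq)}, expected {length}"
                )
    else:
        records = list(AlignIO.read(str(path), "clustal"))
    sequences = {rec.id: str(rec.seq).upper() for rec in records}
    if reference_id is None:
        reference_id = records[0].id
    return AlignmentSet(family_id=family_id or str(path), sequences=sequences, reference_id=reference_id)


def write_alignment_fasta(aln: AlignmentSet, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def map_reference_position(
    aln: AlignmentSet, ref_position: int, ref_numbering_start: int = 1
) -> int:
    """1-based alignment column corresponding to a reference residue number.

    Counts non-gap reference characters: the returned column is the one at
    which that count equals ``ref_position − ref_numbering_start + 1``.
    """
    target = ref_position - ref_numbering_start + 1
    if target < 1:
        raise ValueError(f"position {ref_position} precedes numbering start {ref_numbering_start}")
    count = 0
    for col, ch in enumerate(aln.reference, start=1):
        if ch != GAP:
            count += 1
            if count == target:
                return col
    raise ValueError(
        f"position {ref_position} beyond the reference's ungapped length ({count})"
    )


def conservation_degree(aln: AlignmentSet, column: int, residue_class) -> tuple[float, bool]:
    """Percent of sequences whose character at a 1-based column belongs to
    ``residue_class``, among sequences with a non-gap there.

    Returns (percentage, gap_only_flag); a gap-only column reports 0%.
    """
    if not (1 <= column <= aln.n_columns):
        raise ValueError(f"column {column} outside alignment of width {aln.n_columns}")
    residue_class = set(residue_class)
    chars = [seq[column - 1] for seq in aln.sequences.values()]
    non_gap = [c for c in chars if c != GAP]
    if not non_gap:
        return 0.0, True
    hits = sum(c in residue_class for c in non_gap)
    return 100.0 * hits / len(non_gap), False


def detect_insertion(
    aln: AlignmentSet,
    comparator_id: str,
    window: tuple[int, int] | None = None,
    min_len: int = 8,
) -> tuple[bool, int]:
    """Longest run of columns where the reference has residues and the
    comparator has gaps, within a 1-based column window.

    ``present`` requires the run to reach ``min_len`` columns (default 8,
    below the canonical 12/13-residue acidic insertion).
    """
    if comparator_id not in aln.sequences:
        raise ValueError(f"comparator {comparator_id!r} missing from alignment")
    ref = aln.reference
    comp = aln.sequences[comparator_id]
    lo, hi = window if window is not None else (1, aln.n_columns)
    if not (1 <= lo <= hi <= aln.n_columns):
        raise ValueError(f"window {window} outside alignment of width {aln.n_columns}")
    best = run = 0
    for col in range(lo - 1, hi):
        if ref[col] != GAP and comp[col] == GAP:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best >= min_len, best


def ck2_consensus_match(
    sequence: str,
    center: int,
    acidic_min: int = 2,
) -> tuple[bool, str]:
    """Does an S/T at ``center`` (0-based) sit in a CK2-like acidic context?

    True when an acidic residue (D/E) occupies position +3, or at least
    ``acidic_min`` of positions {+1, +2, +3} are acidic (the canonical
    S/T-x-x-D/E motif with an acidic-context relaxation).  Returns the
    matched pattern description.
    """
    if center < 0 or center >= len(sequence):
        raise ValueError("center outside sequence")
    if sequence[center] not in PHOSPHO:
        raise ValueError(f"center residue {sequence[center]!r} is not S/T")
    context = sequence[center + 1 : center + 4]
    if len(context) >= 3 and context[2] in ACIDIC:
        return True, "S/T-x-x-D/E"
    acidic_count = sum(c in ACIDIC for c in context)
    if acidic_count >= acidic_min:
        return True, f"{acidic_count} acidic residues in +1..+3"
    return False, ""


def _trim_terminal_gaps(a: str, b: str) -> tuple[str, str]:
    start, end = 0, len(a)
    while start < end and (a[start] == GAP or b[start] == GAP):
        start += 1
    while end > start and (a[end - 1] == GAP or b[end - 1] == GAP):
        end -= 1
    return a[start:end], b[start:end]


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> float:
    """Percent identity from a global alignment.

    Needleman–Wunsch with the named substitution matrix and affine gap
    penalties, terminal gaps free; identity = 100 × identical columns /
    aligned columns excluding terminal gaps.  The pair is canonicalised
    (lexicographic order) before aligning so that tie-breaking among
    co-optimal alignments cannot make the result asymmetric.
    """
    seq_a, seq_b = seq_a.replace(GAP, ""), seq_b.replace(GAP, "")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    alignment = aligner.align(seq_a, seq_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    a, b = _trim_terminal_gaps(a, b)
    if not a:
        return 0.0
    identical = sum(x == y and x != GAP for x, y in zip(a, b))
    return 100.0 * identical / len(a)


def family_report(
    aln: AlignmentSet,
    psite1: int,
    psite2: int,
    de1: int,
    de2: int,
    ref_numbering_start: int = 1,
    comparator_id: str | None = None,
    insertion_window: tuple[int, int] | None = None,
) -> ConservationReport:
    """Full conservation report for one family alignment.

    Psite/DE positions are reference residue numbers; DE positions are
    supplied by the caller (they are configuration, not hard-coded).  The
    insertion scan runs only when a comparator row is named.
    """
    flags: list[str] = []
    out = {}
    for key, pos, cls in (
        ("psite1_ST_pct", psite1, PHOSPHO),
        ("psite2_ST_pct", psite2, PHOSPHO),
        ("de1_acidic_pct", de1, ACIDIC),
        ("de2_acidic_pct", de2, ACIDIC),
    ):
        col = map_reference_position(aln, pos, ref_numbering_start)
        pct, gap_only = conservation_degree(aln, col, cls)
        if gap_only:
            flags.append(f"{key}: gap-only column {col}")
        out[key] = pct
    present, length = (False, 0)
    if comparator_id is not None:
        present, length = detect_insertion(aln, comparator_id, insertion_window)
    return ConservationReport(
        family_id=aln.family_id,
        insertion_present=present,
        insertion_length=length,
        flags=flags,
        **out,
    )
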