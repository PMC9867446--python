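"""Global pairwise alignment for identity scoring and anchor-column mapping.

Defaults are EMBOSS-needle-like: BLOSUM62, gap open 10, gap extend 0.5,
terminal gaps free. A gap run of length L costs ``open + (L-1)*extend``.
Identity values from different programs vary by a couple of percentage
points; callers should treat them as tolerance-based, not exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseAlignment:
    """An affine-gap global alignment with a per-column position map.

    ``column_map`` holds, per alignment column, the pair of 1-based sequence
    positions (``None`` on the gapped side).
    """

    aligned_a: str
    aligned_b: str
    score: float
    column_map: tuple[tuple[int | None, int | None], ...]

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("gapped strings differ in length")

    @property
    def identity_pct(self) -> float:
        return percent_identity(self)

    def map_a_to_b(self, a_pos: int) -> int | None:
        """Query position aligned to 1-based position ``a_pos`` of sequence a."""
        for pa, pb in self.column_map:
            if pa == a_pos:
                return pb
        raise AlignmentError(f"position {a_pos} beyond sequence a")


def _as_str(seq: ProteinRecord | str) -> str:
    return seq.sequence if isinstance(seq, ProteinRecord) else seq


@lru_cache(maxsize=8)
def _matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise AlignmentError(f"unknown substitution matrix {name!r}") from exc


def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _matrix(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if mode == "global":
        aligner.end_gap_score = 0.0  # terminal gaps are free, needle-style
    return aligner


def _check_alphabet(s: str, matrix_name: str) -> None:
    alphabet = set(str(a) for a in _matrix(matrix_name).alphabet)
    for i, ch in enumerate(s, start=1):
        if ch not in alphabet:
            raise AlignmentError(
                f"residue {ch!r} at position {i} absent from matrix {matrix_name}"
            )


def _build(a: str, b: str, aln) -> PairwiseAlignment:
    ga, gb = str(aln[0]), str(aln[1])
    column_map = []
    pa = pb = 0
    for ca, cb in zip(ga, gb):
        xa = xb = None
        if ca != "-":
            pa += 1
            xa = pa
        if cb != "-":
            pb += 1
            xb = pb
        column_map.append((xa, xb))
    assert pa == len(a) and pb == len(b)
    return PairwiseAlignment(
        aligned_a=ga, aligned_b=gb, score=float(aln.score), column_map=tuple(column_map)
    )


def global_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment (terminal gaps free).

    Tie-breaking is deterministic: the first optimal alignment in the
    aligner's canonical enumeration order is returned.
    """
    sa, sb = _as_str(a), _as_str(b)
    if not sa or not sb:
        raise AlignmentError("cannot align empty sequences")
    _check_alphabet(sa, matrix)
    _check_alphabet(sb, matrix)
    aligner = _aligner(matrix, gap_open, gap_extend, "global")
    return _build(sa, sb, aligner.align(sa, sb)[0])


def local_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Best local (Smith-Waterman) alignment; used for CBS-domain placement."""
    sa, sb = _as_str(a), _as_str(b)
    if not sa or not sb:
        raise AlignmentError("cannot align empty sequences")
    _check_alphabet(sa, matrix)
    _check_alphabet(sb, matrix)
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # local alignments cover subranges; recover absolute coordinates
    (a_blocks, b_blocks) = aln.aligned
    a_off = int(a_blocks[0][0]) if len(a_blocks) else 0
    b_off = int(b_blocks[0][0]) if len(b_blocks) else 0
    column_map = []
    pa, pb = a_off, b_off
    for ca, cb in zip(ga, gb):
        xa = xb = None
        if ca != "-":
            pa += 1
            xa = pa
        if cb != "-":
            pb += 1
            xb = pb
        column_map.append((xa, xb))
    return PairwiseAlignment(
        aligned_a=ga, aligned_b=gb, score=float(aln.score), column_map=tuple(column_map)
    )


def percent_identity(aln: PairwiseAlignment, mode: str = "aligned") -> float:
    """Identity percentage of an alignment.

    Modes: ``aligned`` (default) — denominator is the columns between the
    first and last column where both sequences have a residue, i.e. terminal
    overhangs are excluded; ``all`` — every column; ``shorter`` — length of
    the shorter input.
    """
    ga, gb = aln.aligned_a, aln.aligned_b
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    if mode == "aligned":
        both = [i for i, (x, y) in enumerate(zip(ga, gb)) if x != "-" and y != "-"]
        if not both:
            return 0.0
        denom = both[-1] - both[0] + 1
    elif mode == "all":
        denom = len(ga)
    elif mode == "shorter":
        denom = min(
            sum(1 for c in ga if c != "-"), sum(1 for c in gb if c != "-")
        )
    else:
        raise AlignmentError(f"unknown identity mode {mode!r}")
    return 100.0 * matches / denom if denom else 0.0
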