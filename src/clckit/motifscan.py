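"""Degenerate motif scanning: conserved CLC motifs and cytosolic sorting signals.

Pattern language (one token per alignment column):

* an upper-case residue letter — fixed position;
* ``x`` — any of the 20 standard residues (never ``X``, the unknown residue);
* ``Φ`` (or the ASCII alias ``@``) — bulky hydrophobic class, by default
  ``{L, I, M, F, V}``;
* ``[...]`` — an explicit residue class.

All overlapping matches are reported, left to right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .seqio import AMINO_ACIDS, ProteinRecord

DEFAULT_HYDROPHOBIC = frozenset("LIMFV")
_STANDARD = frozenset(AMINO_ACIDS)


class MotifError(ValueError):
    pass


def _parse_pattern(pattern: str, hydrophobic: frozenset[str]) -> tuple[frozenset[str], ...]:
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "x":
            positions.append(_STANDARD)
            i += 1
        elif ch in ("Φ", "@"):
            positions.append(hydrophobic)
            i += 1
        elif ch == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise MotifError(f"unclosed class in pattern {pattern!r}")
            members = pattern[i + 1 : j]
            if not members or any(c not in _STANDARD for c in members):
                raise MotifError(f"bad residue class {members!r} in pattern {pattern!r}")
            positions.append(frozenset(members))
            i = j + 1
        elif ch in _STANDARD:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise MotifError(f"illegal token {ch!r} in pattern {pattern!r}")
    if len(positions) < 4:
        raise MotifError(f"pattern {pattern!r} shorter than 4 positions")
    if not any(len(p) == 1 for p in positions):
        raise MotifError(f"pattern {pattern!r} has no fixed position")
    return tuple(positions)


@dataclass(frozen=True)
class MotifDefinition:
    """A named degenerate motif compiled to per-position residue classes."""

    name: str
    pattern: str
    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC
    _compiled: tuple[frozenset[str], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_compiled", _parse_pattern(self.pattern, self.hydrophobic)
        )

    def __len__(self) -> int:
        return len(self._compiled)

    def matches_at(self, sequence: str, start0: int) -> bool:
        """Window test at 0-based offset ``start0``."""
        if start0 < 0 or start0 + len(self._compiled) > len(sequence):
            return False
        return all(
            sequence[start0 + k] in allowed
            for k, allowed in enumerate(self._compiled)
        )


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 1-based
    matched: str
    region: str = "unassigned"  # N-terminal | C-terminal | internal | unassigned

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


@dataclass(frozen=True)
class SortingSignal:
    kind: str  # tyrosine | dileucine_DXXLL | dileucine_DE_XXXL_LI
    start: int  # 1-based
    matched: str
    terminus: str  # N | C | unassigned


def scan_motif(seq: ProteinRecord, motif: MotifDefinition) -> list[MotifHit]:
    """Report all (possibly overlapping) windows of ``seq`` matching ``motif``."""
    s = seq.sequence
    m = len(motif)
    hits = []
    for i in range(len(s) - m + 1):
        if motif.matches_at(s, i):
            hits.append(
                MotifHit(motif_name=motif.name, start=i + 1, matched=s[i : i + m])
            )
    return hits


def _load_config() -> dict:
    with resources.files("clckit.data").joinpath("motifs.json").open() as fh:
        return json.load(fh)


def default_clc_motifs(hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC) -> list[MotifDefinition]:
    cfg = _load_config()
    return [
        MotifDefinition(name=name, pattern=pat, hydrophobic=hydrophobic)
        for name, pat in cfg["clc_motifs"].items()
    ]


def default_sorting_motifs(hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC) -> list[MotifDefinition]:
    cfg = _load_config()
    return [
        MotifDefinition(name=name, pattern=pat, hydrophobic=hydrophobic)
        for name, pat in cfg["sorting_signals"].items()
    ]


def find_sorting_signals(
    seq: ProteinRecord,
    n_limit: int,
    c_limit: int,
    motifs: list[MotifDefinition] | None = None,
) -> list[SortingSignal]:
    """Locate sorting signals confined to the terminal windows.

    Signals are reported only when the whole match lies within the
    N-terminal window ``[1, n_limit]`` or the C-terminal window
    ``[c_limit, len(seq)]``; anything strictly between the windows is
    presumed intramembrane/lumenal and ignored.
    """
    n = len(seq)
    if not (1 <= n_limit < c_limit <= n):
        raise MotifError(
            f"signal windows out of range: need 1 <= n_limit < c_limit <= {n}, "
            f"got n_limit={n_limit}, c_limit={c_limit}"
        )
    if motifs is None:
        motifs = default_sorting_motifs()
    signals = []
    for motif in motifs:
        for hit in scan_motif(seq, motif):
            if hit.end <= n_limit:
                terminus = "N"
            elif hit.start >= c_limit:
                terminus = "C"
            else:
                continue
            signals.append(
                SortingSignal(
                    kind=motif.name,
                    start=hit.start,
                    matched=hit.matched,
                    terminus=terminus,
                )
            )
    signals.sort(key=lambda s: (s.start, s.kind))
    return signals
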