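"""Synthetic CLC-like sequence generation with planted ground truth.

Every generator is a pure function of its blueprint/seed, so downstream
recovery tests can assert exact coordinates instead of spot-checking.
Generated proteins carry the architecture the analysis stages assume:
conserved motifs at controlled positions, a controlled filter residue,
controlled glutamate presence, optional hydrophobic stretches, terminal
sorting signals and CBS copies over a configurable background composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .motifscan import MotifDefinition, default_clc_motifs, default_sorting_motifs
from .phylo import AA_ORDER, JttModel, PhyloTree, load_jtt
from .seqio import CdsRecord, ProteinRecord


class SynthError(ValueError):
    pass


# planted strings, one canonical instance per pattern
FILTER_NITRATE = "GPGIPE"
FILTER_CHLORIDE = "GSGIPE"
FILTER_DEGENERATE = "SSKSSQ"  # deliberately fails the GxGxPE pattern
MOTIF2 = "GKEGPSVH"  # GKxGPxxH
MOTIF3 = "PTMGVLF"  # PxxGxLF
SIGNAL_SEQS = {
    "tyrosine": "YSTL",
    "dileucine_DXXLL": "DQSLL",
    "dileucine_DE_XXXL_LI": "DEESLL",
}

# synthetic stand-ins for CBS reference segments (60 aa each); the package
# ships no third-party reference sequences, so these double as the test refs
CBS1_REF = ProteinRecord(
    id="CBS1_ref",
    sequence="VPVTDVMTPAPVTLSASERVGRVVDLLKNTGHNAFPVVDDARSGEPLGLILRSQLLVLLE",
)
CBS2_REF = ProteinRecord(
    id="CBS2_ref",
    sequence="MTPIVNTSPYTVVETMSLAKAAILFRQLGLRHLCVVPKTGRLAGIVTRKDLLSEHLDQSA",
)

COMPOSITIONS = {
    # hydrophobic-rich, loosely mimicking integral membrane proteins
    "membrane": {
        "A": 0.09, "C": 0.015, "D": 0.035, "E": 0.04, "F": 0.06, "G": 0.075,
        "H": 0.02, "I": 0.075, "K": 0.04, "L": 0.115, "M": 0.025, "N": 0.035,
        "P": 0.045, "Q": 0.03, "R": 0.04, "S": 0.07, "T": 0.055, "V": 0.08,
        "W": 0.015, "Y": 0.035,
    },
    # polar-only background: never crosses a hydropathy TM threshold
    "polar": {
        "D": 0.12, "E": 0.13, "G": 0.11, "H": 0.05, "K": 0.13, "N": 0.11,
        "Q": 0.11, "R": 0.11, "S": 0.08, "T": 0.07,
    },
}


@dataclass(frozen=True)
class PlantedSignal:
    kind: str  # key of SIGNAL_SEQS
    terminus: str  # N | C
    position: int | None = None  # 1-based; auto-placed when None


@dataclass(frozen=True)
class ClcBlueprint:
    """Recipe for one synthetic CLC-like protein."""

    length: int = 750
    seed: int = 0
    filter_residue2: str | None = "P"  # P | S | "degenerate" | None
    filter_pos: int = 170
    motif2_pos: int | None = 330
    motif3_pos: int | None = 400
    gating_present: bool = True
    gating_pos: int = 220
    proton_present: bool = True
    proton_pos: int = 290
    tm_count: int = 0
    tm_span: int = 21
    signals: tuple[PlantedSignal, ...] = ()
    cbs_copies: int = 0
    background: str = "membrane"
    forbid_spurious: bool = True


@dataclass(frozen=True)
class PlantedFeature:
    feature: str
    start: int  # 1-based inclusive
    end: int
    value: str


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _composition(name: str) -> tuple[np.ndarray, str]:
    if name not in COMPOSITIONS:
        raise SynthError(f"unknown background composition {name!r}")
    comp = COMPOSITIONS[name]
    letters = "".join(sorted(comp))
    probs = np.array([comp[ch] for ch in letters], dtype=float)
    return probs / probs.sum(), letters


def generate_clc_protein(bp: ClcBlueprint) -> tuple[ProteinRecord, list[PlantedFeature]]:
    """Build a protein from a blueprint; returns (record, ground truth).

    With ``forbid_spurious`` the background is locally redrawn until the only
    CLC-motif and sorting-signal matches in the sequence are the planted
    ones, which makes downstream recovery an exact assertion.
    """
    rng = np.random.default_rng(bp.seed)
    n = bp.length
    plants: list[tuple[int, str, str, str]] = []  # (start0, string, feature, value)

    def plant(start: int, text: str, feature: str, value: str) -> None:
        if start < 1 or start + len(text) - 1 > n:
            raise SynthError(f"{feature} at {start} does not fit in length {n}")
        plants.append((start - 1, text, feature, value))

    if bp.filter_residue2 in ("P", "S"):
        text = FILTER_NITRATE if bp.filter_residue2 == "P" else FILTER_CHLORIDE
        plant(bp.filter_pos, text, "selectivity_filter", text)
    elif bp.filter_residue2 == "degenerate":
        plant(bp.filter_pos, FILTER_DEGENERATE, "degenerate_filter", FILTER_DEGENERATE)
    elif bp.filter_residue2 is not None:
        raise SynthError(f"filter_residue2 must be P, S, 'degenerate' or None")
    if bp.motif2_pos is not None:
        plant(bp.motif2_pos, MOTIF2, "clc_motif_2", MOTIF2)
    if bp.motif3_pos is not None:
        plant(bp.motif3_pos, MOTIF3, "clc_motif_3", MOTIF3)

    gate = "E" if bp.gating_present else "A"
    plant(bp.gating_pos, gate, "gating_glutamate", gate)
    proton = "E" if bp.proton_present else "T"
    plant(bp.proton_pos, proton, "proton_glutamate", proton)

    if bp.tm_count:
        taken = sorted((s, s + len(t) - 1) for s, t, _, _ in plants)
        spacing = n // (bp.tm_count + 1)
        if spacing < bp.tm_span + 10:
            raise SynthError(
                f"cannot fit {bp.tm_count} TM stretches of {bp.tm_span} in {n}"
            )
        for k in range(bp.tm_count):
            start = (k + 1) * spacing - bp.tm_span // 2
            stretch = "".join(rng.choice(list("LIVF"), size=bp.tm_span))
            plant(start + 1, stretch, "tm_segment", stretch)

    for sig in bp.signals:
        text = SIGNAL_SEQS.get(sig.kind)
        if text is None:
            raise SynthError(f"unknown sorting-signal kind {sig.kind!r}")
        if sig.position is not None:
            pos = sig.position
        elif sig.terminus == "N":
            pos = 3 + 12 * len([p for p in plants if p[2] == "sorting_signal"])
        else:
            pos = n - len(text) - 2
        plant(pos, text, "sorting_signal", f"{sig.kind}:{sig.terminus}")

    for k in range(bp.cbs_copies):
        ref = (CBS1_REF, CBS2_REF)[k % 2]
        pos = n - (bp.cbs_copies - k) * (len(ref) + 10) + 1
        plant(pos, ref.sequence, f"CBS{k + 1}", ref.id)

    intervals = sorted((s, s + len(t) - 1, f) for s, t, f, _ in plants)
    for (a0, a1, fa), (b0, b1, fb) in zip(intervals, intervals[1:]):
        if _intervals_overlap((a0, a1), (b0, b1)):
            raise SynthError(f"planted features overlap: {fa} and {fb}")

    probs, letters = _composition(bp.background)
    occupied = np.zeros(n, dtype=bool)
    chars = np.empty(n, dtype="<U1")
    for s, t, _, _ in plants:
        chars[s : s + len(t)] = list(t)
        occupied[s : s + len(t)] = True
    free = np.where(~occupied)[0]
    chars[free] = rng.choice(list(letters), size=free.size, p=probs)

    if bp.forbid_spurious:
        motifs = default_clc_motifs() + default_sorting_motifs()
        _scrub_spurious(chars, motifs, plants, rng, letters, probs, occupied)

    sequence = "".join(chars)
    record = ProteinRecord(id=f"synthetic_seed{bp.seed}", sequence=sequence)
    truth = [
        PlantedFeature(feature=f, start=s + 1, end=s + len(t), value=v)
        for s, t, f, v in sorted(plants)
    ]
    return record, truth


def _scrub_spurious(
    chars: np.ndarray,
    motifs: list[MotifDefinition],
    plants: list[tuple[int, str, str, str]],
    rng: np.random.Generator,
    letters: str,
    probs: np.ndarray,
    occupied: np.ndarray,
    max_rounds: int = 500,
) -> None:
    """Redraw free background positions until no unplanted motif hit remains."""
    allowed: set[tuple[str, int]] = set()
    for s, t, _, _ in plants:
        for m in motifs:
            for off in range(len(t) - len(m) + 1):
                if m.matches_at(t, off):
                    allowed.add((m.name, s + off))
    for _ in range(max_rounds):
        text = "".join(chars)
        dirty: set[int] = set()
        for m in motifs:
            for i in range(len(text) - len(m) + 1):
                if m.matches_at(text, i) and (m.name, i) not in allowed:
                    dirty.update(
                        j for j in range(i, i + len(m)) if not occupied[j]
                    )
        if not dirty:
            return
        idx = np.array(sorted(dirty))
        chars[idx] = rng.choice(list(letters), size=idx.size, p=probs)
    raise SynthError("could not scrub spurious motif matches from background")


# ---------------------------------------------------------------------------
# reverse translation


_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    if set(codon) <= set("ACGT"):
        _CODONS_BY_AA.setdefault(aa, []).append(codon)
for codons in _CODONS_BY_AA.values():
    codons.sort()


def reverse_translate(prot: ProteinRecord, seed: int = 0) -> CdsRecord:
    """Pick a uniformly random synonymous codon per residue (no stop appended)."""
    if prot.has_unknown:
        raise SynthError(f"record {prot.id!r}: cannot reverse-translate X residues")
    rng = np.random.default_rng(seed)
    parts = []
    for aa in prot.sequence:
        codons = _CODONS_BY_AA[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    return CdsRecord(id=prot.id, sequence="".join(parts), description=prot.description)


# ---------------------------------------------------------------------------
# evolution along a tree


def simulate_evolution(
    root: ProteinRecord | int,
    tree: PhyloTree,
    model: JttModel | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a sequence along a tree under the JTT model; no indels.

    ``root`` is either a concrete sequence or an integer site count, in which
    case the root is drawn from the model's stationary distribution. Returns
    leaf label -> sequence; all sequences are the same length (trivially
    aligned).
    """
    model = model or load_jtt()
    rng = np.random.default_rng(seed)
    if isinstance(root, ProteinRecord):
        states = np.array([AA_ORDER.index(ch) for ch in root.sequence])
    else:
        states = rng.choice(20, size=int(root), p=model.pi)
    nsites = states.size

    start = max(tree.nodes(), key=lambda n: (len(tree.neighbors(n)), -n))
    sequences: dict[int, np.ndarray] = {start: states}
    out: dict[str, str] = {}
    stack = [(start, None)]
    while stack:
        node, parent = stack.pop()
        if node in tree.labels:
            out[tree.labels[node]] = "".join(AA_ORDER[i] for i in sequences[node])
        for child in sorted(tree.neighbors(node)):
            if child == parent:
                continue
            t = tree.length(node, child)
            if t == 0:
                child_states = sequences[node].copy()
            else:
                p = model.transition_matrix(t)
                cum = np.cumsum(p[sequences[node]], axis=1)
                u = rng.random(nsites)
                child_states = (u[:, np.newaxis] > cum).sum(axis=1)
            sequences[child] = child_states
            stack.append((child, node))
    return out
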