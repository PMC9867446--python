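"""Functional classification of CLC-family proteins.

Evidence from motif scanning, anchor mapping and physicochemistry is turned
into the calls a family table reports: anion specificity from the second
selectivity-filter residue (P -> nitrate, S -> chloride), transport mechanism
from the two conserved glutamates (both -> anion/H+ antiporter, exactly one
-> channel, called with low confidence), plus CBS-domain placement, sorting
signals and a best-homolog identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import motifscan, physchem
from .align import global_align, local_align, percent_identity
from .motifscan import MotifDefinition, SortingSignal
from .seqio import ProteinRecord, read_protein_fasta


class ClassifyError(ValueError):
    pass


NOT_DETERMINED = "not determined"

_SPECIFICITY_BY_RESIDUE2 = {"P": "nitrate", "S": "chloride"}


@dataclass(frozen=True)
class SelectivityCall:
    filter_seq: str
    filter_start: int | None
    residue2: str
    specificity: str  # nitrate | chloride | degenerate | unknown


@dataclass(frozen=True)
class AnchorState:
    residue: str | None
    position: int | None  # 1-based query coordinate
    present: bool
    note: str = ""


@dataclass(frozen=True)
class GlutamateStatus:
    gating: AnchorState
    proton: AnchorState


@dataclass(frozen=True)
class MechanismCall:
    mechanism: str  # antiporter | channel | unknown
    rationale: str
    low_confidence: bool = False


@dataclass(frozen=True)
class CbsHit:
    domain: str  # e.g. CBS1 | CBS2
    start: int
    end: int
    identity_to_reference: float


@dataclass(frozen=True)
class ReferenceBundle:
    """Reference sequences and annotations the classifier aligns against.

    ``anchor_ref`` carries the glutamate anchor positions (the EcCLC
    E148/E203 frame in the shipped convention); ``filter_ref`` carries the
    selectivity-filter region used as a fallback when no filter motif
    matches; ``cbs_refs`` are (domain name, segment) pairs; ``homologs`` are
    candidates for the best-identity call.
    """

    anchor_ref: ProteinRecord | None = None
    gating_pos: int | None = None
    proton_pos: int | None = None
    filter_ref: ProteinRecord | None = None
    filter_region: tuple[int, int] | None = None
    cbs_refs: tuple[tuple[str, ProteinRecord], ...] = ()
    homologs: tuple[ProteinRecord, ...] = ()


def load_reference_bundle(json_path) -> ReferenceBundle:
    """Load a bundle from a JSON sidecar plus its FASTA (same directory)."""
    json_path = Path(json_path)
    meta = json.loads(json_path.read_text())
    records = {
        r.id: r for r in read_protein_fasta(json_path.parent / meta["fasta"])
    }

    def rec(rid: str) -> ProteinRecord:
        if rid not in records:
            raise ClassifyError(f"reference bundle: record {rid!r} not in FASTA")
        return records[rid]

    kwargs: dict = {}
    if "anchor_ref" in meta:
        a = meta["anchor_ref"]
        kwargs.update(
            anchor_ref=rec(a["id"]), gating_pos=a["gating"], proton_pos=a["proton"]
        )
    if "filter_ref" in meta:
        f = meta["filter_ref"]
        kwargs.update(filter_ref=rec(f["id"]), filter_region=(f["start"], f["end"]))
    kwargs["cbs_refs"] = tuple((c["domain"], rec(c["id"])) for c in meta.get("cbs", []))
    kwargs["homologs"] = tuple(rec(h) for h in meta.get("homologs", []))
    return ReferenceBundle(**kwargs)


# ---------------------------------------------------------------------------
# selectivity filter


def extract_selectivity_filter(
    seq: ProteinRecord,
    filter_ref: ProteinRecord | None = None,
    filter_region: tuple[int, int] | None = None,
    hydrophobic: frozenset[str] = motifscan.DEFAULT_HYDROPHOBIC,
) -> SelectivityCall:
    """Call anion specificity from the selectivity-filter motif.

    Primary path: the first filter-motif scan hit; the residue at motif
    position 2 decides (P -> nitrate, S -> chloride). Fallback: when no motif
    matches but a reference filter region is available, the region mapped to
    it by global alignment is reported as a degenerate filter.
    """
    motif = MotifDefinition(
        name="selectivity_filter", pattern="GxGxPE", hydrophobic=hydrophobic
    )
    hits = motifscan.scan_motif(seq, motif)
    if hits:
        hit = hits[0]
        residue2 = hit.matched[1]
        return SelectivityCall(
            filter_seq=hit.matched,
            filter_start=hit.start,
            residue2=residue2,
            specificity=_SPECIFICITY_BY_RESIDUE2.get(residue2, "unknown"),
        )
    if filter_ref is not None and filter_region is not None:
        start, end = filter_region
        if not (1 <= start <= end <= len(filter_ref)):
            raise ClassifyError(
                f"filter region {filter_region} out of range for reference "
                f"{filter_ref.id!r}"
            )
        aln = global_align(filter_ref, seq)
        mapped = [aln.map_a_to_b(p) for p in range(start, end + 1)]
        positions = [p for p in mapped if p is not None]
        if positions:
            filter_seq = "".join(seq.sequence[p - 1] for p in positions)
            return SelectivityCall(
                filter_seq=filter_seq,
                filter_start=positions[0],
                residue2=filter_seq[1] if len(filter_seq) > 1 else "",
                specificity="degenerate",
            )
    return SelectivityCall(filter_seq="", filter_start=None, residue2="",
                           specificity="unknown")


# ---------------------------------------------------------------------------
# glutamate anchors and mechanism


def map_anchor_positions(
    query: ProteinRecord,
    reference: ProteinRecord,
    anchor_positions: list[int],
) -> list[int | None]:
    """Query columns aligned to 1-based reference positions (None on gaps)."""
    for pos in anchor_positions:
        if not 1 <= pos <= len(reference):
            raise ClassifyError(
                f"anchor position {pos} beyond reference {reference.id!r} "
                f"length {len(reference)}"
            )
    aln = global_align(reference, query)
    return [aln.map_a_to_b(pos) for pos in anchor_positions]


def _anchor_state(query: ProteinRecord, mapped: int | None) -> AnchorState:
    if mapped is None:
        return AnchorState(residue=None, position=None, present=False,
                           note="anchor aligned to a gap")
    residue = query.sequence[mapped - 1]
    note = ""
    if residue == "D":
        note = "aspartate at anchor column; treated as absent"
    return AnchorState(residue=residue, position=mapped, present=residue == "E",
                       note=note)


def glutamate_status(
    query: ProteinRecord,
    reference: ProteinRecord,
    gating_pos: int,
    proton_pos: int,
) -> GlutamateStatus:
    mapped = map_anchor_positions(query, reference, [gating_pos, proton_pos])
    return GlutamateStatus(
        gating=_anchor_state(query, mapped[0]),
        proton=_anchor_state(query, mapped[1]),
    )


def call_transport_mechanism(status: GlutamateStatus) -> MechanismCall:
    """Decision table: both glutamates -> antiporter; one -> channel; none -> unknown."""
    g, p = status.gating.present, status.proton.present
    if g and p:
        return MechanismCall(
            mechanism="antiporter",
            rationale="gating and proton glutamates both present",
        )
    if g or p:
        which = "gating" if g else "proton"
        return MechanismCall(
            mechanism="channel",
            rationale=f"only the {which} glutamate present",
            low_confidence=True,
        )
    return MechanismCall(mechanism="unknown", rationale="neither glutamate present")


def function_label(selectivity: SelectivityCall, mechanism: MechanismCall) -> str:
    """Human-readable function call in family-table style."""
    anion = {"nitrate": "NO3-", "chloride": "Cl-"}.get(selectivity.specificity, "anion")
    if mechanism.mechanism == "antiporter":
        return f"{anion}/H+ antiporter"
    if mechanism.mechanism == "channel":
        return f"{anion} channel?"
    return NOT_DETERMINED


# ---------------------------------------------------------------------------
# CBS domains


def locate_cbs_domains(
    seq: ProteinRecord,
    cbs_refs: tuple[tuple[str, ProteinRecord], ...],
    identity_threshold: float = 40.0,
    min_columns: int = 40,
) -> list[CbsHit]:
    """Place reference CBS segments in the C-terminal half by local alignment.

    A hit needs identity >= ``identity_threshold`` percent over at least
    ``min_columns`` aligned columns; thresholds are heuristics and are
    surfaced in the configuration, not buried here.
    """
    half = len(seq) // 2
    tail = seq.sequence[half:]
    if not tail:
        return []
    hits = []
    for domain, ref in cbs_refs:
        try:
            aln = local_align(ref.sequence, tail)
        except Exception:
            continue
        cols = [
            (pa, pb) for pa, pb in aln.column_map if pa is not None and pb is not None
        ]
        if len(cols) < min_columns:
            continue
        identity = percent_identity(aln, "aligned")
        if identity < identity_threshold:
            continue
        starts = [pb for _, pb in cols]
        hits.append(
            CbsHit(
                domain=domain,
                start=half + min(starts),
                end=half + max(starts),
                identity_to_reference=identity,
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# full annotation


@dataclass(frozen=True)
class AnnotateConfig:
    signal_window: int = 120  # terminal window when no TM topology available
    cbs_identity_threshold: float = 40.0
    cbs_min_columns: int = 40
    tm_window: int = physchem.TM_WINDOW
    tm_threshold: float = physchem.TM_THRESHOLD
    tm_min_span: int = physchem.TM_MIN_SPAN
    hydrophobic: frozenset[str] = motifscan.DEFAULT_HYDROPHOBIC


@dataclass
class AnnotationReport:
    """One protein's worth of calls; the machine twin of a family table row.

    Fields that could not be computed are None, with the reason recorded in
    ``not_determined``.
    """

    record_id: str
    length: int
    mass_kda: float | None = None
    pi: float | None = None
    gravy: float | None = None
    selectivity: SelectivityCall | None = None
    glutamates: GlutamateStatus | None = None
    mechanism: MechanismCall | None = None
    function: str = NOT_DETERMINED
    cbs_hits: list[CbsHit] = field(default_factory=list)
    sorting_signals: list[SortingSignal] = field(default_factory=list)
    best_homolog: str | None = None
    best_homolog_identity: float | None = None
    tm_count: int | None = None
    not_determined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {
            "id": self.record_id,
            "length": self.length,
            "mass_kda": None if self.mass_kda is None else round(self.mass_kda, 1),
            "pi": None if self.pi is None else round(self.pi, 2),
            "gravy": None if self.gravy is None else round(self.gravy, 3),
            "best_homolog": self.best_homolog,
            "best_homolog_identity": (
                None
                if self.best_homolog_identity is None
                else round(self.best_homolog_identity, 2)
            ),
            "function": self.function,
            "tm_count": self.tm_count,
            "not_determined": self.not_determined,
        }
        if self.selectivity is not None:
            d["selectivity_filter"] = self.selectivity.filter_seq
            d["filter_start"] = self.selectivity.filter_start
            d["filter_residue2"] = self.selectivity.residue2
            d["specificity"] = self.selectivity.specificity
        if self.glutamates is not None:
            d["gating_glutamate"] = {
                "residue": self.glutamates.gating.residue,
                "position": self.glutamates.gating.position,
                "present": self.glutamates.gating.present,
            }
            d["proton_glutamate"] = {
                "residue": self.glutamates.proton.residue,
                "position": self.glutamates.proton.position,
                "present": self.glutamates.proton.present,
            }
        if self.mechanism is not None:
            d["mechanism"] = self.mechanism.mechanism
            d["mechanism_rationale"] = self.mechanism.rationale
            d["low_confidence"] = self.mechanism.low_confidence
        d["cbs_domains"] = [
            {
                "domain": h.domain,
                "start": h.start,
                "end": h.end,
                "identity_pct": round(h.identity_to_reference, 1),
            }
            for h in self.cbs_hits
        ]
        d["sorting_signals"] = [
            {
                "kind": s.kind,
                "start": s.start,
                "matched": s.matched,
                "terminus": s.terminus,
            }
            for s in self.sorting_signals
        ]
        return d


def annotate_protein(
    seq: ProteinRecord,
    references: ReferenceBundle | None = None,
    config: AnnotateConfig | None = None,
) -> AnnotationReport:
    """Assemble every call for one protein; sub-failures never abort the batch."""
    references = references or ReferenceBundle()
    config = config or AnnotateConfig()
    report = AnnotationReport(record_id=seq.id, length=len(seq))

    try:
        report.mass_kda = physchem.compute_mass(seq)
    except physchem.PhyschemError as exc:
        report.not_determined["mass_kda"] = str(exc)
    try:
        report.gravy = physchem.compute_gravy(seq)
    except physchem.PhyschemError as exc:
        report.not_determined["gravy"] = str(exc)
    report.pi = physchem.compute_pi(seq)

    tm_segments = physchem.predict_topology(
        seq, config.tm_window, config.tm_threshold, config.tm_min_span
    )
    report.tm_count = len(tm_segments)

    report.selectivity = extract_selectivity_filter(
        seq, references.filter_ref, references.filter_region, config.hydrophobic
    )

    if references.anchor_ref is not None:
        try:
            report.glutamates = glutamate_status(
                seq, references.anchor_ref, references.gating_pos, references.proton_pos
            )
            report.mechanism = call_transport_mechanism(report.glutamates)
            report.function = function_label(report.selectivity, report.mechanism)
        except (ClassifyError, Exception) as exc:  # noqa: BLE001 - batch must survive
            report.not_determined["glutamates"] = str(exc)
    else:
        report.not_determined["glutamates"] = "no anchor reference supplied"

    if references.cbs_refs:
        report.cbs_hits = locate_cbs_domains(
            seq,
            references.cbs_refs,
            config.cbs_identity_threshold,
            config.cbs_min_columns,
        )
    else:
        report.not_determined["cbs"] = "no CBS reference segments supplied"

    # terminal windows: from TM topology when available, fixed width otherwise
    if tm_segments:
        n_limit = max(1, tm_segments[0].start - 1)
        c_limit = min(len(seq), tm_segments[-1].end + 1)
    else:
        half = min(config.signal_window, max(1, len(seq) // 2 - 1))
        n_limit = half
        c_limit = len(seq) - half + 1
    if 1 <= n_limit < c_limit <= len(seq):
        report.sorting_signals = motifscan.find_sorting_signals(
            seq, n_limit, c_limit,
            motifs=motifscan.default_sorting_motifs(config.hydrophobic),
        )
    else:
        report.not_determined["sorting_signals"] = (
            f"degenerate terminal windows (n_limit={n_limit}, c_limit={c_limit})"
        )

    if references.homologs:
        best_id, best_pct = None, -1.0
        for hom in references.homologs:
            pct = percent_identity(global_align(seq, hom), "aligned")
            if pct > best_pct:
                best_id, best_pct = hom.id, pct
        report.best_homolog = best_id
        report.best_homolog_identity = best_pct
    else:
        report.not_determined["best_homolog"] = "no homolog panel supplied"

    return report
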