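"""Physicochemical summaries: mass, pI, GRAVY, hydropathy profile, TM calling.

The pI model is per-group Henderson-Hasselbalch with the Bjellqvist
(ExPASy-style) pKa set and fixed terminal pKas; the root of the net-charge
curve is found by bisection. The transmembrane caller is a plain
Kyte-Doolittle sliding-window method and is an explicit approximation of a
probabilistic topology predictor, not a reimplementation of one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqio import ProteinRecord


def _load(name: str) -> dict:
    with resources.files("clckit.data").joinpath(name).open() as fh:
        return json.load(fh)


_KD = _load("kyte_doolittle.json")
_MASS = _load("residue_masses.json")
_PKA = _load("pka_bjellqvist.json")

# classic hydropathy-calling defaults; an approximation of Philius-style output
TM_WINDOW = 19
TM_THRESHOLD = 1.6
TM_MIN_SPAN = 10
TM_MERGE_GAP = 3


class PhyschemError(ValueError):
    pass


@dataclass(frozen=True)
class PhyschemSummary:
    length: int
    mass_kda: float
    pi: float
    gravy: float


@dataclass(frozen=True)
class TmSegment:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _residues(seq: ProteinRecord | str) -> str:
    return seq.sequence if isinstance(seq, ProteinRecord) else seq


def _reject_unknown(s: str, what: str) -> None:
    pos = s.find("X")
    if pos != -1:
        raise PhyschemError(f"cannot compute {what}: unknown residue X at position {pos + 1}")


def compute_mass(seq: ProteinRecord | str) -> float:
    """Average isotopic mass in kDa: sum of residue masses plus one water."""
    s = _residues(seq)
    _reject_unknown(s, "mass")
    dalton = sum(_MASS["residues"][ch] for ch in s) + _MASS["water"]
    return dalton / 1000.0


def compute_gravy(seq: ProteinRecord | str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value."""
    s = _residues(seq)
    _reject_unknown(s, "GRAVY")
    return sum(_KD[ch] for ch in s) / len(s)


def net_charge(seq: ProteinRecord | str, ph: float) -> float:
    """Net charge at ``ph`` under per-group Henderson-Hasselbalch."""
    s = _residues(seq)
    pos = _PKA["positive"]
    neg = _PKA["negative"]
    charge = 1.0 / (1.0 + 10.0 ** (ph - pos["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (neg["Cterm"] - ph))
    for ch in s:
        if ch in pos:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pos[ch]))
        elif ch in neg:
            charge -= 1.0 / (1.0 + 10.0 ** (neg[ch] - ph))
    return charge


def compute_pi(seq: ProteinRecord | str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge is strictly decreasing in pH and the termini guarantee a sign
    change on the interval, so the root always exists.
    """
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def summarize(seq: ProteinRecord) -> PhyschemSummary:
    return PhyschemSummary(
        length=len(seq),
        mass_kda=compute_mass(seq),
        pi=compute_pi(seq),
        gravy=compute_gravy(seq),
    )


def hydropathy_profile(seq: ProteinRecord | str, window: int = TM_WINDOW) -> np.ndarray:
    """Centered moving average of Kyte-Doolittle values; ends truncated.

    Entry ``i`` (0-based) covers residues ``i+1 .. i+window`` (1-based) and is
    centered on residue ``i + window//2 + 1``.
    """
    s = _residues(seq)
    if window % 2 == 0:
        raise PhyschemError(f"window must be odd, got {window}")
    if window > len(s):
        raise PhyschemError(f"window {window} exceeds sequence length {len(s)}")
    values = np.array([_KD.get(ch, 0.0) for ch in s], dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def predict_tm_segments(
    profile: np.ndarray,
    threshold: float = TM_THRESHOLD,
    min_span: int = TM_MIN_SPAN,
    window: int = TM_WINDOW,
    merge_gap: int = TM_MERGE_GAP,
) -> list[TmSegment]:
    """Call TM segments as maximal above-threshold runs of the profile.

    A run of window centers ``i..j`` is expanded to the full residue span it
    covers; spans separated by at most ``merge_gap`` residues are merged, and
    survivors shorter than ``min_span`` residues are dropped.
    """
    above = profile >= threshold
    runs: list[list[int]] = []  # [start_res0, end_res0, idx_start, idx_end]
    i = 0
    n = len(profile)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j + window - 1, i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
            merged[-1][3] = run[3]
        else:
            merged.append(run)
    segments = []
    for start0, end0, i0, i1 in merged:
        if end0 - start0 + 1 < min_span:
            continue
        segments.append(
            TmSegment(
                start=start0 + 1,
                end=end0 + 1,
                mean_hydropathy=float(np.mean(profile[i0 : i1 + 1])),
            )
        )
    return segments


def predict_topology(
    seq: ProteinRecord,
    window: int = TM_WINDOW,
    threshold: float = TM_THRESHOLD,
    min_span: int = TM_MIN_SPAN,
) -> list[TmSegment]:
    """Hydropathy profile + TM calling in one step; [] for short sequences."""
    if len(seq) < window:
        return []
    profile = hydropathy_profile(seq, window)
    return predict_tm_segments(profile, threshold, min_span, window)
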