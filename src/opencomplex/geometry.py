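"""Supercoiling arithmetic for the open-complex extension jumps.

On a torsionally constrained tether in the plectonemic regime, unwinding n
base pairs of promoter DNA removes ``n / pitch`` turns of twist (helical
pitch ~10.5 bp/turn).  Linking-number conservation converts the twist change
into writhe, shortening the tether by ``dz_per_turn`` (~60 nm/turn in
reaction buffer) per removed turn -- with opposite sign on positively and
negatively supercoiled molecules -- while any protein-induced DNA bend or
compaction ``L_bend`` shortens the tether by the same amount for either
supercoiling sign.  The observed OS-CS jump magnitudes are therefore

    J_pos = n * dz_per_turn / pitch + L_bend
    J_neg = n * dz_per_turn / pitch - L_bend

and the measured pair (J_pos, J_neg) inverts to the bubble size and bent
length.  Rotation-extension curves recorded in two buffers likewise report
a twist change as the shift of the curve apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryResult",
    "TwistShift",
    "bubble_and_bend",
    "expected_jump",
    "twist_shift",
]


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


@dataclass(frozen=True)
class GeometryResult:
    """Transcription-bubble size and bent-DNA length from jump magnitudes."""

    n_bp: int          # unwound base pairs, rounded
    L_bend: float      # bent/compacted DNA length (nm), rounded
    raw_n: float       # unrounded bubble size (bp)
    raw_L: float       # unrounded bent length (nm)

    def to_dict(self) -> dict:
        return {"n_bp": self.n_bp, "L_bend_nm": self.L_bend,
                "raw_n_bp": self.raw_n, "raw_L_nm": self.raw_L}


@dataclass(frozen=True)
class TwistShift:
    """Apex shift between two rotation-extension curves."""

    delta_turns: float
    deg_per_kb: float
    apex_ref: float
    apex_test: float

    def to_dict(self) -> dict:
        return {"delta_turns": self.delta_turns, "deg_per_kb": self.deg_per_kb,
                "apex_ref": self.apex_ref, "apex_test": self.apex_test}


def bubble_and_bend(J_pos: float, J_neg: float, dz_per_turn: float = 60.0,
                    pitch: float = 10.5) -> GeometryResult:
    """Bubble size and bent length from the two supercoiling-sign jumps.

    ``n = pitch (J_pos + J_neg) / (2 dz_per_turn)`` and
    ``L_bend = (J_pos - J_neg) / 2``.  The worked example of the assay,
    J_pos = 73 nm and J_neg = 42 nm with dz = 60 nm/turn and pitch 10.5,
    gives n = 10 bp and L_bend = 16 nm (raw 10.06 bp, 15.5 nm).
    """
    if not (J_pos >= J_neg >= 0):
        raise ValueError("require J_pos >= J_neg >= 0 (inconsistent jumps)")
    if dz_per_turn <= 0 or pitch <= 0:
        raise ValueError("dz_per_turn and pitch must be > 0")
    raw_n = pitch * (J_pos + J_neg) / (2.0 * dz_per_turn)
    raw_L = 0.5 * (J_pos - J_neg)
    return GeometryResult(n_bp=int(_round_half_away(raw_n)),
                          L_bend=float(_round_half_away(raw_L)),
                          raw_n=raw_n, raw_L=raw_L)


def expected_jump(n_bp: float, L_bend: float, dz_per_turn: float = 60.0,
                  pitch: float = 10.5):
    """Forward prediction of the jump pair from bubble size and bent length.

    Returns ``(J_pos, J_neg, clipped)``; a negative predicted J_neg is
    reported as zero with ``clipped=True``.
    """
    if n_bp < 0 or L_bend < 0:
        raise ValueError("n_bp and L_bend must be >= 0")
    per_turn = n_bp * dz_per_turn / pitch
    J_pos = per_turn + L_bend
    J_neg = per_turn - L_bend
    clipped = J_neg < 0
    return float(J_pos), float(max(J_neg, 0.0)), bool(clipped)


def _apex(turns: np.ndarray, ext: np.ndarray) -> float:
    """Apex of a rotation-extension curve by local parabola fit.

    Points within 90% of the maximal extension are fitted by a parabola and
    the vertex returned; an apex at the boundary of the scanned turn range
    is rejected."""
    turns = np.asarray(turns, dtype=float)
    ext = np.asarray(ext, dtype=float)
    if turns.size != ext.size or turns.size < 3:
        raise ValueError("need matched turns/extension arrays with >= 3 points")
    zmax = ext.max()
    mask = ext >= 0.9 * zmax
    if mask.sum() < 3:
        # too few points near the top: widen to the 5 highest
        idx = np.argsort(ext)[-5:]
        mask = np.zeros_like(mask)
        mask[idx] = True
    a, b, _ = np.polyfit(turns[mask], ext[mask], 2)
    if a >= 0:
        raise ValueError("rotation curve has no downward apex")
    vertex = -b / (2.0 * a)
    lo, hi = turns.min(), turns.max()
    span = hi - lo
    if not (lo + 0.01 * span < vertex < hi - 0.01 * span):
        raise ValueError("apex lies at the boundary of the scanned turn range")
    return float(vertex)


def twist_shift(curve_ref, curve_test, length_kb: float) -> TwistShift:
    """Twist change between two rotation-extension curves.

    Each curve is a ``(turns, extension)`` pair; the apex (zero-twist point)
    of each is located by a parabola fit to the points within 90% of its
    maximal extension, and the shift ``apex_test - apex_ref`` is converted
    to degrees of helical twist per kilobase of the tether.
    """
    if length_kb <= 0:
        raise ValueError("length_kb must be > 0")
    apex_ref = _apex(*curve_ref)
    apex_test = _apex(*curve_test)
    delta = apex_test - apex_ref
    return TwistShift(delta_turns=float(delta),
                      deg_per_kb=float(360.0 * delta / length_kb),
                      apex_ref=apex_ref, apex_test=apex_test)
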