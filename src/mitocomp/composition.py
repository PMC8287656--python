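"""Base composition, GC content and strand-asymmetry skews.

AT skew = (A - T)/(A + T); GC skew = (G - C)/(G + C).  N bases are
excluded from every denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class CompositionStats:
    a: int
    t: int
    g: int
    c: int
    gc_content: float
    at_skew: float | None
    gc_skew: float | None

    @property
    def counted(self) -> int:
        return self.a + self.t + self.g + self.c


def base_composition(seq: str) -> CompositionStats:
    """Exact base counts, GC fraction and both skews for one sequence.

    Skews are ``None`` when their denominator is zero.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    a, t, g, c = seq.count("A"), seq.count("T"), seq.count("G"), seq.count("C")
    total = a + t + g + c
    if total == 0:
        raise ValueError("sequence contains no canonical bases")
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionStats(a, t, g, c, (g + c) / total, at_skew, gc_skew)


def skew_profile(
    seq: str, window: int, step: int, circular: bool = True
) -> list[tuple[float, float | None, float | None]]:
    """Sliding-window skews as (window midpoint, at_skew, gc_skew) records.

    On circular sequences windows wrap around the origin; windows whose
    denominator is zero emit ``None``.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    n = len(seq)
    if window > n and not circular:
        raise ValueError(f"window {window} exceeds linear sequence length {n}")
    seq = seq.upper()
    extended = seq + seq[: min(window - 1, n)] if circular else seq
    out = []
    starts = range(0, n if circular else n - window + 1, step)
    for s in starts:
        w = extended[s : s + window]
        a, t, g, c = w.count("A"), w.count("T"), w.count("G"), w.count("C")
        at = (a - t) / (a + t) if a + t else None
        gc = (g - c) / (g + c) if g + c else None
        mid = s + window / 2
        if circular:
            mid = math.fmod(mid, n)
        out.append((mid, at, gc))
    return out


def composition_row(genome_id: str, seq: str) -> dict:
    """One TSV-ready row of composition statistics."""
    st = base_composition(seq)
    return {
        "genome_id": genome_id,
        "length": len(seq),
        "A": st.a,
        "T": st.t,
        "G": st.g,
        "C": st.c,
        "GC_pct": round(100.0 * st.gc_content, 2),
        "AT_skew": st.at_skew,
        "GC_skew": st.gc_skew,
    }
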