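"""Downstream sequence element (DSE) U/GU-richness profiling.

CstF-64 binds U- or GU-rich sequence downstream of the cleavage site;
a "suboptimal" DSE lacks any discernible such element and fails to
recruit the canonical cleavage machinery. The paper-scale evidence for
suboptimality is qualitative (band-shift gels), so the call here is an
explicit, configurable decision rule: a window is U_RICH if it carries
a run of >= 4 consecutive U, or any 10-nt sub-window that is at least
half U, or >= 40% GU/UG overlapping dinucleotides; otherwise it is
SUBOPTIMAL. The thresholds are chosen so that substituting the literal
UUUUUU element anywhere in a window always yields U_RICH.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .alphabet import is_rna

__all__ = ["DseCall", "DseThresholds", "DseProfile", "profile_dse", "max_u_run"]


class DseCall(str, enum.Enum):
    U_RICH = "U_RICH"
    SUBOPTIMAL = "SUBOPTIMAL"


@dataclass(frozen=True)
class DseThresholds:
    """Decision thresholds for the U_RICH call (all configurable)."""

    min_u_run: int = 4
    min_window_u: float = 0.5
    min_gu_fraction: float = 0.4
    subwindow: int = 10


@dataclass(frozen=True)
class DseProfile:
    """Composition summary and call for one DSE window."""

    u_fraction: float
    max_u_run: int
    max_window_u: float
    gu_dinucleotide_fraction: float
    call: DseCall


def max_u_run(seq: str) -> int:
    run = best = 0
    for ch in seq:
        run = run + 1 if ch == "U" else 0
        best = max(best, run)
    return best


def profile_dse(
    dse_seq: str, thresholds: DseThresholds = DseThresholds()
) -> DseProfile:
    """Score one DSE window and call it U_RICH or SUBOPTIMAL."""
    w = thresholds.subwindow
    n = len(dse_seq)
    if n < w:
        raise ValueError(f"DSE window ({n} nt) shorter than sub-window ({w} nt)")
    if not is_rna(dse_seq):
        raise ValueError("DSE must be a non-empty unmasked RNA string")
    is_u = [ch == "U" for ch in dse_seq]
    u_fraction = sum(is_u) / n
    running = sum(is_u[:w])
    best_window = running
    for i in range(w, n):
        running += is_u[i] - is_u[i - w]
        best_window = max(best_window, running)
    max_window_u = best_window / w
    gu = sum(
        1 for a, b in zip(dse_seq, dse_seq[1:]) if a + b in ("GU", "UG")
    )
    gu_fraction = gu / (n - 1)
    run = max_u_run(dse_seq)
    u_rich = (
        run >= thresholds.min_u_run
        or max_window_u >= thresholds.min_window_u
        or gu_fraction >= thresholds.min_gu_fraction
    )
    return DseProfile(
        u_fraction=u_fraction,
        max_u_run=run,
        max_window_u=max_window_u,
        gu_dinucleotide_fraction=gu_fraction,
        call=DseCall.U_RICH if u_rich else DseCall.SUBOPTIMAL,
    )
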