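"""Per-site PAP-selection prediction from USE motif and DSE call.

The model: a non-canonical poly(A) polymerase (Star-PAP) engages sites
whose upstream element carries an AUA-core motif, while the canonical
PAPalpha requires CstF-64 loading on a U/GU-rich downstream element.
Combining the two binary readouts gives the four-state truth table::

    motif+  SUBOPTIMAL  -> STAR_PAP    (exclusive non-canonical site)
    motif+  U_RICH      -> BOTH        (redundantly processed)
    motif-  U_RICH      -> PAP_ALPHA   (canonical site)
    motif-  SUBOPTIMAL  -> NONE        (no modelled PAP engages)

NONE predicts non-processing of the site, not a degradation mechanism.
In-silico mutagenesis (AUA -> GGG in the USE; UUUUUU substituted into
the DSE) moves one wild-type site through all four states, mirroring
the reporter mutant series.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .alphabet import MASK, RNA_BASES
from .dse import DseCall, DseProfile, DseThresholds, profile_dse
from .kmers import MotifPWM, find_occurrences
from .regions import RegionPair

__all__ = [
    "Label",
    "SiteCall",
    "AuaToGgg",
    "URichSubstitution",
    "classify_site",
    "apply_mutation",
    "make_archetypes",
    "pwm_max_logodds",
]


class Label(str, enum.Enum):
    STAR_PAP = "STAR_PAP"
    PAP_ALPHA = "PAP_ALPHA"
    BOTH = "BOTH"
    NONE = "NONE"


_TRUTH_TABLE = {
    (True, DseCall.SUBOPTIMAL): Label.STAR_PAP,
    (True, DseCall.U_RICH): Label.BOTH,
    (False, DseCall.U_RICH): Label.PAP_ALPHA,
    (False, DseCall.SUBOPTIMAL): Label.NONE,
}


@dataclass(frozen=True)
class SiteCall:
    """Classification of one poly(A) site with its evidence."""

    gene_id: str
    motif_present: bool
    dse_call: DseCall
    label: Label
    motif_word: str | None = None
    motif_distance: int | None = None  # upstream distance of the hit start
    dse_profile: DseProfile | None = None


def pwm_max_logodds(
    pwm: MotifPWM, seq: str, background: Sequence[float] = (0.25,) * 4
) -> float:
    """Best log2-odds PWM score over all unmasked windows of ``seq``."""
    idx = {b: i for i, b in enumerate(RNA_BASES)}
    bg = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        lods = np.log2(np.where(pwm.matrix > 0, pwm.matrix, np.nan)) - np.log2(
            bg
        )[:, None]
    best = -math.inf
    w = pwm.width
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if MASK in window:
            continue
        score = 0.0
        ok = True
        for j, ch in enumerate(window):
            v = lods[idx[ch], j]
            if np.isnan(v):
                ok = False
                break
            score += v
        if ok:
            best = max(best, score)
    return best


def classify_site(
    region: RegionPair,
    frequent_words: Sequence[str],
    dse_profile: DseProfile,
    pwm: MotifPWM | None = None,
    logodds_threshold: float = 0.0,
    background: Sequence[float] = (0.25,) * 4,
) -> SiteCall:
    """Call the regulating PAP for one site.

    ``motif_present`` is true when any frequent AUA-core word occurs
    unmasked in the USE (presence/absence, matching the band-shift
    evidence the table is modelled on). If a PWM is supplied, a best
    log-odds score at or above ``logodds_threshold`` bits also counts.
    The ``region`` should already be PAS-masked.
    """
    word_hit = None
    hit_distance = None
    for w in frequent_words:
        occ = find_occurrences(w, region.use_seq)
        if occ:
            word_hit, hit_distance = w, region.upstream_distance(occ[0])
            break
    motif = word_hit is not None
    if not motif and pwm is not None:
        motif = pwm_max_logodds(pwm, region.use_seq, background) >= logodds_threshold
    return SiteCall(
        gene_id=region.gene_id,
        motif_present=motif,
        dse_call=dse_profile.call,
        label=_TRUTH_TABLE[(motif, dse_profile.call)],
        motif_word=word_hit,
        motif_distance=hit_distance,
        dse_profile=dse_profile,
    )


@dataclass(frozen=True)
class AuaToGgg:
    """USE edit: replace AUA by GGG at ``position`` (use_seq index),
    or every AUA occurrence when ``position`` is None."""

    position: int | None = None


@dataclass(frozen=True)
class URichSubstitution:
    """DSE edit: substitute a U-rich element (default UUUUUU) in place
    at ``position`` (dse_seq index); record length is preserved."""

    position: int
    element: str = "UUUUUU"


Edit = AuaToGgg | URichSubstitution


def apply_mutation(region: RegionPair, edits: Edit | Sequence[Edit]) -> RegionPair:
    """Apply in-silico reporter edits; an empty edit list is identity."""
    if isinstance(edits, (AuaToGgg, URichSubstitution)):
        edits = [edits]
    use, dse = region.use_seq, region.dse_seq
    for edit in edits:
        if isinstance(edit, AuaToGgg):
            if edit.position is not None:
                pos = edit.position
                if use[pos : pos + 3] != "AUA":
                    raise ValueError(f"no AUA occurrence at USE index {pos}")
                use = use[:pos] + "GGG" + use[pos + 3 :]
            else:
                if "AUA" not in use:
                    raise ValueError("no AUA occurrence in the USE")
                while "AUA" in use:
                    use = use.replace("AUA", "GGG", 1)
        elif isinstance(edit, URichSubstitution):
            pos, elem = edit.position, edit.element
            if pos < 0 or pos + len(elem) > len(dse):
                raise ValueError(
                    f"DSE substitution at {pos} does not fit window of {len(dse)} nt"
                )
            dse = dse[:pos] + elem + dse[pos + len(elem) :]
        else:
            raise TypeError(f"unknown edit {edit!r}")
    return replace(region, use_seq=use, dse_seq=dse)


def make_archetypes(
    wild_type: RegionPair, dse_position: int | None = None
) -> dict[str, RegionPair]:
    """The four reporter archetypes derived from one wild-type site.

    WT (unchanged), U-Mut (all AUA -> GGG upstream), D-Mut (UUUUUU
    substituted into the DSE), DU-Mut (both edits). The wild type must
    carry at least one AUA in its USE.
    """
    pos = (len(wild_type.dse_seq) - 6) // 2 if dse_position is None else dse_position
    d_edit = URichSubstitution(pos)
    return {
        "WT": wild_type,
        "U-Mut": apply_mutation(wild_type, AuaToGgg()),
        "D-Mut": apply_mutation(wild_type, d_edit),
        "DU-Mut": apply_mutation(wild_type, [AuaToGgg(), d_edit]),
    }


def classify_archetypes(
    archetypes: dict[str, RegionPair],
    frequent_words: Sequence[str],
    thresholds: DseThresholds = DseThresholds(),
) -> dict[str, SiteCall]:
    """Classify each archetype with fresh DSE profiles."""
    return {
        name: classify_site(
            r, frequent_words, profile_dse(r.dse_seq, thresholds)
        )
        for name, r in archetypes.items()
    }
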