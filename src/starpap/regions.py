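"""Fold-change target selection and strand-aware USE/DSE window extraction.

The upstream sequence element (USE) window defaults to upstream
distances [50, 150) of the cleavage junction — the footprint region in
which the AUA-core motif is sought — and the downstream sequence
element (DSE) window to distances [1, 50], covering the canonical
CstF-64 binding region. Both windows are parameters, never hard-coded
anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .alphabet import is_rna, reverse_complement
from .io import FoldChangeRow, PolyASite, SequenceRecord

__all__ = ["RegionPair", "TruncatedFlankError", "select_targets", "extract_regions"]


class TruncatedFlankError(ValueError):
    """The reference does not cover the requested window.

    Carries the available extent so the caller can decide to lower the
    window; extraction never silently pads.
    """

    def __init__(self, side: str, needed: int, available: int, site: PolyASite):
        self.side = side
        self.needed = needed
        self.available = available
        self.site = site
        super().__init__(
            f"truncated {side} flank for {site.gene_id} on {site.seq_id}: "
            f"need {needed} nt, only {available} available"
        )


@dataclass(frozen=True)
class RegionPair:
    """USE and DSE windows of one poly(A) site, in sense orientation.

    ``use_seq`` covers upstream distances [use_far, use_near) of the
    junction (index 0 maps to distance -use_far); ``dse_seq`` covers
    downstream distances [1, dse_len]. Masked USE positions may carry N.
    """

    gene_id: str
    use_seq: str
    dse_seq: str
    use_far: int = 150
    use_near: int = 50
    dse_len: int = 50
    site: PolyASite | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.use_near < self.use_far):
            raise ValueError("require 0 <= use_near < use_far")
        if len(self.use_seq) != self.use_far - self.use_near:
            raise ValueError("use_seq length must equal use_far - use_near")
        if len(self.dse_seq) != self.dse_len:
            raise ValueError("dse_seq length must equal dse_len")
        if not is_rna(self.use_seq, allow_mask=True):
            raise ValueError("use_seq must be RNA (optionally masked)")
        if not is_rna(self.dse_seq, allow_mask=True):
            raise ValueError("dse_seq must be RNA (optionally masked)")

    def upstream_distance(self, index: int) -> int:
        """Signed upstream distance of USE string index (monotone)."""
        if not 0 <= index < len(self.use_seq):
            raise IndexError(index)
        return index - self.use_far

    def use_index(self, distance: int) -> int:
        """Inverse of :meth:`upstream_distance` (distance is negative)."""
        return distance + self.use_far


def select_targets(
    fold_changes: Iterable[FoldChangeRow] | Mapping[str, float],
    cutoff: float = 1.8,
) -> set[str]:
    """Genes with knockdown fold-reduction strictly greater than ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(fold_changes, Mapping):
        items = fold_changes.items()
    else:
        items = ((r.gene_id, r.fold_change) for r in fold_changes)
    return {g for g, fc in items if fc > cutoff}


def extract_regions(
    site: PolyASite,
    sequence: SequenceRecord,
    use_far: int = 150,
    use_near: int = 50,
    dse_len: int = 50,
) -> RegionPair:
    """Cut the USE and DSE windows around ``site`` in sense orientation.

    On the + strand, use_seq = ref[j-use_far, j-use_near) and
    dse_seq = ref[j, j+dse_len); on the - strand, the mirror windows
    are reverse-complemented into sense orientation.
    """
    if site.seq_id != sequence.id:
        raise ValueError(f"site {site.gene_id} refers to {site.seq_id}, got {sequence.id}")
    ref = sequence.seq
    j = site.junction
    n = len(ref)
    if site.strand == "+":
        if j - use_far < 0:
            raise TruncatedFlankError("upstream", use_far, j, site)
        if j + dse_len > n:
            raise TruncatedFlankError("downstream", dse_len, n - j, site)
        use = ref[j - use_far : j - use_near]
        dse = ref[j : j + dse_len]
    else:
        if j + use_far > n:
            raise TruncatedFlankError("upstream", use_far, n - j, site)
        if j - dse_len < 0:
            raise TruncatedFlankError("downstream", dse_len, j, site)
        use = reverse_complement(ref[j + use_near : j + use_far])
        dse = reverse_complement(ref[j - dse_len : j])
    return RegionPair(
        gene_id=site.gene_id,
        use_seq=use,
        dse_seq=dse,
        use_far=use_far,
        use_near=use_near,
        dse_len=dse_len,
        site=site,
    )
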