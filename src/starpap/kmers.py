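"""AUA-core k-mer enumeration, PAS masking, gene-level occurrence,
frequent-word selection, 7-mer mapping, PWM construction and positional
distributions.

The motif search mirrors a two-stage strategy: first enumerate every
5-mer that carries a complete AUA triplet (48 placements over 47
distinct words — ``AUAUA`` admits the triplet at two offsets), score
each word by the fraction of target genes whose upstream sequence
element (USE) contains it, then map the frequent 5-mers onto 7-mers
that keep AUA at the central position and summarize those as a position
weight matrix. Windows resembling the AAUAAA poly(A) signal are masked
out first so that the degenerate PAS itself is never counted as motif
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import MASK, RNA_BASES
from .regions import RegionPair

__all__ = [
    "KmerPlacement",
    "KmerStat",
    "MotifPWM",
    "PositionalHistogram",
    "enumerate_aua_5mers",
    "enumerate_central_7mers",
    "distinct_aua_5mers",
    "mask_pas_like",
    "find_occurrences",
    "gene_occurrence",
    "gene_kmer_sets",
    "select_frequent",
    "map_to_7mers",
    "build_pwm",
    "positional_distribution",
]


@dataclass(frozen=True)
class KmerPlacement:
    """A k-mer together with the offset of its AUA triplet."""

    word: str
    offset: int

    def __post_init__(self) -> None:
        if self.word[self.offset : self.offset + 3] != "AUA":
            raise ValueError(f"{self.word!r} has no AUA at offset {self.offset}")
        if len(self.word) == 7 and self.offset != 2:
            raise ValueError("7-mers must anchor AUA centrally (offset 2)")


@dataclass
class KmerStat:
    """Gene-level occurrence of one word in target vs background genes."""

    word: str
    n_target_genes_with: int
    n_target_genes: int
    n_bg_genes_with: int
    n_bg_genes: int
    target_fraction: float
    bg_fraction: float
    p_value: float = float("nan")
    q_value: float = float("nan")


def enumerate_aua_5mers() -> list[KmerPlacement]:
    """All (word, offset) placements of AUA inside a 5-letter RNA word.

    3 offsets x 16 flank combinations = 48 placements; the word universe
    has 47 distinct members because AUAUA carries AUA at offsets 0 and 2.
    Order is deterministic: by (offset, word) lexicographically.
    """
    out: list[KmerPlacement] = []
    for offset in (0, 1, 2):
        for flanks in product(RNA_BASES, repeat=2):
            chars = [""] * 5
            chars[offset : offset + 3] = "AUA"
            free = [i for i in range(5) if not chars[i]]
            for i, b in zip(free, flanks):
                chars[i] = b
            out.append(KmerPlacement("".join(chars), offset))
    for offset in (0, 1, 2):
        block = [p for p in out if p.offset == offset]
        block.sort(key=lambda p: p.word)
    out.sort(key=lambda p: (p.offset, p.word))
    return out


def distinct_aua_5mers() -> list[str]:
    """The 47 distinct AUA-carrying 5-mers, lexicographic."""
    return sorted({p.word for p in enumerate_aua_5mers()})


def enumerate_central_7mers() -> list[KmerPlacement]:
    """All 256 7-mers with AUA anchored at the central position (offset 2)."""
    out = []
    for pre in product(RNA_BASES, repeat=2):
        for suf in product(RNA_BASES, repeat=2):
            out.append(KmerPlacement("".join(pre) + "AUA" + "".join(suf), 2))
    out.sort(key=lambda p: p.word)
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def mask_pas_like(
    region: RegionPair, hexamer: str = "AAUAAA", max_mismatch: int = 1
) -> RegionPair:
    """Mask every USE window within ``max_mismatch`` of the PAS hexamer.

    Masked positions become ``N`` and therefore cannot contribute to any
    k-mer occurrence downstream. The DSE is left untouched (U/GU
    profiling is a composition measure, not a motif search).
    """
    seq = region.use_seq
    w = len(hexamer)
    masked = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - w + 1):
        if hamming(seq[i : i + w], hexamer) <= max_mismatch:
            masked[i : i + w] = True
    if not masked.any():
        return region
    chars = [MASK if m else c for c, m in zip(seq, masked)]
    return replace(region, use_seq="".join(chars))


def find_occurrences(word: str, seq: str) -> list[int]:
    """All (overlapping) start indices of ``word`` in ``seq``.

    Masked (N) positions never match because ``word`` is pure RNA.
    """
    hits = []
    start = seq.find(word)
    while start != -1:
        hits.append(start)
        start = seq.find(word, start + 1)
    return hits


def gene_occurrence(
    word: str, regions_by_gene: Mapping[str, Sequence[RegionPair]]
) -> tuple[int, int, float]:
    """Gene-level occurrence: a gene is "with" iff the word occurs
    unmasked in at least one of its analysed USE windows.

    Returns (n_with, n_total, fraction).
    """
    n_total = len(regions_by_gene)
    if n_total == 0:
        raise ValueError("gene_occurrence requires at least one gene")
    n_with = sum(
        1
        for regions in regions_by_gene.values()
        if any(word in r.use_seq for r in regions)
    )
    return n_with, n_total, n_with / n_total


def gene_kmer_sets(
    regions_by_gene: Mapping[str, Sequence[RegionPair]], k: int
) -> dict[str, frozenset]:
    """Per-gene set of unmasked k-substrings of the USE windows.

    Speeds up many-word occurrence queries; membership is equivalent to
    :func:`gene_occurrence` with the same regions.
    """
    out = {}
    for gene, regions in regions_by_gene.items():
        words = set()
        for r in regions:
            s = r.use_seq
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if MASK not in w:
                    words.add(w)
        out[gene] = frozenset(words)
    return out


def select_frequent(
    stats: Iterable[KmerStat], threshold: float = 0.55
) -> list[KmerStat]:
    """Words whose target gene fraction strictly exceeds ``threshold``,
    sorted by fraction descending then lexicographically."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    kept = [s for s in stats if s.target_fraction > threshold]
    kept.sort(key=lambda s: (-s.target_fraction, s.word))
    return kept


def map_to_7mers(
    frequent_5mers: Sequence[str],
    regions_by_gene: Mapping[str, Sequence[RegionPair]],
) -> list[tuple[str, int]]:
    """Central-AUA 7-mers containing any frequent 5-mer, with gene counts.

    Sorted by gene count descending, then lexicographically.
    """
    if not frequent_5mers:
        return []
    candidates = [
        p.word
        for p in enumerate_central_7mers()
        if any(f in p.word for f in frequent_5mers)
    ]
    sets7 = gene_kmer_sets(regions_by_gene, 7)
    counted = [
        (w, sum(1 for s in sets7.values() if w in s)) for w in candidates
    ]
    counted.sort(key=lambda t: (-t[1], t[0]))
    return counted


_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}


@dataclass
class MotifPWM:
    """Position weight matrix over (A, C, G, U) rows.

    ``matrix`` has shape (4, width); every column sums to 1. ``support``
    records the weighted k-mers the matrix was built from.
    """

    matrix: np.ndarray
    support: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have shape (4, width)")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-4):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(RNA_BASES[i] for i in self.matrix.argmax(axis=0))


def build_pwm(
    weighted_7mers: Sequence[tuple[str, float]], pseudocount: float = 0.0
) -> MotifPWM:
    """Weighted base-frequency matrix from supported k-mers.

    matrix[b][j] = (pseudocount + sum of weights of words with base b at
    column j) / (4 * pseudocount + total weight). With zero pseudocount
    and centrally anchored 7-mers, columns 3-5 (1-based) are exact
    indicators on A, U, A.
    """
    if not weighted_7mers:
        raise ValueError("cannot build a PWM from empty support")
    widths = {len(w) for w, _ in weighted_7mers}
    if len(widths) != 1:
        raise ValueError("all supported words must share one width")
    if any(weight <= 0 for _, weight in weighted_7mers):
        raise ValueError("support weights must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    width = widths.pop()
    counts = np.full((4, width), pseudocount, dtype=float)
    total = 4.0 * pseudocount
    for word, weight in weighted_7mers:
        total += weight
        for j, ch in enumerate(word):
            counts[_BASE_INDEX[ch], j] += weight
    return MotifPWM(counts / total, support=tuple(weighted_7mers))


@dataclass
class PositionalHistogram:
    """Histogram of motif-occurrence midpoints by upstream distance.

    ``bin_edges`` are signed upstream distances (ascending, e.g. -150,
    -140, ..., -50); ``counts[i]`` covers [edges[i], edges[i+1]).
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def mode_center(self) -> float:
        """Center of the most-populated bin (first one on ties)."""
        i = int(self.counts.argmax())
        return float(self.bin_edges[i] + self.bin_edges[i + 1]) / 2.0


def positional_distribution(
    word_set: Sequence[str],
    regions: Iterable[RegionPair],
    bin_width: int = 10,
) -> PositionalHistogram:
    """Bin unmasked occurrences of any word in ``word_set`` by the
    upstream distance of the occurrence midpoint."""
    regions = list(regions)
    if not regions:
        raise ValueError("positional_distribution requires regions")
    frames = {(r.use_far, r.use_near) for r in regions}
    if len(frames) != 1:
        raise ValueError("regions mix USE window parameters")
    use_far, use_near = frames.pop()
    span = use_far - use_near
    if span % bin_width:
        raise ValueError("bin_width must divide the USE window length")
    edges = np.arange(-use_far, -use_near + 1, bin_width)
    distances = []
    words = sorted(set(word_set))
    for r in regions:
        for w in words:
            half = len(w) // 2
            for start in find_occurrences(w, r.use_seq):
                distances.append(start + half - use_far)
    counts, _ = np.histogram(distances, bins=edges)
    return PositionalHistogram(bin_edges=edges, counts=counts)
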