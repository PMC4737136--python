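"""Seeded synthetic 3'-UTR cohorts with known cis-element architecture.

The generator emits two gene classes around an annotated cleavage
junction (at a fixed coordinate, so positional analyses share one
frame):

* **targets** — down-regulated on knockdown (fold reduction above the
  selection cutoff), GC-rich upstream composition, a canonical AAUAAA
  poly(A) signal at a fixed upstream offset, with high probability one
  embedded AUA-core 7-mer placed uniformly in a stated upstream window,
  and a U-poor downstream element that profiles SUBOPTIMAL;
* **background** — uniform upstream composition with the same AAUAAA
  placement but no enforced motif, near-unity fold change, and a
  U/GU-rich downstream element carrying an explicit poly-U run.

Every record also gets a ground-truth row (class, embedded flag and
position, U-run position) so recovery tests can be scored exactly.
Identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import RNA_BASES
from .dse import DseCall, DseThresholds, profile_dse
from .io import (
    FoldChangeRow,
    PolyASite,
    SequenceRecord,
    write_fasta,
    write_fold_changes,
    write_sites,
)

__all__ = ["CohortConfig", "TruthRow", "Cohort", "generate_cohort", "write_cohort"]

_PAS = "AAUAAA"


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Distances are nucleotides; ``embed_window`` and ``bg_urun_window``
    are inclusive distance intervals (upstream of / downstream of the
    junction); intervals for lengths and fold changes are inclusive.
    """

    n_target: int = 100
    n_background: int = 100
    upstream_len: int = 200
    downstream_len: int = 100
    use_gc: float = 0.60
    embed_prob: float = 0.9
    embed_window: tuple[int, int] = (60, 120)
    embed_7mer: str | object = "ACAUAUA"  # literal word or a MotifPWM to sample from
    pas_offset: int = 20
    target_dse_u: float = 0.15
    bg_urun_len: tuple[int, int] = (5, 8)
    bg_urun_window: tuple[int, int] = (5, 25)
    fc_target: tuple[float, float] = (2.0, 5.0)
    fc_background: tuple[float, float] = (0.8, 1.5)
    seed: int = 0
    dse_thresholds: DseThresholds = field(default_factory=DseThresholds)

    def __post_init__(self) -> None:
        if self.n_target < 0 or self.n_background < 0:
            raise ValueError("cohort sizes must be non-negative")
        for lo, hi in (
            self.embed_window,
            self.bg_urun_len,
            self.bg_urun_window,
            self.fc_target,
            self.fc_background,
        ):
            if lo > hi:
                raise ValueError(f"interval ({lo}, {hi}) is not well-ordered")
        if not 0 <= self.use_gc <= 1 or not 0 <= self.embed_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.target_dse_u <= 1:
            raise ValueError("target_dse_u must lie in [0, 1]")
        if not (1 <= self.embed_window[0] and self.embed_window[1] <= self.upstream_len):
            raise ValueError("embed_window must lie within [1, upstream_len]")
        if not len(_PAS) <= self.pas_offset <= self.upstream_len:
            raise ValueError("pas_offset must place AAUAAA inside the upstream region")
        if self.bg_urun_window[1] - 1 + self.bg_urun_len[1] > self.downstream_len:
            raise ValueError("background U-run would overrun the downstream region")
        if isinstance(self.embed_7mer, str):
            if len(self.embed_7mer) != 7 or self.embed_7mer[2:5] != "AUA":
                raise ValueError(
                    "embed_7mer must be a 7-mer with AUA at the central "
                    f"position (offset 2), got {self.embed_7mer!r}"
                )


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one synthetic gene."""

    gene_id: str
    label: str  # "target" | "background"
    embedded: bool
    embed_position: int | None  # upstream distance of embedded 7-mer start
    urun_position: int | None  # downstream distance of the poly-U run start
    embed_word: str | None = None  # the 7-mer actually written

    def __post_init__(self) -> None:
        if self.embedded and self.label != "target":
            raise ValueError("only target genes carry an embedded motif")


@dataclass
class Cohort:
    sequences: list[SequenceRecord]
    sites: list[PolyASite]
    fold_changes: list[FoldChangeRow]
    truth: list[TruthRow]


def _draw(rng: np.random.Generator, n: int, probs: Sequence[float]) -> list[str]:
    return list(rng.choice(list(RNA_BASES), size=n, p=probs))


def _paste(chars: list[str], word: str, start: int) -> None:
    chars[start : start + len(word)] = list(word)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate sequences, sites, fold changes and truth for one cohort."""
    rng = np.random.default_rng(config.seed)
    c = config
    gc_half = c.use_gc / 2.0
    at_half = (1.0 - c.use_gc) / 2.0
    target_use_p = [at_half, gc_half, gc_half, at_half]  # A C G U
    uniform_p = [0.25] * 4
    du = c.target_dse_u
    target_dse_p = [(1 - du) / 3.0] * 3 + [du]
    pas_start = c.upstream_len - c.pas_offset
    pas_span = (pas_start, pas_start + len(_PAS))

    sequences, sites, fcs, truth = [], [], [], []

    def sample_embed_word() -> str:
        if isinstance(c.embed_7mer, str):
            return c.embed_7mer
        pwm = c.embed_7mer  # a MotifPWM: sample one base per column
        bases = list(RNA_BASES)
        return "".join(
            str(rng.choice(bases, p=pwm.matrix[:, j])) for j in range(pwm.width)
        )

    def add_gene(gene_id: str, upstream: list[str], downstream: list[str], fc: float,
                 label: str, embedded: bool, embed_pos, urun_pos, embed_word=None) -> None:
        seq = "".join(upstream) + "".join(downstream)
        sequences.append(SequenceRecord(gene_id, seq))
        sites.append(PolyASite(gene_id, c.upstream_len, "+", gene_id))
        fcs.append(FoldChangeRow(gene_id, round(float(fc), 6)))
        truth.append(TruthRow(gene_id, label, embedded, embed_pos, urun_pos, embed_word))

    for i in range(c.n_target):
        gene_id = f"TGT{i:04d}"
        use = _draw(rng, c.upstream_len, target_use_p)
        _paste(use, _PAS, pas_start)
        embedded = bool(rng.random() < c.embed_prob)
        embed_pos = None
        word = None
        if embedded:
            word = sample_embed_word()
            lo, hi = c.embed_window
            for _ in range(100):
                d = int(rng.integers(lo, hi + 1))
                start = c.upstream_len - d
                if start + len(word) <= pas_span[0] or start >= pas_span[1]:
                    break
            else:
                raise ValueError(
                    "embed_window overlaps the AAUAAA placement; cannot embed"
                )
            _paste(use, word, start)
            embed_pos = d
        # reject U-rich draws so the emitted DSE is suboptimal by
        # construction, exactly as the truth label asserts
        for _ in range(200):
            dse = _draw(rng, c.downstream_len, target_dse_p)
            if profile_dse("".join(dse), c.dse_thresholds).call is DseCall.SUBOPTIMAL:
                break
        else:
            raise ValueError("could not draw a SUBOPTIMAL target DSE in 200 tries")
        fc = rng.uniform(*c.fc_target)
        add_gene(gene_id, use, dse, fc, "target", embedded, embed_pos, None, word)

    for i in range(c.n_background):
        gene_id = f"BGD{i:04d}"
        use = _draw(rng, c.upstream_len, uniform_p)
        _paste(use, _PAS, pas_start)
        dse = _draw(rng, c.downstream_len, uniform_p)
        run_len = int(rng.integers(c.bg_urun_len[0], c.bg_urun_len[1] + 1))
        pos = int(rng.integers(c.bg_urun_window[0], c.bg_urun_window[1] + 1))
        _paste(dse, "U" * run_len, pos - 1)  # downstream distance 1 == index 0
        fc = rng.uniform(*c.fc_background)
        add_gene(gene_id, use, dse, fc, "background", False, None, pos)

    return Cohort(sequences, sites, fcs, truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA/BED/fold-change/truth files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "cohort.fasta",
        "sites": out / "sites.bed",
        "fold_changes": out / "fold_changes.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(cohort.sequences, paths["fasta"])
    write_sites(cohort.sites, paths["sites"])
    write_fold_changes(cohort.fold_changes, paths["fold_changes"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tlabel\tembedded\tembed_position\turun_position\tembed_word\n")
        for t in cohort.truth:
            fh.write(
                f"{t.gene_id}\t{t.label}\t{int(t.embedded)}\t"
                f"{'' if t.embed_position is None else t.embed_position}\t"
                f"{'' if t.urun_position is None else t.urun_position}\t"
                f"{t.embed_word or ''}\n"
            )
    return paths
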