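"""End-to-end composition of the cis-element analysis.

Stages: select target genes by knockdown fold change, cut USE/DSE
windows around every annotated poly(A) site, mask AAUAAA-like
sequence, score AUA-core 5-mer enrichment (Fisher, BH), select the
frequent 5-mers, map them onto centrally anchored 7-mers, build the
recognition-motif PWM and the positional histogram, profile every DSE,
and classify each site by the four-state PAP-selection model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .classify import SiteCall, classify_site
from .dse import DseProfile, DseThresholds, profile_dse
from .io import FoldChangeRow, PolyASite, SequenceRecord
from .kmers import (
    KmerStat,
    MotifPWM,
    PositionalHistogram,
    build_pwm,
    map_to_7mers,
    mask_pas_like,
    positional_distribution,
    select_frequent,
)
from .regions import RegionPair, extract_regions, select_targets
from .stats import compute_kmer_stats, kmer_stats_frame

__all__ = ["AnalysisParams", "AnalysisResult", "run_analysis", "group_regions"]


@dataclass(frozen=True)
class AnalysisParams:
    """Every tunable of the analysis, with the defaults used throughout."""

    fc_cutoff: float = 1.8
    use_far: int = 150
    use_near: int = 50
    dse_len: int = 50
    pas_hexamer: str = "AAUAAA"
    pas_max_mismatch: int = 1
    frequent_threshold: float = 0.55
    sevenmer_fraction: float = 0.30
    alpha: float = 0.05
    bin_width: int = 10
    alternative: str = "greater"
    pwm_pseudocount: float = 0.0
    dse_thresholds: DseThresholds = field(default_factory=DseThresholds)


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one cohort."""

    targets: set[str]
    target_regions: dict[str, list[RegionPair]]
    bg_regions: dict[str, list[RegionPair]]
    kmer_stats: list[KmerStat]
    frequent: list[KmerStat]
    sevenmer_counts: list[tuple[str, int]]
    pwm: MotifPWM | None
    histogram: PositionalHistogram | None
    dse_profiles: dict[tuple[str, int], DseProfile]
    site_calls: list[SiteCall]

    @property
    def stats_frame(self) -> pd.DataFrame:
        return kmer_stats_frame(self.kmer_stats)

    @property
    def frequent_words(self) -> list[str]:
        return [s.word for s in self.frequent]

    @property
    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in self.site_calls],
                "motif_present": [c.motif_present for c in self.site_calls],
                "motif_word": [c.motif_word or "" for c in self.site_calls],
                "motif_distance": [c.motif_distance for c in self.site_calls],
                "dse_call": [c.dse_call.value for c in self.site_calls],
                "label": [c.label.value for c in self.site_calls],
            }
        )


def group_regions(
    sites: Sequence[PolyASite],
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    params: AnalysisParams = AnalysisParams(),
) -> dict[str, list[RegionPair]]:
    """Extract one RegionPair per site, grouped by gene.

    Genes with multiple poly(A) sites contribute one pair per site;
    gene-level occurrence downstream is an OR over a gene's sites.
    """
    if not isinstance(sequences, Mapping):
        sequences = {r.id: r for r in sequences}
    grouped: dict[str, list[RegionPair]] = {}
    for site in sites:
        region = extract_regions(
            site,
            sequences[site.seq_id],
            use_far=params.use_far,
            use_near=params.use_near,
            dse_len=params.dse_len,
        )
        grouped.setdefault(site.gene_id, []).append(region)
    return grouped


def run_analysis(
    sequences: Sequence[SequenceRecord],
    sites: Sequence[PolyASite],
    fold_changes: Sequence[FoldChangeRow],
    params: AnalysisParams = AnalysisParams(),
) -> AnalysisResult:
    """Run the full cis-element analysis on one cohort."""
    seq_index = {r.id: r for r in sequences}
    targets = select_targets(fold_changes, cutoff=params.fc_cutoff)
    regions = group_regions(sites, seq_index, params)
    masked = {
        gene: [
            mask_pas_like(r, params.pas_hexamer, params.pas_max_mismatch)
            for r in rs
        ]
        for gene, rs in regions.items()
    }
    target_regions = {g: rs for g, rs in masked.items() if g in targets}
    bg_regions = {g: rs for g, rs in masked.items() if g not in targets}
    if not target_regions or not bg_regions:
        raise ValueError(
            "need both target and background genes "
            f"(got {len(target_regions)} targets, {len(bg_regions)} background)"
        )

    stats = compute_kmer_stats(
        target_regions, bg_regions, alternative=params.alternative
    )
    frequent = select_frequent(stats, threshold=params.frequent_threshold)
    frequent_words = [s.word for s in frequent]

    sevenmers = map_to_7mers(frequent_words, target_regions)
    n_t = len(target_regions)
    supported = [
        (w, n) for w, n in sevenmers if n / n_t > params.sevenmer_fraction
    ]
    pwm = (
        build_pwm([(w, float(n)) for w, n in supported], params.pwm_pseudocount)
        if supported
        else None
    )

    flat_targets = [r for rs in target_regions.values() for r in rs]
    histogram = (
        positional_distribution(frequent_words, flat_targets, params.bin_width)
        if flat_targets
        else None
    )

    dse_profiles: dict[tuple[str, int], DseProfile] = {}
    site_calls: list[SiteCall] = []
    for gene, rs in masked.items():
        for r in rs:
            profile = profile_dse(r.dse_seq, params.dse_thresholds)
            key = (gene, r.site.junction if r.site else 0)
            dse_profiles[key] = profile
            site_calls.append(classify_site(r, frequent_words, profile))

    return AnalysisResult(
        targets=targets,
        target_regions=target_regions,
        bg_regions=bg_regions,
        kmer_stats=stats,
        frequent=frequent,
        sevenmer_counts=sevenmers,
        pwm=pwm,
        histogram=histogram,
        dse_profiles=dse_profiles,
        site_calls=site_calls,
    )
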