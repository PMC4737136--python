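"""Target-vs-background contingency testing for k-mer occurrence.

Each word yields a 2x2 table of gene counts (target with/without vs
background with/without). Enrichment is assessed by Fisher's exact
test, one-sided towards enrichment in targets by default — the
one-sided p is the hypergeometric tail P(X >= a | margins). Raw
p < 0.05 is the default significance filter; Benjamini–Hochberg
q-values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kmers import KmerStat, distinct_aua_5mers, gene_kmer_sets
from .regions import RegionPair

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "bh_adjust",
    "compute_kmer_stats",
    "kmer_stats_frame",
    "compare_fractions",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Gene counts: a/b = targets with/without, c/d = background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_target(self) -> int:
        return self.a + self.b

    @property
    def n_background(self) -> int:
        return self.c + self.d


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact p-value for one 2x2 gene-count table.

    ``greater`` (default) is the enrichment tail P(X >= a | margins);
    ``two-sided`` uses the point-probability rule.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    total = a + b + c + d
    if total == 0:
        raise ValueError("contingency table has all-zero margins")
    if alternative == "greater":
        # X ~ Hypergeom(total, a+c successes, a+b draws); tail at X >= a
        return float(sps.hypergeom.sf(a - 1, total, a + c, a + b))
    if alternative == "less":
        return float(sps.hypergeom.cdf(a, total, a + c, a + b))
    if alternative == "two-sided":
        return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    raise ValueError(f"unknown alternative {alternative!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (empty in, empty out)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return sps.false_discovery_control(p, method="bh")


def _window_params(regions_by_gene: Mapping[str, Sequence[RegionPair]]) -> tuple:
    params = {
        (r.use_far, r.use_near, r.dse_len)
        for regions in regions_by_gene.values()
        for r in regions
    }
    if len(params) > 1:
        raise ValueError(f"regions mix window parameters: {sorted(params)}")
    return params.pop() if params else ()


def compute_kmer_stats(
    target_by_gene: Mapping[str, Sequence[RegionPair]],
    bg_by_gene: Mapping[str, Sequence[RegionPair]],
    words: Sequence[str] | None = None,
    alternative: str = "greater",
) -> list[KmerStat]:
    """Per-word gene-occurrence counts, fractions, Fisher p and BH q.

    ``words`` defaults to the 47 distinct AUA-core 5-mers. Both region
    groups must have been extracted with identical window parameters.
    """
    if not target_by_gene or not bg_by_gene:
        raise ValueError("both gene groups must be non-empty")
    pt, pb = _window_params(target_by_gene), _window_params(bg_by_gene)
    if pt and pb and pt != pb:
        raise ValueError(f"window parameters differ between groups: {pt} vs {pb}")
    if words is None:
        words = distinct_aua_5mers()
    n_t, n_b = len(target_by_gene), len(bg_by_gene)
    sets_t: dict[int, dict] = {}
    sets_b: dict[int, dict] = {}
    stats: list[KmerStat] = []
    for w in words:
        k = len(w)
        if k not in sets_t:
            sets_t[k] = gene_kmer_sets(target_by_gene, k)
            sets_b[k] = gene_kmer_sets(bg_by_gene, k)
        a = sum(1 for s in sets_t[k].values() if w in s)
        c = sum(1 for s in sets_b[k].values() if w in s)
        p = fisher_exact(
            ContingencyTable(a, n_t - a, c, n_b - c), alternative=alternative
        )
        stats.append(
            KmerStat(
                word=w,
                n_target_genes_with=a,
                n_target_genes=n_t,
                n_bg_genes_with=c,
                n_bg_genes=n_b,
                target_fraction=a / n_t,
                bg_fraction=c / n_b,
                p_value=p,
            )
        )
    qs = bh_adjust([s.p_value for s in stats])
    for s, q in zip(stats, qs):
        s.q_value = float(q)
    return stats


def kmer_stats_frame(stats: Sequence[KmerStat], alpha: float = 0.05) -> pd.DataFrame:
    """Tabular view of k-mer statistics (one row per word)."""
    return pd.DataFrame(
        {
            "word": [s.word for s in stats],
            "a": [s.n_target_genes_with for s in stats],
            "b": [s.n_target_genes - s.n_target_genes_with for s in stats],
            "c": [s.n_bg_genes_with for s in stats],
            "d": [s.n_bg_genes - s.n_bg_genes_with for s in stats],
            "target_fraction": [s.target_fraction for s in stats],
            "bg_fraction": [s.bg_fraction for s in stats],
            "p": [s.p_value for s in stats],
            "q": [s.q_value for s in stats],
            "significant": [s.p_value < alpha for s in stats],
        }
    )


def compare_fractions(
    target_by_gene: Mapping[str, Sequence[RegionPair]],
    bg_by_gene: Mapping[str, Sequence[RegionPair]],
    words: Sequence[str] = (),
    alternative: str = "greater",
) -> pd.DataFrame:
    """Target vs background occurrence of the AUA core and tested words.

    Refuses region groups extracted with mismatched window parameters
    (silent incomparability would invalidate every fraction).
    """
    all_words = ["AUA", *[w for w in words if w != "AUA"]]
    stats = compute_kmer_stats(
        target_by_gene, bg_by_gene, words=all_words, alternative=alternative
    )
    df = kmer_stats_frame(stats)
    df.insert(
        df.columns.get_loc("p"),
        "difference",
        df["target_fraction"] - df["bg_fraction"],
    )
    return df
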