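"""Minimal visualisations: a sequence logo for the recognition-motif
PWM and the positional-occurrence histogram.

The logo is a small self-contained matplotlib renderer (stacked letter
glyphs scaled by per-column information content, the usual
2 - H(column) bits for a 4-letter alphabet)."""

from __future__ import annotations

import numpy as np

from .alphabet import RNA_BASES
from .kmers import MotifPWM, PositionalHistogram

_LETTER_COLORS = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "U": "#d62839"}


def plot_pwm_logo(pwm: MotifPWM, ax=None, information_scaled: bool = True):
    """Draw a sequence logo of the PWM; returns the matplotlib axes."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import PathPatch
    from matplotlib.text import TextPath
    from matplotlib.transforms import Affine2D

    if ax is None:
        _, ax = plt.subplots(figsize=(0.8 * pwm.width, 2.4))
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    info = 2.0 + plogp.sum(axis=0)  # bits per column
    for j in range(pwm.width):
        heights = p[:, j] * (info[j] if information_scaled else 1.0)
        y = 0.0
        for b in np.argsort(p[:, j]):  # small letters at the bottom
            h = heights[b]
            if h <= 0:
                continue
            letter = RNA_BASES[b]
            tp = TextPath((0, 0), letter, size=1.0)
            bbox = tp.get_extents()
            scale_x = 0.9 / bbox.width
            scale_y = h / bbox.height
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(scale_x, scale_y)
                .translate(j + 0.05, y)
            )
            ax.add_patch(
                PathPatch(
                    tp.transformed(transform),
                    facecolor=_LETTER_COLORS[letter],
                    edgecolor="none",
                )
            )
            y += h
    ax.set_xlim(0, pwm.width)
    ax.set_ylim(0, 2.0 if information_scaled else 1.05)
    ax.set_xticks(np.arange(pwm.width) + 0.5)
    ax.set_xticklabels(range(1, pwm.width + 1))
    ax.set_ylabel("bits" if information_scaled else "probability")
    ax.set_xlabel("motif position")
    return ax


def plot_positional_histogram(hist: PositionalHistogram, ax=None):
    """Bar plot of motif occurrences by upstream distance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 2.8))
    widths = np.diff(hist.bin_edges)
    ax.bar(
        hist.bin_edges[:-1],
        hist.counts,
        width=widths,
        align="edge",
        color="#255c99",
        edgecolor="white",
    )
    ax.set_xlabel("upstream distance from cleavage site (nt)")
    ax.set_ylabel("motif occurrences")
    return ax
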