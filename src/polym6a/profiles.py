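"""Signal profiling around anchor points and across scaled gene bodies.

Three profile geometries cover the figures this pipeline reproduces:
fixed windows around anchor points (e.g. m6A peak centers), scaled
TSS-to-TES gene bodies with fixed-width flanks, and the same two
geometries on weighted cytosine-methylation levels.  Windows running off
a chromosome end are truncated with per-bin weight bookkeeping (bins with
no covered bases are reported missing, never zero-filled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import CONTEXTS, SignalTrack


@dataclass
class Profile:
    """Mean signal per bin over a set of anchors or genes."""

    positions: np.ndarray  # bin centers in relative coordinates (or bin index)
    values: np.ndarray  # per-bin mean; nan where no data
    n_anchors: int
    stratum: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "value": self.values,
                             "n_anchors": self.n_anchors, "stratum": self.stratum})


def _bin_means(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Length-weighted per-bin sums and weights for one window.

    Bases are assigned to bins proportionally (bin i covers
    [i*L/n, (i+1)*L/n)); NaN values contribute no weight.
    """
    L = values.size
    idx = (np.arange(L) * n_bins) // max(L, 1)
    idx = np.minimum(idx, n_bins - 1)
    ok = np.isfinite(values)
    sums = np.bincount(idx[ok], weights=values[ok], minlength=n_bins)
    wts = np.bincount(idx[ok], minlength=n_bins).astype(float)
    return sums, wts


def profile_around_points(
    track: SignalTrack,
    anchors: list[tuple[str, int, str]],
    flank: int,
    n_bins: int = 100,
) -> Profile:
    """Mean signal in ``n_bins`` equal bins over [anchor-flank, anchor+flank).

    Anchors are (chrom, position, strand) triples; minus-strand windows
    are flipped so bins run 5' to 3'.  Windows beyond chromosome bounds
    are truncated and the affected bins weighted by covered bases only.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not anchors:
        raise ValueError("no anchors supplied")
    sums = np.zeros(n_bins)
    wts = np.zeros(n_bins)
    width = 2 * flank
    for chrom, pos, strand in anchors:
        size = track.chrom_sizes[chrom]
        lo, hi = pos - flank, pos + flank
        clo, chi = max(0, lo), min(size, hi)
        if clo >= chi:
            continue
        window = np.full(width, np.nan)
        window[clo - lo: chi - lo] = track.values(chrom, clo, chi)
        if strand == "-":
            window = window[::-1]
        s, w = _bin_means(window, n_bins)
        sums += s
        wts += w
    values = np.divide(sums, wts, out=np.full(n_bins, np.nan), where=wts > 0)
    centers = (np.arange(n_bins) + 0.5) * width / n_bins - flank
    return Profile(positions=centers, values=values, n_anchors=len(anchors))


def scaled_gene_profile(
    track: SignalTrack,
    transcripts: dict,
    body_bins: int = 100,
    flank: int = 2000,
    flank_bins: int = 50,
    strata: pd.Series | None = None,
) -> dict[str, Profile]:
    """Per-stratum mean profile over upstream flank, scaled gene body
    (TSS to TES rescaled to ``body_bins``), and downstream flank.

    ``strata`` maps gene_id to a stratum label; genes without a label go
    to stratum ``"all"``.  Genes shorter than ``body_bins`` nt are still
    rescaled (bins then share bases).
    """
    if body_bins < 10:
        raise ValueError("body_bins must be >= 10")
    total_bins = body_bins + 2 * flank_bins
    acc: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for gid, tx in transcripts.items():
        stratum = "all" if strata is None else str(strata.get(gid, "all"))
        size = track.chrom_sizes[tx.chrom]
        gs, ge = tx.span
        lo, hi = gs - flank, ge + flank
        clo, chi = max(0, lo), min(size, hi)
        window = np.full(hi - lo, np.nan)
        window[clo - lo: chi - lo] = track.values(tx.chrom, clo, chi)
        if tx.strand == "-":
            window = window[::-1]
        up, body, down = window[:flank], window[flank:flank + (ge - gs)], window[flank + (ge - gs):]
        parts = [_bin_means(up, flank_bins), _bin_means(body, body_bins),
                 _bin_means(down, flank_bins)]
        s = np.concatenate([p[0] for p in parts])
        w = np.concatenate([p[1] for p in parts])
        if stratum not in acc:
            acc[stratum] = (np.zeros(total_bins), np.zeros(total_bins), 0)
        S, W, n = acc[stratum]
        acc[stratum] = (S + s, W + w, n + 1)
    out = {}
    positions = np.arange(total_bins)
    for stratum, (S, W, n) in sorted(acc.items()):
        vals = np.divide(S, W, out=np.full(total_bins, np.nan), where=W > 0)
        out[stratum] = Profile(positions=positions, values=vals, n_anchors=n,
                               stratum=stratum)
    return out


def methylation_profile(
    methyl: pd.DataFrame,
    anchors: list[tuple[str, int, str]],
    context: str,
    flank: int = 2000,
    n_bins: int = 100,
) -> Profile:
    """Weighted methylation level per bin around anchor points.

    Level = sum(methylated) / sum(total) over sites of the requested
    context falling in the bin, pooling both strands; bins with zero total
    are missing.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    sub = methyl[methyl["context"] == context]
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)
    width = 2 * flank
    by_chrom = {c: g for c, g in sub.groupby("chrom")}
    for chrom, pos, strand in anchors:
        g = by_chrom.get(chrom)
        if g is None:
            continue
        p0 = g["pos"].to_numpy() - 1  # CX positions are 1-based
        rel = p0 - (pos - flank)
        ok = (rel >= 0) & (rel < width)
        if strand == "-":
            rel = width - 1 - rel
        idx = np.minimum((rel[ok] * n_bins) // width, n_bins - 1).astype(int)
        np.add.at(meth, idx, g["count_methylated"].to_numpy()[ok])
        np.add.at(total, idx, (g["count_methylated"] + g["count_unmethylated"]).to_numpy()[ok])
    values = np.divide(meth, total, out=np.full(n_bins, np.nan), where=total > 0)
    centers = (np.arange(n_bins) + 0.5) * width / n_bins - flank
    return Profile(positions=centers, values=values, n_anchors=len(anchors))


def plot_profiles(profs: list[Profile], path: str, xlabel: str = "position",
                  ylabel: str = "mean signal") -> None:
    """Simple line plot of one or more profiles to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profs:
        ax.plot(p.positions, p.values, label=p.stratum or None)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if any(p.stratum for p in profs):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def peak_centers(peaks, transcripts) -> list[tuple[str, int, str]]:
    """Genomic midpoints of peaks as (chrom, pos, strand) anchor triples."""
    anchors = []
    for p in peaks:
        tx = transcripts[p.gene_id]
        mid_t = (p.tx_start + p.tx_end) // 2
        mid_g = tx.transcript_to_genomic(min(mid_t, tx.mature_length - 1))
        anchors.append((p.chrom, mid_g, tx.strand))
    return anchors
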