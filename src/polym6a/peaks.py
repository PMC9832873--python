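"""m6A peak calling from IP versus input coverage.

Windows slide along each mature transcript (so spliced genes are handled
exactly); each window's IP count is tested against an input-derived
Poisson rate scaled by the IP/input library-size ratio.  Windows passing
the (BH-adjusted by default) p-value gate and a fold-enrichment gate are
merged into peaks.  Replicate peak sets are reduced to a consensus by
overlap support; differential methylation between genotypes is a
per-consensus-peak Fisher exact test with the fold-change >= 2 and
p < 1e-4 gates applied on normalized enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import Peak, TranscriptModel

#: pseudocount in fold-enrichment ratios
EPS = 0.5

DM_FC_MIN = 2.0
DM_P_MAX = 1e-4


@dataclass(frozen=True)
class WindowTest:
    gene_id: str
    start: int  # transcript coordinates
    end: int
    ip_count: float
    input_count: float
    scaled_lambda: float
    p_value: float
    fold: float


@dataclass
class DifferentialPeak:
    peak_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    log2fc: float
    p_value: float
    direction: str  # "hyper" | "hypo" | "ns" | "untestable"


def _transcript_coverage(track, tx: TranscriptModel) -> np.ndarray:
    """Per-base coverage along the mature transcript, 5' to 3'."""
    parts = [track.values(tx.chrom, s, e) for s, e in tx.exons]
    arr = np.concatenate(parts)
    if tx.strand == "-":
        arr = arr[::-1]
    return arr


def _windows(L: int, w: int, step: int) -> list[tuple[int, int]]:
    if L <= w:
        return [(0, L)]
    starts = list(range(0, L - w + 1, step))
    if starts[-1] + w < L:
        starts.append(L - w)
    return [(s, s + w) for s in starts]


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_peaks(
    ip_track,
    input_track,
    transcripts: dict[str, TranscriptModel],
    w: int = 150,
    step: int = 50,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    raw_p: bool = False,
    ip_library_size: float | None = None,
    input_library_size: float | None = None,
) -> list[Peak]:
    """Call peaks on every transcript from one IP/input track pair.

    Library sizes default to the tracks' genome-wide totals.  Windows with
    adjusted p < alpha (raw p when ``raw_p``) AND fold >= fc_min are
    merged when overlapping or within ``step`` nt; the merged peak's
    summit is the center of its minimal-p window (5'-most on ties) and its
    p/fold are those of that window.  Transcripts with zero input coverage
    are skipped.
    """
    ip_lib = ip_library_size if ip_library_size is not None else ip_track.total
    in_lib = input_library_size if input_library_size is not None else input_track.total
    if ip_lib <= 0 or in_lib <= 0:
        raise ValueError("library sizes must be positive")
    ratio = ip_lib / in_lib

    tests: list[WindowTest] = []
    skipped: list[str] = []
    for gid, tx in transcripts.items():
        ip_cov = _transcript_coverage(ip_track, tx)
        in_cov = _transcript_coverage(input_track, tx)
        if in_cov.sum() == 0:
            skipped.append(gid)
            continue
        ip_cum = np.concatenate([[0.0], np.cumsum(ip_cov)])
        in_cum = np.concatenate([[0.0], np.cumsum(in_cov)])
        for s, e in _windows(tx.mature_length, w, step):
            ip_n = float(ip_cum[e] - ip_cum[s])
            in_n = float(in_cum[e] - in_cum[s])
            lam = in_n * ratio
            p = float(sps.poisson.sf(ip_n - 1, lam)) if lam > 0 else (1.0 if ip_n == 0 else 0.0)
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            fold = (ip_n + EPS) / (lam + EPS)
            tests.append(WindowTest(gid, s, e, ip_n, in_n, lam, p, fold))
    if skipped:
        import warnings

        warnings.warn(f"{len(skipped)} transcripts with zero input coverage skipped",
                      stacklevel=2)
    if not tests:
        return []

    pvals = np.array([t.p_value for t in tests])
    gate_p = pvals if raw_p else benjamini_hochberg(pvals)
    peaks: list[Peak] = []
    by_gene: dict[str, list[WindowTest]] = {}
    for t, gp in zip(tests, gate_p):
        if gp < alpha and t.fold >= fc_min:
            by_gene.setdefault(t.gene_id, []).append(t)
    for gid, wins in by_gene.items():
        tx = transcripts[gid]
        wins.sort(key=lambda t: t.start)
        cluster: list[WindowTest] = []
        for t in wins + [None]:
            if t is not None and (not cluster or t.start <= cluster[-1].end + step):
                cluster.append(t)
                continue
            if cluster:
                peaks.append(_merge_cluster(cluster, tx))
            cluster = [t] if t is not None else []
    return peaks


def _merge_cluster(cluster: list, tx: TranscriptModel) -> Peak:
    s = min(t.start for t in cluster)
    e = max(t.end for t in cluster)
    best = min(cluster, key=lambda t: (t.p_value, t.start))  # 5'-most on ties
    summit = (best.start + best.end) // 2
    blocks = tx.transcript_interval_to_genomic(s, e)
    return Peak(
        gene_id=tx.gene_id, chrom=tx.chrom,
        start=blocks[0][0], end=blocks[-1][1],
        tx_start=s, tx_end=e,
        summit=min(summit, tx.mature_length - 1),
        fold_enrichment=best.fold, p_value=best.p_value,
    )


def consensus_peaks(replicate_sets: list[list[Peak]], min_support: int = 2) -> list[Peak]:
    """Reduce replicate peak sets to consensus peaks.

    Peaks from different replicates on the same gene that overlap (single
    linkage in transcript coordinates) form a cluster; clusters supported
    by >= ``min_support`` distinct replicates are kept.  The consensus
    interval is the intersection of the supporting peaks and the summit is
    the median of their summits.
    """
    if min_support > len(replicate_sets):
        raise ValueError(
            f"min_support={min_support} exceeds {len(replicate_sets)} replicates")
    by_gene: dict[str, list[tuple[int, Peak]]] = {}
    for rep, peaks in enumerate(replicate_sets):
        for p in peaks:
            by_gene.setdefault(p.gene_id, []).append((rep, p))
    out: list[Peak] = []
    for gid, items in by_gene.items():
        items.sort(key=lambda rp: rp[1].tx_start)
        cluster: list[tuple[int, Peak]] = []
        hi = -1
        for rp in items + [None]:
            if rp is not None and (not cluster or rp[1].tx_start < hi):
                cluster.append(rp)
                hi = max(hi, rp[1].tx_end)
                continue
            if cluster:
                cp = _consensus_of(cluster, min_support)
                if cp is not None:
                    out.append(cp)
            if rp is not None:
                cluster, hi = [rp], rp[1].tx_end
    return out


def _consensus_of(cluster: list[tuple[int, "Peak"]], min_support: int):
    reps = {rep for rep, _ in cluster}
    if len(reps) < min_support:
        return None
    peaks = [p for _, p in cluster]
    s = max(p.tx_start for p in peaks)
    e = min(p.tx_end for p in peaks)
    if e <= s:  # single-linkage chain without a common core: fall back to union
        s = min(p.tx_start for p in peaks)
        e = max(p.tx_end for p in peaks)
    summit = int(np.median([p.summit for p in peaks]))
    summit = min(max(summit, s), e - 1) if s < e else summit
    ref = min(peaks, key=lambda p: p.p_value)
    return Peak(
        gene_id=ref.gene_id, chrom=ref.chrom,
        start=min(p.start for p in peaks), end=max(p.end for p in peaks),
        tx_start=s, tx_end=e, summit=summit,
        fold_enrichment=float(np.mean([p.fold_enrichment for p in peaks])),
        p_value=ref.p_value,
    )


def differential_methylation(
    peaks: list[Peak],
    ip_a, input_a, ip_b, input_b,
    transcripts: dict[str, TranscriptModel],
    fc_min: float = DM_FC_MIN,
    p_max: float = DM_P_MAX,
) -> list[DifferentialPeak]:
    """Per-peak differential methylation between genotypes A and B.

    For each peak (normally the union of both genotypes' consensus sets),
    IP and input counts over the peak's transcript interval are summed for
    each genotype and tested with Fisher's exact test on the 2x2 table
    [[ipA, inputA], [ipB, inputB]].  The fold change is the ratio of
    library-normalized IP/input enrichments (B relative to A); a peak is
    flagged hyper/hypo only if |log2FC| >= log2(fc_min) and p < p_max.
    """
    libs = {
        "ip_a": ip_a.total, "in_a": input_a.total,
        "ip_b": ip_b.total, "in_b": input_b.total,
    }
    out = []
    for i, p in enumerate(peaks):
        tx = transcripts[p.gene_id]
        counts = {}
        for name, track in (("ip_a", ip_a), ("in_a", input_a), ("ip_b", ip_b), ("in_b", input_b)):
            cov = _transcript_coverage(track, tx)[p.tx_start:p.tx_end]
            counts[name] = float(cov.sum())
        pid = f"peak_{i}_{p.gene_id}"
        table = np.array([[counts["ip_a"], counts["in_a"]],
                          [counts["ip_b"], counts["in_b"]]])
        if table.sum() == 0:
            out.append(DifferentialPeak(pid, p.gene_id, p.chrom, p.start, p.end,
                                        float("nan"), float("nan"), "untestable"))
            continue
        e_a = ((counts["ip_a"] + EPS) / libs["ip_a"]) / ((counts["in_a"] + EPS) / libs["in_a"])
        e_b = ((counts["ip_b"] + EPS) / libs["ip_b"]) / ((counts["in_b"] + EPS) / libs["in_b"])
        lfc = float(np.log2(e_b / e_a))
        _, pv = sps.fisher_exact(np.round(table).astype(int))
        flagged = abs(lfc) >= np.log2(fc_min) and pv < p_max
        direction = "ns" if not flagged else ("hyper" if lfc > 0 else "hypo")
        out.append(DifferentialPeak(pid, p.gene_id, p.chrom, p.start, p.end,
                                    lfc, float(pv), direction))
    return out


def dm_frame(dms: list[DifferentialPeak]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in dms])


def qc_replicate_correlation(tracks: list, bin_size: int = 1000) -> pd.DataFrame:
    """Pairwise Spearman correlation of binned coverage between tracks."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    binned = [t.binned(bin_size) for t in tracks]
    n = len(binned)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        mat[i, i] = 1.0 if np.ptp(binned[i]) > 0 else np.nan
        for j in range(i + 1, n):
            if np.ptp(binned[i]) == 0 or np.ptp(binned[j]) == 0:
                continue  # constant track: correlation undefined
            rho, _ = sps.spearmanr(binned[i], binned[j])
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat)
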