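"""Transcript geometry: representative transcripts, the five-segment
partition of an mRNA, and peak localization along it.

An mRNA is partitioned into five contiguous segments in mature-transcript
coordinates: the 5' UTR, a 200-nt window centered on the translational
start codon (``startC``), the coding sequence, a 200-nt window centered on
the translational stop codon (``stopC``), and the 3' UTR.  m6A peaks are
localized to a single segment by their summit, and enrichment is measured
relative to the fraction of aggregate transcript length each segment
occupies.

All internal coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

SEGMENTS = ("5UTR", "startC", "CDS", "stopC", "3UTR")

#: default bins per segment for metagene profiles (sums to 110)
DEFAULT_BINS = (10, 20, 50, 20, 10)

#: half-width of the startC/stopC windows (200 bp centered on the codon)
CODON_WINDOW_HALF = 100


class AnnotationError(ValueError):
    """Raised for malformed annotation or out-of-range coordinates."""


@dataclass
class TranscriptModel:
    """Exon/CDS geometry of one representative mRNA.

    Parameters
    ----------
    gene_id, transcript_id : str
        Identifiers from the annotation.
    chrom : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : list of (start, end)
        Genomic intervals, 0-based half-open, sorted by genomic start,
        non-overlapping.
    cds_start, cds_end : int
        Genomic bounds of the CDS (0-based half-open, cds_start < cds_end).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons {((s1, e1), (s2, e2))}"
                )
        self.exons = exons
        lengths = np.array([e - s for s, e in exons], dtype=int)
        self._cum = np.concatenate([[0], np.cumsum(lengths)])

    @property
    def mature_length(self) -> int:
        return int(self._cum[-1])

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def tes(self) -> int:
        """Genomic coordinate of the transcription end site."""
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the full gene body."""
        return self.exons[0][0], self.exons[-1][1]

    # -- coordinate maps ---------------------------------------------------
    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position (must fall in an exon) to a transcript
        position; position 0 is the 5' end regardless of strand."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                t_plus = self._cum[i] + (pos - s)
                if self.strand == "+":
                    return int(t_plus)
                return int(self.mature_length - 1 - t_plus)
        raise AnnotationError(f"genomic position {pos} not exonic in {self.transcript_id}")

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript`."""
        if not 0 <= tpos < self.mature_length:
            raise AnnotationError(f"transcript position {tpos} outside [0, {self.mature_length})")
        t_plus = tpos if self.strand == "+" else self.mature_length - 1 - tpos
        i = int(np.searchsorted(self._cum, t_plus, side="right")) - 1
        s, _ = self.exons[i]
        return int(s + (t_plus - self._cum[i]))

    def transcript_interval_to_genomic(self, tstart: int, tend: int) -> list[tuple[int, int]]:
        """Project a transcript interval [tstart, tend) onto genomic exon
        blocks (0-based half-open, sorted by genomic start)."""
        if tend <= tstart:
            return []
        g1 = self.transcript_to_genomic(tstart)
        g2 = self.transcript_to_genomic(tend - 1)
        lo, hi = (g1, g2 + 1) if g1 <= g2 else (g2, g1 + 1)
        blocks = []
        for s, e in self.exons:
            bs, be = max(s, lo), min(e, hi)
            if bs < be:
                blocks.append((bs, be))
        return blocks

    @property
    def cds_transcript_interval(self) -> tuple[int, int]:
        """CDS as a [start, end) interval in transcript coordinates."""
        if self.strand == "+":
            a = self.genomic_to_transcript(self.cds_start)
            b = self.genomic_to_transcript(self.cds_end - 1) + 1
        else:
            a = self.genomic_to_transcript(self.cds_end - 1)
            b = self.genomic_to_transcript(self.cds_start) + 1
        return a, b

    @property
    def exon_length(self) -> int:
        return self.mature_length

    @property
    def intron_length(self) -> int:
        s, e = self.span
        return (e - s) - self.mature_length

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class SegmentMap:
    """Five-segment partition of one transcript, in transcript coordinates.

    Stores the four internal boundaries ``a <= b <= c <= d`` so that
    5UTR=[0,a), startC=[a,b), CDS=[b,c), stopC=[c,d), 3UTR=[d,L).
    """

    gene_id: str
    mature_length: int
    bounds: tuple[int, int, int, int]

    @property
    def intervals(self) -> dict[str, tuple[int, int]]:
        a, b, c, d = self.bounds
        return {
            "5UTR": (0, a),
            "startC": (a, b),
            "CDS": (b, c),
            "stopC": (c, d),
            "3UTR": (d, self.mature_length),
        }

    @property
    def lengths(self) -> dict[str, int]:
        return {k: e - s for k, (s, e) in self.intervals.items()}

    def segment_of(self, tpos: int) -> str:
        if not 0 <= tpos < self.mature_length:
            raise AnnotationError(
                f"{self.gene_id}: position {tpos} outside [0, {self.mature_length})"
            )
        for name, (s, e) in self.intervals.items():
            if s <= tpos < e:
                return name
        raise AssertionError("unreachable: segments partition the transcript")


@dataclass
class Peak:
    """A called m6A interval on one transcript."""

    gene_id: str
    chrom: str
    start: int  # genomic, 0-based half-open bounding interval
    end: int
    tx_start: int  # transcript coordinates
    tx_end: int
    summit: int  # transcript coordinate of max enrichment
    fold_enrichment: float
    p_value: float
    segment_label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak start {self.start} >= end {self.end}")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be > 0")

    @property
    def summit_genomic(self) -> int | None:
        return None


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_annotation(gff3_path: str) -> dict[str, TranscriptModel]:
    """Parse a GFF3 file into one representative :class:`TranscriptModel`
    per gene.

    The representative mRNA is the one with the longest CDS; ties break to
    the longest mature transcript, then to the lexicographically smallest
    mRNA id.  mRNAs without CDS features are ignored; a gene whose mRNAs
    all lack CDS is skipped with a warning.
    """
    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, TranscriptModel] = {}
    for gene in db.features_of_type("gene"):
        best: TranscriptModel | None = None
        best_key: tuple | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not cds or not exons:
                continue
            cds_len = sum(e - s for s, e in cds)
            tm = TranscriptModel(
                gene_id=gene.id,
                transcript_id=mrna.id,
                chrom=gene.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds),
                cds_end=max(e for _, e in cds),
            )
            # sort key: prefer longest CDS, then longest mature, then smallest id
            key = (-cds_len, -tm.mature_length, mrna.id)
            if best_key is None or key < best_key:
                best, best_key = tm, key
        if best is None:
            warnings.warn(f"gene {gene.id} has no mRNA with CDS; skipped", stacklevel=2)
            continue
        models[gene.id] = best
    return models


# ---------------------------------------------------------------------------
# five-segment partition
# ---------------------------------------------------------------------------

def five_segments(tx: TranscriptModel) -> SegmentMap:
    """Partition a transcript into 5UTR / startC / CDS / stopC / 3UTR.

    startC and stopC are each 200 nt centered on the first base of the
    start and stop codons (interpreted as +/-100 nt around that base),
    clipped to the transcript; they take priority over UTR/CDS, and stopC
    takes priority over startC when the CDS is shorter than 200 nt.
    """
    L = tx.mature_length
    cds_a, cds_b = tx.cds_transcript_interval
    s = cds_a  # first base of the start codon
    t = cds_b - 3  # first base of the stop codon
    h = CODON_WINDOW_HALF

    def clamp(x: int, lo: int = 0, hi: int = L) -> int:
        return max(lo, min(hi, x))

    c = clamp(t - h)
    d = clamp(t + h)
    a = clamp(s - h, 0, c)
    b = clamp(s + h, a, c)
    return SegmentMap(gene_id=tx.gene_id, mature_length=L, bounds=(a, b, c, d))


def assign_peak(peak: Peak, segmap: SegmentMap) -> str:
    """Label a peak by the segment containing its summit (single label)."""
    label = segmap.segment_of(peak.summit)
    peak.segment_label = label
    return label


def relative_enrichment(
    peaks: list[Peak], segmaps: dict[str, SegmentMap]
) -> pd.DataFrame:
    """Per-segment enrichment of peak summits relative to segment length.

    score(seg) = (fraction of summits in seg) / (fraction of aggregate
    transcript length in seg).  1 means no enrichment.  Segments with zero
    aggregate length get a missing score.
    """
    if not peaks:
        raise ValueError("relative_enrichment requires at least one peak")
    total_len = {seg: 0 for seg in SEGMENTS}
    for sm in segmaps.values():
        for seg, ln in sm.lengths.items():
            total_len[seg] += ln
    agg = sum(total_len.values())
    counts = {seg: 0 for seg in SEGMENTS}
    for p in peaks:
        seg = p.segment_label or assign_peak(p, segmaps[p.gene_id])
        counts[seg] += 1
    n = len(peaks)
    rows = []
    for seg in SEGMENTS:
        len_frac = total_len[seg] / agg
        cnt_frac = counts[seg] / n
        score = cnt_frac / len_frac if len_frac > 0 else np.nan
        rows.append((seg, counts[seg], cnt_frac, total_len[seg], len_frac, score))
    return pd.DataFrame(
        rows,
        columns=["segment", "n_peaks", "peak_fraction", "length", "length_fraction", "enrichment"],
    ).set_index("segment")


def metagene_peak_density(
    peaks: list[Peak],
    segmaps: dict[str, SegmentMap],
    bins_per_segment: tuple[int, int, int, int, int] = DEFAULT_BINS,
) -> np.ndarray:
    """Metagene density of peak summits over the five rescaled segments.

    Each transcript's segments are rescaled to the fixed bin counts; a peak
    contributes its summit to exactly one bin.  The returned vector sums to
    1 (or is all zero, with a warning, when there are no peaks).
    """
    if any(b < 1 for b in bins_per_segment):
        raise ValueError("bins_per_segment entries must be >= 1")
    offsets = np.concatenate([[0], np.cumsum(bins_per_segment)])
    total_bins = int(offsets[-1])
    hist = np.zeros(total_bins)
    if not peaks:
        warnings.warn("no peaks: metagene profile is all zero", stacklevel=2)
        return hist
    for p in peaks:
        sm = segmaps[p.gene_id]
        for i, seg in enumerate(SEGMENTS):
            s, e = sm.intervals[seg]
            if s <= p.summit < e:
                nb = bins_per_segment[i]
                j = int((p.summit - s) / (e - s) * nb)
                hist[offsets[i] + min(j, nb - 1)] += 1
                break
    return hist / hist.sum()


def segment_density_mass(
    profile: np.ndarray,
    bins_per_segment: tuple[int, int, int, int, int] = DEFAULT_BINS,
) -> dict[str, float]:
    """Collapse a metagene profile to total density mass per segment."""
    offsets = np.concatenate([[0], np.cumsum(bins_per_segment)])
    return {
        seg: float(profile[offsets[i]: offsets[i + 1]].sum())
        for i, seg in enumerate(SEGMENTS)
    }
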