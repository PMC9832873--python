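"""Stepwise-constant genomic signal tracks and their text formats.

A :class:`SignalTrack` holds per-base coverage as dense numpy arrays per
chromosome (the synthetic genomes used here are small enough that a dense
representation is both the simplest and the fastest).  bedGraph I/O uses
0-based half-open intervals and run-length encodes on write; cytosine
methylation tables use the Bismark CX-report layout (chrom, 1-based
position, strand, context, methylated count, unmethylated count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CX_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_unmethylated"]
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class SignalTrack:
    """Per-base signal over one or more chromosomes."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    @property
    def total(self) -> float:
        """Sum of signal over the genome (library size for count tracks)."""
        return float(sum(a.sum() for a in self.data.values()))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); out-of-bounds is an error
        (callers handle truncation explicitly)."""
        arr = self.data[chrom]
        if start < 0 or end > len(arr):
            raise IndexError(f"window [{start},{end}) outside {chrom} [0,{len(arr)})")
        return arr[start:end]

    # ------------------------------------------------------------------
    @classmethod
    def from_bedgraph(cls, path: str, chrom_sizes: dict[str, int]) -> "SignalTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"], comment="#")
        data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
        for chrom, sub in df.groupby("chrom"):
            if chrom not in data:
                raise KeyError(f"bedGraph chrom {chrom!r} not in chrom sizes")
            arr = data[chrom]
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                arr[s:e] = v
        return cls(data)

    def to_bedgraph(self, path: str) -> None:
        """Run-length-encoded 4-column bedGraph; zero runs are skipped."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                arr = self.data[chrom]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [arr.size]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v == 0:
                        continue
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def binned(self, bin_size: int) -> np.ndarray:
        """Genome-wide fixed-bin sums, concatenated across chromosomes in
        sorted chromosome order (used by replicate QC)."""
        parts = []
        for chrom in sorted(self.data):
            arr = self.data[chrom]
            n = (len(arr) + bin_size - 1) // bin_size
            padded = np.zeros(n * bin_size)
            padded[:len(arr)] = arr
            parts.append(padded.reshape(n, bin_size).sum(axis=1))
        return np.concatenate(parts)


def read_cx_report(path: str) -> pd.DataFrame:
    """Read a CX-style cytosine report into a MethylationTable frame."""
    df = pd.read_csv(path, sep="\t", header=None, names=CX_COLUMNS)
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(f"unknown contexts {sorted(df.loc[bad, 'context'].unique())}")
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        raise ValueError("negative counts in CX report")
    return df


def write_cx_report(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            chrom, size = line.split()
            out[chrom] = int(size)
    return out
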