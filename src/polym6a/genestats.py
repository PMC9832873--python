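"""Gene-level m6A status and the base statistical tests.

Genes are split into m6A genes (carrying at least one consensus peak on
the representative transcript) and non-m6A genes, and their sequence
features and expression are compared with a Wilcoxon rank-sum test.  The
rank-sum test and Pearson's chi-square test are implemented here so their
exact small-sample behaviour is fully specified and desk-checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

#: largest combined sample size for which the exact null enumeration runs
EXACT_N_MAX = 12

FEATURES = ("gene_length", "exon_length", "intron_length", "exon_number", "FPKM")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class GeneM6AStatus:
    gene_id: str
    genotype: str
    status: str  # "m6A" | "non_m6A"
    n_peaks: int


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    median_m6a: float
    median_non: float
    n_m6a: int
    n_non: int
    statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and tie-group sizes."""
    ranks = sps.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses mid-ranks for ties.  The null distribution is enumerated exactly
    when ``len(x)+len(y) <= 12`` and there are no ties across the pooled
    sample; otherwise a normal approximation with tie and continuity
    corrections is used.  If every pooled value is identical, p = 1.

    Returns the Mann-Whitney U statistic of ``x`` and the two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks, tie_counts = _rank_with_ties(pooled)
    rank_sum_x = float(ranks[:nx].sum())
    u = rank_sum_x - nx * (nx + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=u, p_value=1.0, method="degenerate")

    has_ties = np.any(tie_counts > 1)
    if nx + ny <= EXACT_N_MAX and not has_ties:
        return TestResult(u, _exact_two_sided_p(ranks, nx), "exact")

    n = nx + ny
    mean_u = nx * ny / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return TestResult(u, 1.0, "degenerate")
    # continuity correction toward the mean
    z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(u, float(min(1.0, p)), "normal")


def _exact_two_sided_p(ranks: np.ndarray, nx: int) -> float:
    """Exact two-sided p: 2 * min(tail) over all C(n, nx) labelings."""
    n = ranks.size
    observed = float(ranks[:nx].sum())
    le = ge = 0
    for idx in combinations(range(n), nx):
        w = float(ranks[list(idx)].sum())
        if w <= observed + 1e-9:
            le += 1
        if w >= observed - 1e-9:
            ge += 1
    total = comb(n, nx)
    return min(1.0, 2.0 * min(le, ge) / total)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def chi_square_test(table, yates: bool = False) -> TestResult:
    """Pearson's chi-square test of independence on an r x c count table.

    No continuity correction by default; ``yates=True`` enables the Yates
    correction for 2x2 tables.  A zero row or column marginal is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(stat, float(sps.chi2.sf(stat, df)), f"pearson_df{df}")


# ---------------------------------------------------------------------------
# gene classification and feature comparison
# ---------------------------------------------------------------------------

def classify_m6a_genes(peaks, transcripts, genotype: str) -> list[GeneM6AStatus]:
    """Assign every annotated gene an m6A / non-m6A status for one genotype
    from its consensus peak count."""
    counts: dict[str, int] = {g: 0 for g in transcripts}
    for p in peaks:
        if p.gene_id not in counts:
            raise KeyError(f"peak assigned to unknown gene {p.gene_id!r}")
        counts[p.gene_id] += 1
    return [
        GeneM6AStatus(g, genotype, "m6A" if n >= 1 else "non_m6A", n)
        for g, n in counts.items()
    ]


def status_frame(statuses: list[GeneM6AStatus]) -> pd.DataFrame:
    df = pd.DataFrame([(s.gene_id, s.genotype, s.status, s.n_peaks) for s in statuses],
                      columns=["gene_id", "genotype", "status", "n_peaks"])
    return df


def compare_features(
    statuses: list[GeneM6AStatus],
    transcripts,
    fpkm: pd.DataFrame | None = None,
) -> list[FeatureComparison]:
    """Wilcoxon comparison of sequence features (and optionally mean FPKM)
    between m6A and non-m6A genes.

    Intron length of intronless genes is 0.  Genes missing a feature are
    excluded from that feature's test (with a warning if >10% are missing).
    """
    feats: dict[str, dict[str, float]] = {}
    for gid, tx in transcripts.items():
        s, e = tx.span
        feats[gid] = {
            "gene_length": e - s,
            "exon_length": tx.exon_length,
            "intron_length": tx.intron_length,
            "exon_number": tx.n_exons,
        }
    if fpkm is not None:
        mean_fpkm = fpkm.mean(axis=1)
        for gid in feats:
            if gid in mean_fpkm.index:
                feats[gid]["FPKM"] = float(mean_fpkm.loc[gid])

    m6a_ids = [s.gene_id for s in statuses if s.status == "m6A"]
    non_ids = [s.gene_id for s in statuses if s.status == "non_m6A"]
    out = []
    feature_names = FEATURES if fpkm is not None else FEATURES[:-1]
    for feat in feature_names:
        xs = np.array([feats[g][feat] for g in m6a_ids if feat in feats.get(g, {})])
        ys = np.array([feats[g][feat] for g in non_ids if feat in feats.get(g, {})])
        n_total = len(m6a_ids) + len(non_ids)
        if xs.size + ys.size < 0.9 * n_total:
            warnings.warn(f"feature {feat}: >10% of genes missing; excluded from test",
                          stacklevel=2)
        if xs.size == 0 or ys.size == 0:
            continue
        res = wilcoxon_rank_sum(xs, ys)
        out.append(FeatureComparison(
            feature=feat,
            median_m6a=float(np.median(xs)),
            median_non=float(np.median(ys)),
            n_m6a=xs.size,
            n_non=ys.size,
            statistic=res.statistic,
            p_value=res.p_value,
        ))
    return out
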