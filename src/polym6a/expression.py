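"""Expression quantification, differential expression, expression
divergence of duplicate pairs, and DM x DE integration.

FPKM = count * 1e9 / (transcript length in nt * library size).
Differential expression uses a replicate-level Wilcoxon rank-sum test on
FPKM plus a fold-change gate (significant iff p <= 0.05 and
|log2FC| >= 1); an externally computed DE table can be plugged in instead.
Expression divergence of a duplicate pair is ED = |E1-E2|/(E1+E2) on
genotype-mean FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genestats import wilcoxon_rank_sum

#: FPKM pseudocount used in log2 fold changes
FPKM_PSEUDO = 0.5

DE_P_MAX = 0.05
DE_LFC_MIN = 1.0


@dataclass(frozen=True)
class EDResult:
    pair_id: str
    e1: float
    e2: float
    ed: float  # nan when e1 + e2 == 0


def fpkm(counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series | None = None
         ) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``lengths`` is the mature transcript length in nt per gene; library
    sizes default to column sums.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise KeyError(f"missing transcript lengths for genes {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e9 / np.outer(lengths, library_sizes)


def differential_expression(
    fpkm_ref: pd.DataFrame,
    fpkm_test: pd.DataFrame,
    p_max: float = DE_P_MAX,
    lfc_min: float = DE_LFC_MIN,
) -> pd.DataFrame:
    """Per-gene DE between two genotypes from replicate-level FPKM.

    log2FC = log2((mean_test + 0.5) / (mean_ref + 0.5)); p from the
    Wilcoxon rank-sum test on replicate FPKM (exact enumeration at 3 vs 3).
    A gene is flagged iff p <= p_max and |log2FC| >= lfc_min; ``category``
    is up / down / unchanged relative to the test genotype.
    """
    if fpkm_ref.shape[1] < 2 or fpkm_test.shape[1] < 2:
        raise ValueError("need >= 2 replicates per genotype")
    common = fpkm_ref.index.intersection(fpkm_test.index)
    rows = []
    for g in common:
        a = fpkm_ref.loc[g].to_numpy(dtype=float)
        b = fpkm_test.loc[g].to_numpy(dtype=float)
        lfc = float(np.log2((b.mean() + FPKM_PSEUDO) / (a.mean() + FPKM_PSEUDO)))
        p = wilcoxon_rank_sum(a, b).p_value
        sig = p <= p_max and abs(lfc) >= lfc_min
        cat = "unchanged" if not sig else ("up" if lfc > 0 else "down")
        rows.append({"gene_id": g, "log2fc": lfc, "p_value": p,
                     "significant": sig, "category": cat})
    return pd.DataFrame(rows).set_index("gene_id")


def expression_divergence(
    pairs: pd.DataFrame, mean_fpkm: pd.Series
) -> list[EDResult]:
    """ED = |E1-E2|/(E1+E2) per duplicate pair on genotype-mean FPKM.

    ``pairs`` needs columns pair_id, gene1, gene2.  Pairs with
    E1 + E2 == 0 get a missing ED; negative expression is an error.
    """
    out = []
    for row in pairs.itertuples(index=False):
        e1 = float(mean_fpkm.get(row.gene1, np.nan))
        e2 = float(mean_fpkm.get(row.gene2, np.nan))
        if e1 < 0 or e2 < 0:
            raise ValueError(f"negative expression for pair {row.pair_id}")
        tot = e1 + e2
        ed = abs(e1 - e2) / tot if tot > 0 else float("nan")
        out.append(EDResult(row.pair_id, e1, e2, ed))
    return out


def ed_frame(results: list[EDResult]) -> pd.DataFrame:
    return pd.DataFrame([(r.pair_id, r.e1, r.e2, r.ed) for r in results],
                        columns=["pair_id", "E1", "E2", "ED"]).set_index("pair_id")


def integrate_dm_de(dm_peaks: pd.DataFrame, de: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate differential methylation with differential expression.

    ``dm_peaks`` needs columns gene_id, direction (hyper/hypo); ``de`` is
    the output of :func:`differential_expression`.  A gene carrying both a
    hyper and a hypo peak is counted in both rows.  Returns a
    (hyper, hypo) x (up, down, unchanged) count table.
    """
    cats = ("up", "down", "unchanged")
    tab = pd.DataFrame(0, index=["hyper", "hypo"], columns=list(cats))
    if dm_peaks.empty:
        return tab
    seen = dm_peaks.drop_duplicates(subset=["gene_id", "direction"])
    for row in seen.itertuples(index=False):
        cat = de["category"].get(row.gene_id, "unchanged")
        tab.loc[row.direction, cat] += 1
    return tab
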