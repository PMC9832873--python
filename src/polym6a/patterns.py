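"""Cross-genotype m6A pattern taxonomy and gene-class stratification.

Genes are classified into four patterns between a reference and a test
genotype: I (methylated in both), II (methylated in neither), III
(methylated in the reference only — loss), IV (methylated in the test
only — gain).  Duplicate pairs are classified within one genotype as IM
(both members methylated), DM (exactly one), or NM (neither).  For
comparisons of the two diploid parents against a polyploid, each
subgenome gene's reference status is taken from its parent of origin
(A_n from A, C_n from C).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genestats import chi_square_test

PATTERNS = ("I", "II", "III", "IV")
PAIR_PATTERNS = ("IM", "DM", "NM")

STRATA_KEYS = ("subgenome", "duplication_status", "dup_type", "dosage", "genotype")


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PatternSummary:
    comparison: str
    counts: dict[str, int]
    percentages: dict[str, float]


def pattern_summary_from_counts(counts: dict[str, int], comparison: str = "") -> PatternSummary:
    """Percentages (rounded half-up to one decimal) from pattern counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty pattern counts")
    pct = {p: _round_half_up(100.0 * counts.get(p, 0) / total) for p in PATTERNS}
    return PatternSummary(comparison, {p: counts.get(p, 0) for p in PATTERNS}, pct)


def classify_patterns(
    status_ref: pd.Series, status_test: pd.Series, comparison: str = ""
) -> tuple[pd.Series, PatternSummary]:
    """Assign every gene one of patterns I-IV from boolean m6A statuses.

    Both series must be boolean and cover exactly the same gene universe.
    Returns the per-gene labels and a count/percentage summary.
    """
    only_ref = status_ref.index.difference(status_test.index)
    only_test = status_test.index.difference(status_ref.index)
    if len(only_ref) or len(only_test):
        raise ValueError(
            "status tables cover different gene universes; "
            f"only in reference: {list(only_ref[:5])}, only in test: {list(only_test[:5])}"
        )
    ref = status_ref.astype(bool)
    test = status_test.reindex(ref.index).astype(bool)
    labels = pd.Series("II", index=ref.index, name="pattern")
    labels[ref & test] = "I"
    labels[ref & ~test] = "III"
    labels[~ref & test] = "IV"
    counts = labels.value_counts().to_dict()
    return labels, pattern_summary_from_counts(counts, comparison)


def parent_reference_status(
    status_by_genotype: dict[str, pd.Series],
    subgenome: pd.Series,
    parent_of: dict[str, str],
) -> pd.Series:
    """Build the parental reference status for a polyploid comparison.

    Each gene's reference status comes from the genotype that contributed
    its subgenome (e.g. ``{"A_n": "A", "C_n": "C"}``).  Genes whose
    subgenome has no parent mapping are dropped.
    """
    keep = subgenome[subgenome.isin(parent_of)].index
    out = pd.Series(index=keep, dtype=bool)
    for sub, parent in parent_of.items():
        genes = subgenome[subgenome == sub].index
        out.loc[genes] = status_by_genotype[parent].reindex(genes).astype(bool)
    return out


def classify_pair_patterns(
    pairs: pd.DataFrame, status: pd.Series
) -> pd.DataFrame:
    """IM/DM/NM classification of duplicate pairs within one genotype.

    ``pairs`` needs columns pair_id, gene1, gene2; ``status`` is a boolean
    m6A status indexed by gene_id.  For DM pairs ``methylated_member``
    records which gene carries the peak.
    """
    rows = []
    for row in pairs.itertuples(index=False):
        if row.gene1 == row.gene2:
            raise ValueError(f"pair {row.pair_id}: gene paired with itself")
        s1 = bool(status.loc[row.gene1])
        s2 = bool(status.loc[row.gene2])
        if s1 and s2:
            pat, member = "IM", None
        elif s1 or s2:
            pat, member = "DM", (row.gene1 if s1 else row.gene2)
        else:
            pat, member = "NM", None
        rows.append({"pair_id": row.pair_id, "pattern": pat,
                     "methylated_member": member})
    return pd.DataFrame(rows).set_index("pair_id")


def stratified_m6a_proportion(
    status: pd.Series,
    classes: pd.DataFrame,
    strata_keys: list[str],
    contrasts: list[tuple] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """m6A-gene proportion per stratum with pairwise chi-square contrasts.

    ``classes`` holds one row per gene with the stratification columns
    (subgenome, duplication_status, dup_type, dosage, ...).  Contrasts
    default to all stratum pairs; p-values are BH-adjusted across the
    contrasts tested.  Empty strata are reported with n = 0 and excluded
    from tests.
    """
    bad = set(strata_keys) - set(STRATA_KEYS)
    if bad:
        raise ValueError(f"unknown strata keys {sorted(bad)}")
    df = classes.copy()
    df["m6a"] = status.reindex(df.index).astype(bool)
    grouped = df.groupby(list(strata_keys), dropna=False, observed=True)
    rows = []
    tallies = {}
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        n, k = len(sub), int(sub["m6a"].sum())
        tallies[key] = (k, n)
        rows.append({**dict(zip(strata_keys, key)), "n_genes": n, "n_m6a": k,
                     "proportion": k / n if n else float("nan")})
    summary = pd.DataFrame(rows)
    strata = sorted(tallies)
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(strata) for b in strata[i + 1:]]
    test_rows = []
    for a, b in contrasts:
        a = a if isinstance(a, tuple) else (a,)
        b = b if isinstance(b, tuple) else (b,)
        ka, na = tallies.get(a, (0, 0))
        kb, nb = tallies.get(b, (0, 0))
        if na == 0 or nb == 0:
            continue
        table = [[ka, na - ka], [kb, nb - kb]]
        try:
            res = chi_square_test(table)
            p = res.p_value
        except ValueError:  # degenerate marginal (all or none methylated)
            p = 1.0
        test_rows.append({"stratum1": "/".join(map(str, a)),
                          "stratum2": "/".join(map(str, b)), "p_value": p})
    tests = pd.DataFrame(test_rows)
    if not tests.empty:
        tests["p_adj"] = _benjamini_hochberg(tests["p_value"].to_numpy())
    return summary, tests


def _benjamini_hochberg(p):
    import numpy as np

    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
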