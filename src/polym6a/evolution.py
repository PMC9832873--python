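"""Ka/Ks estimation by the Nei-Gojobori (NG86) counting method.

For an ungapped pair of in-frame CDS sequences, each codon contributes
synonymous and non-synonymous *sites* (the per-position fraction of the
three possible single-nucleotide changes that are synonymous, with changes
to stop codons counted as non-synonymous), averaged over the two
sequences.  Observed differences are split into synonymous and
non-synonymous counts by averaging over all orderings of single-step
mutational paths between the two codons; paths passing through a stop
codon are excluded and the remaining paths re-weighted uniformly.
Proportions are corrected for multiple hits with the Jukes-Cantor formula
K = -(3/4) ln(1 - 4p/3); p >= 3/4 (saturation) yields a missing K.

omega = Ka/Ks is the evolutionary-rate ratio: omega < 1 indicates
purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .genestats import wilcoxon_rank_sum

NUCS = "TCAG"

_CODON_TABLE = {}


def _build_table() -> dict[str, str]:
    # standard genetic code, '*' = stop
    bases = NUCS
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


_CODON_TABLE = _build_table()
STOP_CODONS = frozenset(c for c, a in _CODON_TABLE.items() if a == "*")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


class SequenceError(ValueError):
    pass


@dataclass
class KaKsResult:
    """NG86 estimates for one aligned CDS pair."""

    pair_id: str
    n_codons: int  # codons actually used (gap/ambiguity/stop codons excluded)
    S: float  # synonymous sites
    N: float  # non-synonymous sites
    Sd: float  # synonymous differences (path-averaged)
    Nd: float
    ps: float
    pn: float
    Ks: float  # nan when saturated
    Ka: float
    omega: float  # nan when Ks == 0 or missing

    def to_row(self) -> dict:
        return {
            "pair_id": self.pair_id, "n_codons": self.n_codons,
            "S": self.S, "N": self.N, "Sd": self.Sd, "Nd": self.Nd,
            "Ka": self.Ka, "Ks": self.Ks, "omega": self.omega,
        }


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one sense codon.

    Each position contributes (number of synonymous single-nt changes)/3;
    changes to stop codons count as non-synonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue  # non-synonymous by convention
            if _CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) difference counts between two
    codons over all orderings of single-step paths, excluding paths that
    pass through a stop codon (all paths kept if every path hits a stop)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    valid = [(sd, nd) for sd, nd, ts in paths if not ts]
    if not valid:  # every ordering crosses a stop; keep all rather than none
        valid = [(sd, nd) for sd, nd, _ in paths]
    sd = float(np.mean([v[0] for v in valid]))
    nd = float(np.mean([v[1] for v in valid]))
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction; nan at saturation (p >= 3/4)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds1: str, cds2: str, pair_id: str = "") -> KaKsResult:
    """NG86 Ka, Ks and omega for one aligned, ungapped CDS pair.

    Codons containing gaps, ambiguity codes, or a stop in either sequence
    are excluded pairwise.  Symmetric in its arguments.
    """
    cds1, cds2 = cds1.upper().replace("U", "T"), cds2.upper().replace("U", "T")
    if len(cds1) != len(cds2):
        raise SequenceError(f"length mismatch: {len(cds1)} vs {len(cds2)}")
    if len(cds1) % 3 != 0:
        raise SequenceError(f"length {len(cds1)} not divisible by 3")
    valid = set(NUCS)
    S = N = Sd = Nd = 0.0
    n_used = 0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3], cds2[i:i + 3]
        if not (set(a) <= valid and set(b) <= valid):
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            continue
        n_used += 1
        sa, sb = _syn_sites(a), _syn_sites(b)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _path_differences(a, b)
        Sd += sd
        Nd += nd
    if n_used == 0:
        raise SequenceError(f"pair {pair_id!r}: no analyzable codons")
    ps = Sd / S if S > 0 else float("nan")
    pn = Nd / N if N > 0 else float("nan")
    Ks = jukes_cantor(ps) if np.isfinite(ps) else float("nan")
    Ka = jukes_cantor(pn) if np.isfinite(pn) else float("nan")
    omega = Ka / Ks if np.isfinite(Ks) and np.isfinite(Ka) and Ks > 0 else float("nan")
    return KaKsResult(pair_id, n_used, S, N, Sd, Nd, ps, pn, Ks, Ka, omega)


def kaks_table(pairs: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Run :func:`ng86_kaks` over (pair_id, cds1, cds2) triples."""
    return pd.DataFrame([ng86_kaks(c1, c2, pid).to_row() for pid, c1, c2 in pairs])


def group_omega_comparison(
    kaks: pd.DataFrame, labels: pd.Series | dict, contrasts: list[tuple[str, str]] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize omega by group and test pairwise contrasts.

    Parameters
    ----------
    kaks : DataFrame with columns pair_id, omega.
    labels : map pair_id -> group label.
    contrasts : group pairs to test with the Wilcoxon rank-sum test;
        default is all pairwise.

    Returns (summary, tests): summary has group, n, n_missing, mean, sd;
    omega-missing pairs are excluded from statistics but counted.  Groups
    with fewer than two finite omegas are excluded from tests.
    """
    labels = pd.Series(labels)
    df = kaks.copy()
    df["group"] = df["pair_id"].map(labels)
    df = df.dropna(subset=["group"])
    rows = []
    samples: dict[str, np.ndarray] = {}
    for grp, sub in df.groupby("group"):
        vals = sub["omega"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        samples[grp] = finite
        rows.append({
            "group": grp, "n": finite.size, "n_missing": vals.size - finite.size,
            "mean_omega": float(finite.mean()) if finite.size else float("nan"),
            "sd_omega": float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
        })
    summary = pd.DataFrame(rows).set_index("group")
    groups = sorted(samples)
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    test_rows = []
    for a, b in contrasts:
        if samples.get(a, np.array([])).size < 2 or samples.get(b, np.array([])).size < 2:
            test_rows.append({"group1": a, "group2": b, "p_value": float("nan")})
            continue
        res = wilcoxon_rank_sum(samples[a], samples[b])
        test_rows.append({"group1": a, "group2": b, "p_value": res.p_value})
    return summary, pd.DataFrame(test_rows)
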