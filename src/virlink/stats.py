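"""Per-SAG summaries and the association-statistics layer.

Builds one summary row per retained SAG (taxon, plastidic flag, virus /
bacteriophage / inter-phylum-virus / bacteria indicators, viral contig
count) and provides the tests used on such summaries: Pearson chi-square
contingency tests of independence (no continuity correction), one-way
ANOVA with a post hoc Tukey HSD compact letter display, and the
Mann–Whitney U test with midrank ties (exact enumeration for small
samples, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "SagSummary",
    "build_summary",
    "contingency_from_summary",
    "chi_square_test",
    "one_way_anova",
    "tukey_hsd",
    "mann_whitney",
]

DEFAULT_PHAGE_LINEAGES = ("Caudovirales", "Microviridae")


@dataclass(frozen=True)
class SagSummary:
    sag_id: str
    taxon: str
    plastidic: bool
    has_virus: bool
    has_bacteriophage: bool
    has_interphylum_virus: bool
    has_bacteria: bool
    n_viral_contigs: int


def build_summary(retained_sags, sag_contigs: dict, categories: dict,
                  clusters, contig_lca: dict, sag_taxa: dict,
                  plastidic: dict, interphylum_cluster_ids: set,
                  phage_lineages=DEFAULT_PHAGE_LINEAGES) -> pd.DataFrame:
    """One row per retained SAG.

    ``has_bacteriophage`` is true iff the SAG holds a viral contig whose
    cluster LCA falls in ``phage_lineages`` (tailed dsDNA phages and ssDNA
    Microviridae by default); ``has_interphylum_virus`` iff it holds a
    member of an inter-phylum viral cluster.
    """
    cluster_of = {m: c for c in clusters for m in c.members}
    rows = []
    for sag_id in retained_sags:
        contigs = sag_contigs[sag_id]
        viral = [c for c in contigs if categories.get(c) == "viral"]
        has_phage = False
        has_inter = False
        for c in viral:
            cl = cluster_of.get(c)
            if cl is None:
                continue
            if cl.lca_label in phage_lineages:
                has_phage = True
            if cl.cluster_id in interphylum_cluster_ids:
                has_inter = True
        rows.append({
            "sag_id": sag_id,
            "taxon": sag_taxa.get(sag_id, "unidentified"),
            "plastidic": bool(plastidic.get(sag_id, False)),
            "has_virus": bool(viral),
            "has_bacteriophage": has_phage,
            "has_interphylum_virus": has_inter,
            "has_bacteria": any(categories.get(c) == "bacterial" for c in contigs),
            "n_viral_contigs": len(viral),
        })
    return pd.DataFrame(rows, columns=[
        "sag_id", "taxon", "plastidic", "has_virus", "has_bacteriophage",
        "has_interphylum_virus", "has_bacteria", "n_viral_contigs"])


def contingency_from_summary(summary: pd.DataFrame, column: str,
                             min_sags: int = 1) -> pd.DataFrame:
    """TRUE/FALSE contingency table of ``column`` by taxon.

    Taxa with fewer than ``min_sags`` SAGs (and "unidentified") are
    dropped; taxa with zero sampled SAGs never appear, avoiding zero
    marginals.
    """
    sub = summary[summary["taxon"] != "unidentified"]
    counts = sub.groupby("taxon")[column].agg(["sum", "count"])
    counts = counts[counts["count"] >= min_sags]
    table = pd.DataFrame({
        "TRUE": counts["sum"].astype(int),
        "FALSE": (counts["count"] - counts["sum"]).astype(int),
    })
    return table


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence; no continuity correction.

    ``table`` is a 2-D array-like of non-negative counts (rows = taxa,
    columns = TRUE/FALSE).  Returns (statistic, dof, p).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("negative cell in contingency table")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for i, rs in enumerate(row_sums):
        if rs == 0:
            raise ValueError(f"zero marginal in row {i}")
    for j, cs in enumerate(col_sums):
        if cs == 0:
            raise ValueError(f"zero marginal in column {j}")
    res = sstats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA.  Returns (F, df_between, df_within, p).

    Degenerate input (zero within-group variance everywhere but unequal
    means) is signalled with F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    n = sum(len(g) for g in groups)
    kg = len(groups)
    if n <= kg:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = kg - 1, n - kg
    if ssw == 0:
        if ssb == 0:
            return 0.0, dfb, dfw, 1.0
        return math.inf, dfb, dfw, 0.0
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), dfb, dfw, float(sstats.f.sf(f, dfb, dfw))


def tukey_hsd(groups, labels=None, alpha: float = 0.05):
    """Tukey HSD pairwise comparisons with a compact letter display.

    Returns ``(pvalues, letters)``: a labelled DataFrame of pairwise
    studentized-range p-values and a dict label → letter string such that
    two groups sharing no letter differ at ``alpha``.  Letter assembly
    uses the insert-and-absorb algorithm, deterministic in group order.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs >=2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    res = sstats.tukey_hsd(*groups)
    pmat = pd.DataFrame(res.pvalue, index=labels, columns=labels)

    k = len(groups)
    sig_pairs = [(i, j) for i in range(k) for j in range(i + 1, k)
                 if res.pvalue[i, j] < alpha]
    letter_sets = [set(range(k))]
    for i, j in sig_pairs:
        for s in [s for s in letter_sets if i in s and j in s]:
            letter_sets.remove(s)
            a, b = s - {i}, s - {j}
            for cand in (a, b):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    letter_sets = [s for s in letter_sets if s]
    # final absorption: drop sets contained in another set
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t or (s == t and i > j)
                              for j, t in enumerate(letter_sets) if j != i)]
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for idx, s in enumerate(letter_sets):
        for gi in sorted(s):
            letters[labels[gi]] += alphabet[idx % len(alphabet)]
    return pmat, letters


def _u_from_ranks(pooled_ranks, n1):
    r1 = pooled_ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(x, y, exact_limit: int = 400,
                 max_enumeration: int = 200_000) -> tuple[float, float]:
    """Mann–Whitney U test (U for the first sample, two-sided p).

    Ties are handled with midranks.  When ``n1*n2 <= exact_limit`` and the
    number of label assignments is enumerable (<= ``max_enumeration``),
    the p-value is computed by exhaustive enumeration of the permutation
    distribution of U over the pooled values; otherwise a tie-corrected
    normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    u1 = _u_from_ranks(ranks, n1)
    mu = n1 * n2 / 2.0

    if n1 * n2 <= exact_limit and math.comb(n1 + n2, n1) <= max_enumeration:
        dev = abs(u1 - mu)
        count = 0
        total = 0
        idx_all = range(n1 + n2)
        for combo in itertools.combinations(idx_all, n1):
            r1 = ranks[list(combo)].sum()
            u = r1 - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return float(u1), count / total

    # tie-corrected normal approximation
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return float(u1), 1.0
    z = (u1 - mu) / math.sqrt(var)
    return float(u1), float(2.0 * sstats.norm.sf(abs(z)))
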