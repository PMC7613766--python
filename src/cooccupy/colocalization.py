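"""Summit-based co-localization: nearest-summit matching, Venn/overlap
fractions, cross-factor strength correlation, and the GFI1-anchored triple
inter-summit distance analysis.

Two peaks are considered co-located when their absolute summits lie within
``max_dist`` (default 100 bp) on the same chromosome.  Signed distances keep
the side structure (partner minus anchor); distributional summaries use
absolute distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import PeakSet

__all__ = [
    "match_summits",
    "overlap_fractions",
    "VennResult",
    "strength_correlation",
    "CorrelationResult",
    "triple_analysis",
    "DistanceStats",
]

PAIR_TYPES = ["hmg20b_lsd1", "hmg20b_gfi1", "lsd1_gfi1"]


def _nearest(b_summits: np.ndarray, pos: int) -> int | None:
    """Index of the nearest value; equidistant ties go to the smaller
    coordinate (the left neighbour)."""
    k = int(np.searchsorted(b_summits, pos))
    best = None
    for j in (k - 1, k):
        if 0 <= j < len(b_summits):
            cand = (abs(int(b_summits[j]) - pos), int(b_summits[j]), j)
            if best is None or cand[:2] < best[:2]:
                best = cand
    return None if best is None else best[2]


def match_summits(A: PeakSet, B: PeakSet, max_dist: int = 100) -> pd.DataFrame:
    """For each A-peak, the nearest B-summit on the same chromosome within
    ``max_dist``.  Signed distance is ``summit_B - summit_A``.  A-peaks with
    no match are absent from the output; matching is not one-to-one (two
    A-peaks may share a B-peak).
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("match_summits: both peak sets must be non-empty")
    b_by_chrom = {
        c: grp.sort_values(["summit", "name"], kind="mergesort")
        for c, grp in B.df.groupby("chrom")
    }
    rows = []
    for a in A.df.itertuples(index=False):
        grp = b_by_chrom.get(a.chrom)
        if grp is None:
            continue
        summits = grp["summit"].to_numpy()
        j = _nearest(summits, int(a.summit))
        if j is None:
            continue
        dist = int(summits[j]) - int(a.summit)
        if abs(dist) > max_dist:
            continue
        rows.append((a.name, grp["name"].iloc[j], dist,
                     a.pileup, grp["pileup"].iloc[j]))
    return pd.DataFrame(rows, columns=["a_name", "b_name", "distance",
                                       "a_pileup", "b_pileup"])


@dataclass
class VennResult:
    """Partition of the anchor set H by co-location with G and L."""

    n_h: int
    both: int
    g_only: int
    l_only: int
    neither: int
    pct_g: float       # % of H matched to G (one decimal)
    pct_l: float
    pct_either: float


def overlap_fractions(H: PeakSet, G: PeakSet, L: PeakSet,
                      max_dist: int = 100) -> VennResult:
    """Fractions of H peaks whose summit lies within ``max_dist`` of a G or L
    summit, plus the Venn partition of H."""
    in_g = set(match_summits(H, G, max_dist)["a_name"])
    in_l = set(match_summits(H, L, max_dist)["a_name"])
    n = len(H)
    both = len(in_g & in_l)
    g_only = len(in_g - in_l)
    l_only = len(in_l - in_g)
    neither = n - both - g_only - l_only
    pct = lambda k: round(100.0 * k / n, 1)
    return VennResult(n, both, g_only, l_only, neither,
                      pct(len(in_g)), pct(len(in_l)), pct(both + g_only + l_only))


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    n: int


def _correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return CorrelationResult(float(pr), float(pp), float(sr), float(sp), len(x))


def strength_correlation(pairs: pd.DataFrame) -> CorrelationResult:
    """Correlation of paired peak strengths (Pearson, with Spearman reported
    alongside); two-sided p-values."""
    if len(pairs) < 3:
        raise ValueError("strength_correlation needs >= 3 pairs")
    return _correlate(pairs["a_pileup"].to_numpy(float),
                      pairs["b_pileup"].to_numpy(float))


@dataclass
class DistanceStats:
    """Inter-summit distance statistics over co-located triples.

    ``abs_stats`` is indexed by pair type with mean/SEM/median/IQR of the
    absolute distances; ``correlations`` maps signed-distance pairs (e.g.
    ``("hg", "lg")``) to a CorrelationResult; Tukey p-values compare the
    absolute-distance groups pairwise.
    """

    abs_stats: pd.DataFrame
    correlations: dict[tuple[str, str], CorrelationResult]
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame


def triple_analysis(
    G: PeakSet, H: PeakSet, L: PeakSet,
    gfi1_min_pileup: float = 300.0,
    max_dist: int = 100,
) -> tuple[pd.DataFrame, DistanceStats | None]:
    """Anchor on strong GFI1 peaks and collect co-located HMG20B/LSD1 peaks.

    A triple requires a GFI1 peak with pileup >= ``gfi1_min_pileup`` plus a
    nearest HMG20B and LSD1 summit each within ``max_dist``, and all three
    summits pairwise within ``max_dist``.  Signed distances are
    ``hg = HMG20B - GFI1``, ``lg = LSD1 - GFI1``, ``hl = HMG20B - LSD1``
    (so ``hl = hg - lg`` identically).
    """
    strong_g = G.subset(G.pileups >= gfi1_min_pileup)
    if len(strong_g) == 0 or len(H) == 0 or len(L) == 0:
        return _empty_triples(), None
    to_h = match_summits(strong_g, H, max_dist).set_index("a_name")
    to_l = match_summits(strong_g, L, max_dist).set_index("a_name")
    rows = []
    for g in strong_g.df.itertuples(index=False):
        if g.name not in to_h.index or g.name not in to_l.index:
            continue
        h, l = to_h.loc[g.name], to_l.loc[g.name]
        d_hg, d_lg = int(h["distance"]), int(l["distance"])
        d_hl = d_hg - d_lg
        if abs(d_hl) > max_dist:
            continue
        rows.append((g.name, h["b_name"], l["b_name"], d_hg, d_lg, d_hl,
                     g.pileup, h["b_pileup"], l["b_pileup"]))
    triples = pd.DataFrame(rows, columns=[
        "gfi1", "hmg20b", "lsd1", "d_hg", "d_lg", "d_hl",
        "gfi1_pileup", "hmg20b_pileup", "lsd1_pileup",
    ])
    if len(triples) == 0:
        return triples, None

    groups = {
        "hmg20b_lsd1": np.abs(triples["d_hl"].to_numpy(float)),
        "hmg20b_gfi1": np.abs(triples["d_hg"].to_numpy(float)),
        "lsd1_gfi1": np.abs(triples["d_lg"].to_numpy(float)),
    }
    abs_stats = pd.DataFrame({
        name: {
            "mean": g.mean(),
            "sem": stats.sem(g) if len(g) > 1 else 0.0,
            "median": np.median(g),
            "iqr": np.percentile(g, 75) - np.percentile(g, 25),
            "n": len(g),
        }
        for name, g in groups.items()
    }).T.loc[PAIR_TYPES]
    correlations = {}
    if len(triples) >= 3:
        signed = {k: triples[f"d_{k}"].to_numpy(float) for k in ("hg", "lg", "hl")}
        for pair in (("hg", "lg"), ("hl", "hg"), ("hl", "lg")):
            correlations[pair] = _correlate(signed[pair[0]], signed[pair[1]])
    f, p = stats.f_oneway(*groups.values())
    tk = stats.tukey_hsd(*groups.values())
    idx = pd.Index(PAIR_TYPES)
    tukey = pd.DataFrame(tk.pvalue, index=idx, columns=idx)
    return triples, DistanceStats(abs_stats, correlations, float(f), float(p), tukey)


def _empty_triples() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "gfi1", "hmg20b", "lsd1", "d_hg", "d_lg", "d_hl",
        "gfi1_pileup", "hmg20b_pileup", "lsd1_pileup",
    ])
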