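"""Peak-to-gene mapping, cohort gene sets, and a preranked gene-set
enrichment engine.

The enrichment statistic is the weighted Kolmogorov–Smirnov running-sum ES of
GSEA: walking down the ranked list, hits increment the running sum by
``|score|^p / sum_hits |score|^p`` and misses decrement it by
``1 / (N - N_hits)``; ES is the signed maximum deviation from zero.
Significance uses size-matched random gene-set permutations (the standard
null for preranked input), NES normalization by the same-sign null mean, and
the usual NES-ratio FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import AnnotationResult, CohortTable, PeakSet, annotate_peaks

__all__ = [
    "map_nearest_gene",
    "build_cohort_gene_sets",
    "write_gmt",
    "read_gmt",
    "preranked_es",
    "gsea",
]

_PROMOTER_CATS = {"promoter", "5'UTR"}
_ENHANCER_CATS = {"intergenic", "intron"}


def map_nearest_gene(peaks: PeakSet, genes: pd.DataFrame,
                     annotation: AnnotationResult | None = None) -> pd.DataFrame:
    """Map each peak to the nearest gene by summit-to-TSS distance.

    Equidistant TSSs tie-break to the smaller gene identifier.  Each peak is
    also classed from its genomic annotation: promoter/5'UTR -> "promoter",
    intergenic/intron -> "enhancer", anything else -> "other".
    Returns a frame indexed by peak name with gene_id, distance, category and
    class columns.
    """
    if len(genes) == 0:
        raise ValueError("map_nearest_gene: empty gene table")
    if annotation is None:
        annotation = annotate_peaks(peaks, genes)
    by_chrom = {
        c: grp.sort_values(["tss", "gene_id"], kind="mergesort")
        for c, grp in genes.groupby("chrom")
    }
    rows = []
    for p in peaks.df.itertuples(index=False):
        grp = by_chrom.get(p.chrom)
        gene_id, dist = None, None
        if grp is not None:
            tss = grp["tss"].to_numpy(int)
            k = int(np.searchsorted(tss, p.summit))
            best = None
            for j in (k - 1, k, k + 1):
                if 0 <= j < len(grp):
                    cand = (abs(int(tss[j]) - int(p.summit)), grp["gene_id"].iloc[j])
                    if best is None or cand < best:
                        best = cand
            dist, gene_id = best
        cat = annotation.categories.get(p.name, "intergenic")
        cls = ("promoter" if cat in _PROMOTER_CATS
               else "enhancer" if cat in _ENHANCER_CATS else "other")
        rows.append((p.name, gene_id, dist, cat, cls))
    return pd.DataFrame(
        rows, columns=["name", "gene_id", "distance", "category", "class"]
    ).set_index("name")


def build_cohort_gene_sets(
    cohorts: CohortTable,
    mapping: pd.DataFrame,
    peak_class: str | None = None,
) -> dict[str, set[str]]:
    """One gene set per strength cohort, optionally restricted to peaks of
    one class ("promoter"/"enhancer").  Duplicate genes within a cohort are
    collapsed; empty cohorts yield empty sets (retained)."""
    suffix = f"_{peak_class}" if peak_class else ""
    out: dict[str, set[str]] = {}
    for k in range(1, cohorts.n_cohorts + 1):
        names = [n for n in cohorts.members(k) if n in mapping.index]
        sub = mapping.loc[names]
        if peak_class is not None:
            sub = sub[sub["class"] == peak_class]
        out[f"cohort_{k:02d}{suffix}"] = set(sub["gene_id"].dropna())
    return out


def write_gmt(gene_sets: Mapping[str, set[str]], path,
              description: str = "cohort") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            out[fields[0]] = set(fields[2:])
    return out


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _order_ranking(ranked: pd.Series) -> pd.Series:
    """Descending scores with ties broken by gene identifier."""
    df = ranked.rename_axis("gene_id").reset_index(name="score")
    df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                        kind="mergesort")
    return df.set_index("gene_id")["score"]


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, N: int) -> np.ndarray:
    """ES for one or more hit-position sets.

    ``pos``: (m, k) hit positions (0-based in the ranked list), each row
    sorted ascending; ``absw``: |score|^p for every list position.  Only the
    running-sum values at hit boundaries can be extremes, so the signed
    maximum deviation is computed from those.
    """
    pos = np.atleast_2d(pos)
    m, k = pos.shape
    w = absw[pos]
    wsum = w.sum(axis=1, keepdims=True)
    flat = wsum[:, 0] == 0
    if flat.any():  # all-zero hit scores: fall back to equal weights
        w[flat] = 1.0
        wsum[flat] = k
    cw = np.cumsum(w, axis=1) / wsum
    miss = 1.0 / (N - k)
    misses_before = pos - np.arange(k)
    s_after = cw - miss * misses_before
    s_before = s_after - w / wsum
    up = s_after.max(axis=1)
    down = s_before.min(axis=1)
    # the positive extreme wins only when larger in magnitude; the tolerance
    # keeps exact mathematical ties from flipping on rounding order
    return np.where(up + down > 1e-12, up, down)


def preranked_es(ranked: pd.Series, gene_set: Sequence[str] | set,
                 weight: float = 1.0) -> float:
    """Weighted KS enrichment score of ``gene_set`` in the ranked list."""
    ordered = _order_ranking(ranked)
    members = set(gene_set) & set(ordered.index)
    if not members:
        raise ValueError("gene set has empty intersection with the ranked list")
    if len(members) >= len(ordered):
        raise ValueError("gene set covers the entire ranked list")
    scores = ordered.to_numpy(float)
    absw = np.abs(scores) ** weight
    pos = np.sort(np.flatnonzero(ordered.index.isin(members)))
    return float(_es_from_positions(pos, absw, len(ordered))[0])


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    fdr_q: float


def gsea(
    ranked: pd.Series,
    gene_sets: Mapping[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked enrichment over a collection of gene sets.

    Null distributions come from size-matched random gene sets drawn from the
    ranked list (deterministic given ``seed``).  NES divides ES by the mean
    absolute same-sign null ES; the nominal p is one-sided against the
    same-sign null; FDR q follows the standard pooled-NES ratio procedure,
    made monotone in |NES| within each sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ordered = _order_ranking(ranked)
    N = len(ordered)
    scores = ordered.to_numpy(float)
    absw = np.abs(scores) ** weight
    index_set = set(ordered.index)
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    perms_by_size: dict[int, np.ndarray] = {}
    for name, members in gene_sets.items():
        hits = set(members) & index_set
        k = len(hits)
        if k == 0 or k >= N:
            rows.append((name, k, np.nan, np.nan, np.nan))
            continue
        if k > N // 2:
            warnings.warn(f"gene set {name!r} covers more than half the list",
                          stacklevel=2)
        es = float(_es_from_positions(
            np.sort(np.flatnonzero(ordered.index.isin(hits))), absw, N)[0])
        if k not in perms_by_size:
            perms_by_size[k] = np.sort(
                np.argsort(rng.random((n_perm, N)), axis=1)[:, :k], axis=1
            )
        null = _es_from_positions(perms_by_size[k], absw, N)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) == 0:
            nes, p = np.nan, 1.0 / (1 + n_perm)
            null_nes = np.array([])
        else:
            denom = np.abs(same).mean()
            nes = es / denom
            p = (np.sum(np.abs(same) >= abs(es)) + 1) / (len(same) + 1)
            pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
            neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
            null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(null_nes)
        rows.append((name, k, es, float(nes), float(p)))

    res = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p"])
    pool = (np.concatenate(null_nes_pool)
            if null_nes_pool else np.array([]))
    res["fdr_q"] = _fdr_from_pool(res["nes"].to_numpy(), pool)
    return res.set_index("name")


def _fdr_from_pool(nes: np.ndarray, pool: np.ndarray) -> np.ndarray:
    q = np.full(len(nes), np.nan)
    if len(pool) == 0:
        return q
    finite = np.isfinite(nes)
    for sign in (1, -1):
        if sign == 1:
            obs_side = nes[finite & (nes >= 0)]
            null_side = pool[pool >= 0]
        else:
            obs_side = nes[finite & (nes < 0)]
            null_side = pool[pool < 0]
        if len(obs_side) == 0 or len(null_side) == 0:
            continue
        for i in np.flatnonzero(finite):
            v = nes[i]
            if (sign == 1) != (v >= 0):
                continue
            frac_null = np.mean(np.abs(null_side) >= abs(v))
            frac_obs = np.mean(np.abs(obs_side) >= abs(v))
            q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
    # monotone: a stronger |NES| never gets a larger q (within each sign);
    # traverse from least to most extreme so small q never leaks downward
    for sign in (1, -1):
        side = np.flatnonzero(finite & ((nes >= 0) if sign == 1 else (nes < 0)))
        if len(side) == 0:
            continue
        order = side[np.argsort(np.abs(nes[side]), kind="mergesort")]
        running = np.inf
        for i in order:
            running = min(running, q[i])
            q[i] = running
    return q
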