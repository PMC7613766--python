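"""Consensus motif scanning and positional-probability curves around peak
summits (CentriMo-style centrality analysis).

The positional curve reports, for each offset o in [-W, W], the fraction of
summits with at least one motif occurrence centered exactly at summit + o.  A
narrow curve with its apex at offset 0 indicates the factor binds the motif
directly; a broader, bimodal curve with apexes offset to either side
indicates the factor sits next to the motif-bound anchor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthetic import IUPAC_CODES

__all__ = [
    "scan_consensus",
    "positional_curve",
    "PositionalCurve",
    "curve_metrics",
    "CurveMetrics",
]

_COMPLEMENT_MAP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(consensus: str) -> str:
    parts = []
    for c in consensus.upper():
        if c not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {c!r} in consensus {consensus!r}")
        bases = IUPAC_CODES[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def reverse_complement(consensus: str) -> str:
    return consensus.upper().translate(_COMPLEMENT_MAP)[::-1]


def scan_consensus(sequences: Mapping[str, str] | "object",
                   consensus: str) -> pd.DataFrame:
    """Scan both strands for exact IUPAC-consensus matches.

    ``sequences`` maps chromosome name to sequence (a GenomeModel is also
    accepted).  Overlapping occurrences are all reported.  The occurrence
    center is ``start + len(consensus) // 2`` on either strand.
    """
    if hasattr(sequences, "as_strings"):
        sequences = sequences.as_strings()
    if not consensus:
        raise ValueError("consensus must be non-empty")
    center = len(consensus) // 2
    fwd = re.compile(f"(?=({_iupac_regex(consensus)}))")
    rev = re.compile(f"(?=({_iupac_regex(reverse_complement(consensus))}))")
    rows = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        for m in fwd.finditer(seq):
            rows.append((chrom, m.start() + center, "+"))
        for m in rev.finditer(seq):
            rows.append((chrom, m.start() + center, "-"))
    df = pd.DataFrame(rows, columns=["chrom", "center", "strand"])
    return df.sort_values(["chrom", "center", "strand"]).reset_index(drop=True)


@dataclass
class PositionalCurve:
    """Motif probability as a function of offset from the summit.

    ``raw[i]`` is the fraction of summits with >= 1 occurrence centered at
    offset ``offsets[i]``; ``smoothed`` is a centered moving average;
    ``background`` is the mean smoothed probability over the outer flanks
    (|offset| >= 80% of the window).
    """

    offsets: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    background: float
    flank_std: float
    n_summits: int
    smooth_window: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "raw": self.raw,
                             "smoothed": self.smoothed})


def _as_summits(summits) -> list[tuple[str, int]]:
    if hasattr(summits, "df"):  # PeakSet
        summits = summits.df
    if isinstance(summits, pd.DataFrame):
        return list(zip(summits["chrom"], summits["summit"].astype(int)))
    return [(c, int(p)) for c, p in summits]


def positional_curve(occurrences: pd.DataFrame, summits,
                     W: int = 250, smooth_window: int = 5) -> PositionalCurve:
    """Per-offset motif probability around summits, with strand collapsed.

    ``summits`` may be a PeakSet, a frame with chrom/summit columns, or an
    iterable of (chrom, position) pairs.
    """
    if W <= 0:
        raise ValueError("window W must be > 0")
    pts = _as_summits(summits)
    if not pts:
        raise ValueError("positional_curve needs >= 1 summit")
    occ_by_chrom = {
        c: np.unique(grp["center"].to_numpy(int))
        for c, grp in occurrences.groupby("chrom")
    } if len(occurrences) else {}
    counts = np.zeros(2 * W + 1)
    for chrom, pos in pts:
        centers = occ_by_chrom.get(chrom)
        if centers is None:
            continue
        lo = np.searchsorted(centers, pos - W)
        hi = np.searchsorted(centers, pos + W, side="right")
        offs = centers[lo:hi] - pos
        counts[offs + W] += 1  # centers unique -> at most one count per offset
    raw = counts / len(pts)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(raw, kernel, mode="same")
    flank = np.abs(np.arange(-W, W + 1)) >= int(np.ceil(0.8 * W))
    background = float(smoothed[flank].mean())
    flank_std = float(smoothed[flank].std())
    return PositionalCurve(np.arange(-W, W + 1), raw, smoothed,
                           background, flank_std, len(pts), smooth_window)


@dataclass
class CurveMetrics:
    """Enriched-region width and apex offset(s) of a positional curve.

    ``width`` is the length (bp) of the maximal contiguous run of offsets
    above the enrichment threshold that contains the global maximum.
    ``apexes`` holds one offset (unimodal) or the negative- and positive-side
    offsets (bimodal).
    """

    width: int
    apexes: tuple[int, ...]
    bimodal: bool


def curve_metrics(curve: PositionalCurve, z: float = 2.0,
                  bimodal_ratio: float = 0.7) -> CurveMetrics:
    """Width, apex offsets and bimodality of a smoothed positional curve.

    The enrichment threshold is ``background + z * flank std``.  Apexes are
    local maxima of the smoothed curve above the threshold; the curve is
    called bimodal when local maxima on both sides of zero each reach
    ``bimodal_ratio`` of the global maximum, in which case both signed apex
    offsets are reported.
    """
    sm, offs = curve.smoothed, curve.offsets
    threshold = curve.background + z * curve.flank_std
    gmax = sm.max()
    if gmax <= threshold or gmax <= 0:
        return CurveMetrics(0, (), False)
    above = sm > threshold
    imax = int(np.argmax(sm))
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(sm) - 1 and above[hi + 1]:
        hi += 1
    width = hi - lo + 1

    idx, _ = find_peaks(sm, height=max(threshold, 0.0))
    if len(idx) == 0:
        idx = np.array([imax])
    strong = idx[sm[idx] >= bimodal_ratio * gmax]
    neg = [i for i in strong if offs[i] < 0]
    pos = [i for i in strong if offs[i] > 0]

    half = curve.smooth_window // 2

    def refine(i: int) -> int:
        # the smoothed curve locates the peak region to within the smoothing
        # window; the raw curve inside it gives the modal offset
        lo_i, hi_i = max(0, i - half), min(len(sm), i + half + 1)
        window = range(lo_i, hi_i)
        j = min(window, key=lambda t: (-curve.raw[t], abs(int(offs[t]))))
        return int(offs[j])

    if neg and pos:
        best_neg = max(neg, key=lambda i: (sm[i], offs[i]))
        best_pos = max(pos, key=lambda i: (sm[i], -offs[i]))
        return CurveMetrics(width, (refine(best_neg), refine(best_pos)), True)
    return CurveMetrics(width, (refine(imax),), False)
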