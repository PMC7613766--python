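"""Binned signal tracks, summit-window aggregation, and strength-cohort
statistics for knockdown comparisons.

The analyses here reproduce the cohort logic used for factor-depletion
ChIP-seq experiments: peaks are ranked by strength into equal cohorts, a
per-peak statistic (fold change, signal ratio, absolute loss) is averaged per
cohort, and cohorts are compared by one-way ANOVA with a Tukey HSD post hoc
test.  The GFI1-anchored normalization rescales knockdown-condition factor
signal by a single global scalar chosen so that total GFI1 signal over peak
windows is equal between conditions, removing track-wide depth artifacts
without cancelling locus-level biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import CohortTable, PeakSet

__all__ = [
    "SignalTrack",
    "window_signal",
    "cohort_summary",
    "CohortSummary",
    "fold_change",
    "gfi1_anchor_factor",
    "apply_anchor",
    "lsd1_gfi1_ratio",
    "cohort_loss",
    "loss_correlation",
    "strength_signal_relation",
]


@dataclass
class SignalTrack:
    """Per-chromosome binned, non-negative coverage for one factor/mark in
    one condition.  ``data[chrom][i]`` is the signal of the bin spanning
    ``[i*bin_size, (i+1)*bin_size)``."""

    data: dict[str, np.ndarray]
    bin_size: int
    factor: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be > 0")

    def window_mean(self, chrom: str, summit: int, h: int) -> float:
        """Mean of bins whose centers lie in ``[summit-h, summit+h)``.

        Windows partially off the chromosome use the available bins; a window
        entirely off the chromosome is an error.  If no bin center falls in a
        very narrow window, the bin containing the summit is used.
        """
        if h <= 0:
            raise ValueError("half-window must be > 0")
        values = self.data[chrom]
        b = self.bin_size
        lo = math_ceil((summit - h) / b - 0.5)
        hi = math_ceil((summit + h) / b - 0.5)
        if hi <= 0 or lo >= len(values):
            raise ValueError(
                f"window around {chrom}:{summit} entirely off the chromosome"
            )
        lo_c, hi_c = max(lo, 0), min(hi, len(values))
        if hi_c <= lo_c:  # window narrower than one bin
            i = min(max(summit // b, 0), len(values) - 1)
            return float(values[i])
        return float(values[lo_c:hi_c].mean())

    def to_bedgraph(self, path, skip_zero: bool = True) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                vals = self.data[chrom]
                for i, v in enumerate(vals):
                    if skip_zero and v == 0:
                        continue
                    fh.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:g}\n")

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: Mapping[str, int],
                      bin_size: int, factor: str = "", condition: str = "") -> "SignalTrack":
        data = {c: np.zeros(-(-int(n) // bin_size)) for c, n in chrom_sizes.items()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")
                s, e, v = int(s), int(e), float(v)
                if s % bin_size or (e - s) != bin_size:
                    raise ValueError(f"{path}:{lineno}: interval not aligned to {bin_size} bp bins")
                data[chrom][s // bin_size] = v
        return cls(data, bin_size, factor=factor, condition=condition)


def math_ceil(x: float) -> int:
    return int(np.ceil(x))


def window_signal(track: SignalTrack, peaks: PeakSet, h: int) -> pd.Series:
    """Mean track signal in ``[summit-h, summit+h)`` for every peak.

    Returns a Series indexed by peak name, in peak order.
    """
    values = [
        track.window_mean(p.chrom, int(p.summit), h)
        for p in peaks.df.itertuples(index=False)
    ]
    return pd.Series(values, index=peaks.df["name"].to_numpy(), name=f"{track.factor}_{track.condition}")


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-cohort mean/SEM of a per-peak statistic plus ANOVA and Tukey HSD.

    ``tukey_p.loc[i, j]`` is the Tukey-adjusted p-value comparing cohorts i
    and j; ``table`` is indexed by cohort (1 = strongest).
    """

    table: pd.DataFrame          # columns: mean, sem, n
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame
    values: pd.Series            # per-peak statistic (retained peaks only)
    cohorts: pd.Series           # peak name -> cohort

    def significant_vs_bottom(
        self,
        alpha: float = 0.01,
        bottom: Sequence[int] | None = None,
        direction: str | None = None,
    ) -> list[int]:
        """Cohorts (outside ``bottom``) whose Tukey contrast against *every*
        bottom cohort is significant at ``alpha``; ``direction`` restricts to
        cohorts whose mean is 'greater' or 'less' than all bottom means."""
        k = len(self.table)
        bottom = list(bottom) if bottom is not None else list(range(k - 4, k + 1))
        means = self.table["mean"]
        out = []
        for c in self.table.index:
            if c in bottom:
                continue
            ok = all(self.tukey_p.loc[c, b] < alpha for b in bottom)
            if ok and direction == "greater":
                ok = all(means[c] > means[b] for b in bottom)
            elif ok and direction == "less":
                ok = all(means[c] < means[b] for b in bottom)
            if ok:
                out.append(c)
        return out


def cohort_summary(values: pd.Series, cohorts: CohortTable) -> CohortSummary:
    """Summarize a per-peak statistic over strength cohorts."""
    missing = [n for n in cohorts.retained if n not in values.index]
    if missing:
        raise ValueError(f"{len(missing)} cohort peak(s) missing from the statistic, e.g. {missing[0]!r}")
    groups = [values.loc[cohorts.members(k)].to_numpy(float)
              for k in range(1, cohorts.n_cohorts + 1)]
    table = pd.DataFrame(
        {
            "mean": [g.mean() for g in groups],
            "sem": [stats.sem(g) if len(g) > 1 else 0.0 for g in groups],
            "n": [len(g) for g in groups],
        },
        index=pd.Index(range(1, cohorts.n_cohorts + 1), name="cohort"),
    )
    f, p = stats.f_oneway(*groups)
    res = stats.tukey_hsd(*groups)
    idx = table.index
    tukey = pd.DataFrame(res.pvalue, index=idx, columns=idx)
    retained = values.loc[cohorts.retained]
    return CohortSummary(table, float(f), float(p), tukey, retained,
                         cohorts.assignments.copy())


def fold_change(
    kd: pd.Series,
    ntc: pd.Series,
    cohorts: CohortTable,
    pseudocount: float = 0.5,
) -> tuple[pd.Series, CohortSummary]:
    """Per-peak knockdown/control fold change ``(kd+eps)/(ntc+eps)`` and its
    cohort summary.  Both window signals must cover the same peak universe."""
    if not kd.index.equals(ntc.index):
        raise ValueError("fold_change: KD and NTC window signals cover different peaks")
    fc = (kd + pseudocount) / (ntc + pseudocount)
    fc.name = "fold_change"
    return fc, cohort_summary(fc, cohorts)


def gfi1_anchor_factor(gfi1_kd: pd.Series, gfi1_ntc: pd.Series) -> float:
    """Global scalar that equalizes total GFI1 window signal between
    conditions: ``sum(NTC) / sum(KD)``.  Multiplying knockdown-condition
    factor signals by this scalar implements the "constant GFI1" anchor."""
    if not gfi1_kd.index.equals(gfi1_ntc.index):
        raise ValueError("anchor: KD and NTC window signals cover different peaks")
    denom = float(gfi1_kd.sum())
    if denom == 0:
        raise ValueError("anchor: knockdown GFI1 signal sums to zero")
    return float(gfi1_ntc.sum()) / denom


def apply_anchor(window: pd.Series, factor: float) -> pd.Series:
    return window * factor


def lsd1_gfi1_ratio(
    lsd1_kd: pd.Series,
    lsd1_ntc: pd.Series,
    gfi1_kd: pd.Series,
    gfi1_ntc: pd.Series,
    cohorts: CohortTable,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, CohortSummary]:
    """Per-peak LSD1:GFI1 signal ratio in each condition and the cohort
    summary of the knockdown/control ratio change.

    Expects the GFI1 anchor factor to have been applied to the KD window
    signals already.  Returns a frame with ``ratio_ntc``, ``ratio_kd`` and
    ``change = ratio_kd / ratio_ntc`` plus the CohortSummary of ``change``.
    """
    for s in (lsd1_ntc, gfi1_kd, gfi1_ntc):
        if not lsd1_kd.index.equals(s.index):
            raise ValueError("ratio: window signals cover different peaks")
    r_ntc = (lsd1_ntc + pseudocount) / (gfi1_ntc + pseudocount)
    r_kd = (lsd1_kd + pseudocount) / (gfi1_kd + pseudocount)
    change = r_kd / r_ntc
    frame = pd.DataFrame({"ratio_ntc": r_ntc, "ratio_kd": r_kd, "change": change})
    return frame, cohort_summary(change, cohorts)


def cohort_loss(ntc: pd.Series, kd: pd.Series, cohorts: CohortTable) -> pd.Series:
    """Mean absolute signal loss ``mean(NTC) - mean(KD)`` per cohort."""
    if not ntc.index.equals(kd.index):
        raise ValueError("loss: KD and NTC window signals cover different peaks")
    loss = ntc - kd
    return pd.Series(
        [loss.loc[cohorts.members(k)].mean() for k in range(1, cohorts.n_cohorts + 1)],
        index=pd.Index(range(1, cohorts.n_cohorts + 1), name="cohort"),
        name="loss",
    )


def loss_correlation(loss_a: pd.Series, loss_b: pd.Series) -> tuple[float, float]:
    """Pearson correlation of two per-cohort mean absolute losses."""
    if len(loss_a) < 3 or len(loss_b) != len(loss_a):
        raise ValueError("loss_correlation needs >= 3 matched cohort points")
    r, p = stats.pearsonr(loss_a.to_numpy(float), loss_b.to_numpy(float))
    return float(r), float(p)


@dataclass
class StrengthRelation:
    """Boxplot statistics of a mark per strength cohort plus a monotonicity
    test (Spearman of cohort index vs cohort median)."""

    table: pd.DataFrame  # median, q25, q75, p5, p95, n per cohort
    spearman_rho: float
    spearman_p: float


def strength_signal_relation(mark: pd.Series, cohorts: CohortTable) -> StrengthRelation:
    rows = []
    for k in range(1, cohorts.n_cohorts + 1):
        g = mark.loc[cohorts.members(k)].to_numpy(float)
        rows.append({
            "median": np.median(g),
            "q25": np.percentile(g, 25),
            "q75": np.percentile(g, 75),
            "p5": np.percentile(g, 5),
            "p95": np.percentile(g, 95),
            "n": len(g),
        })
    table = pd.DataFrame(rows, index=pd.Index(range(1, cohorts.n_cohorts + 1), name="cohort"))
    rho, p = stats.spearmanr(table.index.to_numpy(), table["median"].to_numpy())
    return StrengthRelation(table, float(rho), float(p))
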