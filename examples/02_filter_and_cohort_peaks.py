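"""Stringent peak filtering, strong-peak selection and strength cohorts.

Reproduces the worked arithmetic of the filtering scheme: with 18,385 peaks
of which 3,797 reach pileup >= 110, the strong fraction is 20.7%, and ten
equal strength cohorts hold 1,838 peaks each with 5 discarded.
"""

import numpy as np
import pandas as pd

import cooccupy as cp

pileups = np.concatenate([np.linspace(110, 900, 3797),
                          np.linspace(50, 109.9, 18385 - 3797)])
starts = np.arange(len(pileups)) * 1000
peaks = cp.PeakSet(pd.DataFrame({
    "chrom": "chr1", "start": starts, "end": starts + 200,
    "summit": starts + 100, "pileup": pileups, "fold_enrichment": 10.0,
    "name": [f"p{i}" for i in range(len(pileups))],
}), factor="hmg20b")

filtered = cp.filter_peaks(peaks, min_pileup=50, min_fe=5)
print(f"peaks passing pileup >= 50 and fold enrichment >= 5: {len(filtered):,}")

strong, frac = cp.select_top(filtered, 110)
print(f"strong peaks (pileup >= 110): {len(strong):,} = {frac}% of all peaks")

cohorts = cp.assign_cohorts(filtered, 10)
print(f"ten strength cohorts of {cohorts.cohort_size:,} peaks each, "
      f"{len(cohorts.discarded)} weakest discarded")
# Cohort 1 holds the strongest peaks; all downstream knockdown analyses
# average their per-peak statistics within these cohorts.
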