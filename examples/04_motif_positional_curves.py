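"""Motif positional-probability curves around peak summits.

Scans the synthetic genome for the GFI1-like consensus and builds curves
anchored on each factor's summits.  The motif-bound factor (GFI1) gives a
narrow curve peaking at offset 0; the partner factors give broader, bimodal
curves with apexes offset ~9 bp to each side, reflecting the planted
side-consistent geometry.
"""

import cooccupy as cp

cfg = cp.SimulationConfig(seed=1)
genome = cp.generate_genome(cfg)
truth = cp.plant_sites(genome, cfg)
peaks = cp.emit_peaks(truth, genome, cfg)

occurrences = cp.scan_consensus(genome, cfg.motif_consensus)
print(f"consensus {cfg.motif_consensus}: {len(occurrences)} occurrences "
      f"on both strands ({len(truth.sites)} planted)")

for factor in ("gfi1", "hmg20b", "lsd1"):
    curve = cp.positional_curve(occurrences, peaks[factor], W=250)
    m = cp.curve_metrics(curve)
    shape = f"bimodal apexes at {m.apexes} bp" if m.bimodal \
        else f"single apex at {m.apexes[0]} bp"
    print(f"{factor:>7}: enriched width {m.width} bp, {shape}")
# The width ordering (GFI1 narrowest) and the ±9 bp partner apexes recover
# the planted offset geometry from sequence alone.
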