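"""Generate a synthetic co-occupancy dataset and write it in standard formats.

Builds a 2 x 4 Mb genome with 2,000 motif-anchored GFI1/HMG20B/LSD1 triple
sites plus 500 CEBPA-like control sites, then writes the genome (FASTA), the
peak calls (narrowPeak + MACS2 xls), two signal tracks (bedGraph), the gene
table, the knockdown-response ranked list (RNK) and the ground-truth tables
(TSV) into ./scratch_example_data/.
"""

from pathlib import Path

import cooccupy as cp

out = Path("scratch_example_data")
out.mkdir(exist_ok=True)

cfg = cp.SimulationConfig(seed=1)
genome = cp.generate_genome(cfg)
truth = cp.plant_sites(genome, cfg)
tracks = cp.render_tracks(truth, genome, cfg)
peaks = cp.emit_peaks(truth, genome, cfg)
genes, ranked, gene_truth = cp.generate_genes_and_expression(truth, genome, cfg)

genome.write_fasta(out / "genome.fa")
for factor, ps in peaks.items():
    cp.write_narrowpeak(ps, out / f"{factor}.narrowPeak")
    cp.write_macs2_xls(ps, out / f"{factor}_peaks.xls")
tracks[("h3k27ac", "ntc")].to_bedgraph(out / "h3k27ac_ntc.bedGraph")
tracks[("h3k27ac", "kd")].to_bedgraph(out / "h3k27ac_kd.bedGraph")
genes.to_csv(out / "genes.tsv", sep="\t", index=False)
cp.write_rnk(ranked, out / "knockdown_response.rnk")
truth.write_tsv(out / "truth_sites.tsv", out / "truth_control_sites.tsv")

print(f"genome: {sum(genome.lengths.values()):,} bp over {len(genome.lengths)} chromosomes")
print(f"triple sites: {len(truth.sites)}  control sites: {len(truth.control_sites)}")
print(f"peaks per factor: { {f: len(ps) for f, ps in peaks.items()} }")
print(f"genes: {len(genes)}  ranked (expressed): {len(ranked)}")
print(f"wrote files to {out}/")
# Every planted site yields one peak per factor; the truth tables record the
# planted offsets, strengths and knockdown retentions that the analysis
# modules are expected to recover.
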