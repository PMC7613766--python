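"""Ground-truth simulator for the co-occupancy analysis.

Emulates the statistical structure the downstream analyses assume: a
sequence-specific factor (GFI1-like) binds a planted consensus motif, and two
partner factors (HMG20B- and LSD1-like) co-occupy chromatin at a shared,
side-consistent offset from the motif.  Peak strengths are lognormal and
rank-correlated across factors; knockdown attenuates factor signal only at
strong sites; histone acetylation and accessibility are inversely related to
repressor strength at strong sites; a strength-neutral control factor
(CEBPA-like) binds elsewhere without motif or knockdown response; genes near
strong sites respond transcriptionally to the knockdown.

Every operation is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import PeakSet
from .signal_cohort import SignalTrack

__all__ = [
    "SimulationConfig",
    "GenomeModel",
    "TruthTable",
    "generate_genome",
    "plant_sites",
    "render_tracks",
    "emit_peaks",
    "generate_genes_and_expression",
    "write_rnk",
    "read_rnk",
]

# salts so each operation draws from its own independent stream of the seed
_SALT_GENOME, _SALT_SITES, _SALT_TRACKS, _SALT_PEAKS, _SALT_GENES = range(101, 106)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable generator parameters.  ``seed`` is mandatory.

    Offsets: each planted site draws a side ``s`` uniformly from {-1, +1};
    partner summits sit at ``GFI1 summit + s*d`` where ``d`` is the modal
    offset plus truncated-normal noise (d >= 0), and each partner adds an
    independent uniform jitter of up to ``partner_jitter`` bp.
    """

    seed: int
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 4_000_000}
    )
    n_sites: int = 2000
    n_control_sites: int = 500
    min_spacing: int = 2000          # windows of +/-1 kb never overlap
    margin: int = 1000
    # offset geometry (bp)
    offset_modal: float = 9.0
    offset_sd: float = 2.0
    partner_jitter: int = 2
    colocalized_frac: float = 0.95   # fraction of sites with partners within reach
    # strengths (pileup units): floor + lognormal, Gaussian-copula correlated
    strength_floor: float = 50.0
    strength_mu: float = math.log(40.0)
    strength_sigma: float = 1.0
    strength_rho: float = 0.9
    fe_floor: float = 5.0
    # motif
    motif_consensus: str = "TAAATCACWGC"  # configurable GFI1-like consensus
    # tracks
    bin_size: int = 10
    bump_sd: float = 75.0
    noise: bool = True               # Poisson noise per bin
    kd_depth_scale: float = 0.8      # technical depth scale on all KD factor tracks
    # knockdown biology (fractions are of sites, ranked by HMG20B strength)
    hmg20b_retention: float = 0.4
    hmg20b_kd_top_frac: float = 0.4
    lsd1_retention: float = 0.6
    lsd1_kd_top_frac: float = 0.4
    lsd1_coupled: bool = True        # False: no LSD1 knockdown response at all
    # chromatin marks
    k27_base_amp: float = 30.0
    atac_base_amp: float = 30.0
    k4me1_amp: float = 20.0
    inverse_top_frac: float = 0.3    # strongest sites have depressed K27Ac/ATAC
    k27_gain: float = 1.0            # KD multiplies K27Ac bump by (1 + gain) at top sites
    k27_gain_top_frac: float = 0.3
    # genes and expression
    n_genes: int = 1200
    promoter_gene_frac: float = 0.6
    gene_length: int = 5000
    responsive_top_frac: float = 0.3
    expression_effect: float = 3.0
    expression_noise_sd: float = 1.0
    fpkm_min: float = 0.25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("offset_sd", "expression_noise_sd", "bump_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.motif_consensus:
            raise ValueError("motif consensus must be non-empty")
        bad = set(self.motif_consensus.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in consensus")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be > 0")
        if self.bin_size <= 0:
            raise ValueError("bin size must be > 0")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), salt])


@dataclass
class GenomeModel:
    """Chromosome names, lengths and (mutable) sequences."""

    lengths: dict[str, int]
    sequences: dict[str, bytearray]

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("chromosome names must be unique")

    def as_strings(self) -> dict[str, str]:
        return {c: bytes(s).decode("ascii") for c, s in self.sequences.items()}

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(bytes(seq).decode("ascii")), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path) -> "GenomeModel":
        seqs = {r.id: bytearray(str(r.seq).upper().encode("ascii"))
                for r in SeqIO.parse(str(path), "fasta")}
        return cls({c: len(s) for c, s in seqs.items()}, seqs)


@dataclass
class TruthTable:
    """Planted ground truth: one row per triple site, plus control sites.

    ``sites`` columns include the three factor summits, the shared side and
    offset, per-factor strengths and knockdown retention fractions, mark bump
    amplitudes, the acetylation knockdown gain, and responsiveness flags.
    """

    sites: pd.DataFrame
    control_sites: pd.DataFrame

    def write_tsv(self, sites_path, control_path=None) -> None:
        self.sites.to_csv(sites_path, sep="\t", index=False)
        if control_path is not None:
            self.control_sites.to_csv(control_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> GenomeModel:
    """Random genome with uniform base composition (motifs are planted later
    by :func:`plant_sites`)."""
    rng = config.rng(_SALT_GENOME)
    sequences = {}
    for chrom, length in config.chrom_lengths.items():
        idx = rng.integers(0, 4, size=int(length))
        sequences[chrom] = bytearray(_BASES[idx].tobytes())
    return GenomeModel({c: int(l) for c, l in config.chrom_lengths.items()}, sequences)


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

def _site_positions(genome: GenomeModel, config: SimulationConfig,
                    n_total: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Positions on a jittered grid guaranteeing >= min_spacing separation."""
    jitter_max = 512
    pitch = config.min_spacing + jitter_max
    slots: list[tuple[str, int]] = []
    for chrom, length in genome.lengths.items():
        usable = length - 2 * config.margin
        n_slots = max(usable // pitch, 0)
        slots.extend((chrom, s) for s in range(n_slots))
    if n_total > len(slots):
        raise ValueError(
            f"genome too small: {n_total} sites requested but only {len(slots)} "
            f"slots at {config.min_spacing} bp spacing"
        )
    chosen = rng.permutation(len(slots))[:n_total]
    positions = []
    for i in sorted(chosen):
        chrom, slot = slots[i]
        pos = config.margin + slot * pitch + int(rng.integers(0, jitter_max))
        positions.append((chrom, pos))
    return positions


def _realize_motif(consensus: str, rng: np.random.Generator) -> bytes:
    return bytes(
        ord(rng.choice(list(IUPAC_CODES[c.upper()]))) for c in consensus
    )


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def plant_sites(genome: GenomeModel, config: SimulationConfig) -> TruthTable:
    """Plant motif-anchored triple sites and control-factor sites.

    Mutates ``genome`` by writing one exact-consensus motif instance centered
    at each triple site's GFI1 summit (random strand).  Control sites carry
    no motif and no knockdown response.
    """
    rng = config.rng(_SALT_SITES)
    n, n_ctl = config.n_sites, config.n_control_sites
    positions = _site_positions(genome, config, n + n_ctl, rng)
    rng.shuffle(positions)
    site_pos, ctl_pos = positions[:n], positions[n:]

    # offset geometry
    side = rng.choice([-1, 1], size=n)
    d = config.offset_modal + config.offset_sd * rng.standard_normal(n)
    while np.any(d < 0):  # truncated at zero
        bad = d < 0
        d[bad] = config.offset_modal + config.offset_sd * rng.standard_normal(bad.sum())
    d = np.rint(d).astype(int)
    j = config.partner_jitter
    jit_h = rng.integers(-j, j + 1, size=n) if j > 0 else np.zeros(n, dtype=int)
    jit_l = rng.integers(-j, j + 1, size=n) if j > 0 else np.zeros(n, dtype=int)

    coloc = rng.random(n) < config.colocalized_frac
    # displaced partners go to opposite sides so no pair stays within reach
    disp_side = rng.choice([-1, 1], size=n)
    disp_h = np.where(coloc, 0, disp_side * rng.integers(300, 801, size=n))
    disp_l = np.where(coloc, 0, -disp_side * rng.integers(300, 801, size=n))

    g_summit = np.array([p for _, p in site_pos])
    chroms = np.array([c for c, _ in site_pos])
    h_summit = g_summit + np.where(coloc, side * d + jit_h, disp_h)
    l_summit = g_summit + np.where(coloc, side * d + jit_l, disp_l)

    # correlated lognormal strengths (Gaussian copula, common rho)
    rho = config.strength_rho
    cov = np.full((3, 3), rho) + np.eye(3) * (1 - rho)
    z = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    strengths = config.strength_floor + np.exp(
        config.strength_mu + config.strength_sigma * z
    )
    s_h, s_l, s_g = strengths[:, 0], strengths[:, 1], strengths[:, 2]

    # knockdown biology keyed to HMG20B strength rank (fraction of sites,
    # 0 = strongest)
    rank_frac = (np.argsort(np.argsort(-s_h)) + 0.5) / n
    ret_h = np.where(rank_frac <= config.hmg20b_kd_top_frac, config.hmg20b_retention, 1.0)
    if config.lsd1_coupled:
        in_band = rank_frac <= config.lsd1_kd_top_frac
        ret_l = np.where(in_band, config.lsd1_retention, 1.0)
    else:  # uncoupled null: LSD1 does not respond to the knockdown
        ret_l = np.ones(n)

    # inverse strength ~ acetylation/accessibility at strong sites
    thr = np.quantile(s_h, 1 - config.inverse_top_frac)
    damp = np.minimum(1.0, thr / s_h)
    k27_amp = config.k27_base_amp * damp
    atac_amp = config.atac_base_amp * damp
    k27_gain = np.where(rank_frac <= config.k27_gain_top_frac, config.k27_gain, 0.0)
    responsive = rank_frac <= config.responsive_top_frac

    # plant exactly one motif instance centered at each GFI1 summit
    L = len(config.motif_consensus)
    strands = rng.choice(["+", "-"], size=n)
    for chrom, pos, strand in zip(chroms, g_summit, strands):
        motif = _realize_motif(config.motif_consensus, rng)
        if strand == "-":
            motif = motif.translate(_COMPLEMENT)[::-1]
        start = int(pos) - L // 2
        genome.sequences[chrom][start:start + L] = motif

    sites = pd.DataFrame({
        "site_id": [f"s{i:05d}" for i in range(n)],
        "chrom": chroms,
        "gfi1_summit": g_summit,
        "side": side,
        "offset_d": d,
        "hmg20b_summit": h_summit,
        "lsd1_summit": l_summit,
        "colocalized": coloc,
        "motif_strand": strands,
        "strength_hmg20b": s_h,
        "strength_lsd1": s_l,
        "strength_gfi1": s_g,
        "ret_hmg20b": ret_h,
        "ret_lsd1": ret_l,
        "ret_gfi1": np.ones(n),
        "k27_amp": k27_amp,
        "atac_amp": atac_amp,
        "k27_gain": k27_gain,
        "responsive": responsive,
    })

    s_ctl = config.strength_floor + rng.lognormal(
        config.strength_mu, config.strength_sigma, size=n_ctl
    )
    # control acetylation rises with control-factor strength but has no
    # knockdown response (strength-neutral control)
    med = np.median(s_ctl) if n_ctl else 1.0
    control = pd.DataFrame({
        "site_id": [f"c{i:05d}" for i in range(n_ctl)],
        "chrom": [c for c, _ in ctl_pos],
        "summit": [p for _, p in ctl_pos],
        "strength": s_ctl,
        "k27_amp": config.k27_base_amp * s_ctl / med if n_ctl else [],
    })

    # invariant: all summits within chromosome bounds
    for frame, cols in ((sites, ["gfi1_summit", "hmg20b_summit", "lsd1_summit"]),
                        (control, ["summit"])):
        for _, row in frame.iterrows():
            for col in cols:
                if not 0 <= row[col] < genome.lengths[row["chrom"]]:
                    raise AssertionError("planted summit outside chromosome bounds")

    return TruthTable(sites, control)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _add_bumps(data: dict[str, np.ndarray], bin_size: int, sd: float,
               chroms, summits, amps) -> None:
    half = int(4 * sd)
    for chrom, summit, amp in zip(chroms, summits, amps):
        if amp <= 0:
            continue
        arr = data[chrom]
        lo = max(0, (int(summit) - half) // bin_size)
        hi = min(len(arr), (int(summit) + half) // bin_size + 1)
        centers = (np.arange(lo, hi) + 0.5) * bin_size
        arr[lo:hi] += amp * np.exp(-((centers - summit) ** 2) / (2 * sd * sd))


def render_tracks(
    truth: TruthTable, genome: GenomeModel, config: SimulationConfig
) -> dict[tuple[str, str], SignalTrack]:
    """Render binned signal tracks per factor/mark and condition.

    Each site contributes a Gaussian bump (sd ``bump_sd``) centered on the
    factor summit with height proportional to strength.  Knockdown multiplies
    bump height by the site's retention fraction, and all knockdown-condition
    factor ChIP tracks are additionally scaled by ``kd_depth_scale`` (a
    track-wide technical artifact the GFI1 anchor is meant to remove).
    H3K27Ac/ATAC bumps follow the planted inverse-strength rule; the H3K27Ac
    knockdown track applies the planted gain at strong sites.  Poisson noise
    is applied per bin on the expected signal when ``config.noise`` is set.
    """
    if config.bin_size <= 0:
        raise ValueError("bin size must be > 0")
    s, ctl = truth.sites, truth.control_sites
    scale = config.kd_depth_scale
    specs: dict[tuple[str, str], list[tuple]] = {
        ("hmg20b", "ntc"): [(s["chrom"], s["hmg20b_summit"], s["strength_hmg20b"])],
        ("hmg20b", "kd"): [(s["chrom"], s["hmg20b_summit"],
                            s["strength_hmg20b"] * s["ret_hmg20b"] * scale)],
        ("lsd1", "ntc"): [(s["chrom"], s["lsd1_summit"], s["strength_lsd1"])],
        ("lsd1", "kd"): [(s["chrom"], s["lsd1_summit"],
                          s["strength_lsd1"] * s["ret_lsd1"] * scale)],
        ("gfi1", "ntc"): [(s["chrom"], s["gfi1_summit"], s["strength_gfi1"])],
        ("gfi1", "kd"): [(s["chrom"], s["gfi1_summit"],
                          s["strength_gfi1"] * s["ret_gfi1"] * scale)],
        ("h3k27ac", "ntc"): [(s["chrom"], s["gfi1_summit"], s["k27_amp"]),
                             (ctl["chrom"], ctl["summit"], ctl["k27_amp"])],
        ("h3k27ac", "kd"): [(s["chrom"], s["gfi1_summit"],
                             s["k27_amp"] * (1 + s["k27_gain"])),
                            (ctl["chrom"], ctl["summit"], ctl["k27_amp"])],
        ("atac", "ntc"): [(s["chrom"], s["gfi1_summit"], s["atac_amp"])],
        ("h3k4me1", "ntc"): [(s["chrom"], s["gfi1_summit"],
                              np.full(len(s), config.k4me1_amp))],
        ("cebpa", "ntc"): [(ctl["chrom"], ctl["summit"], ctl["strength"])],
    }
    rng = config.rng(_SALT_TRACKS)
    tracks: dict[tuple[str, str], SignalTrack] = {}
    for (factor, condition), layers in specs.items():
        data = {c: np.zeros(-(-l // config.bin_size))
                for c, l in genome.lengths.items()}
        for chroms, summits, amps in layers:
            _add_bumps(data, config.bin_size, config.bump_sd,
                       np.asarray(chroms), np.asarray(summits, float),
                       np.asarray(amps, float))
        if config.noise:
            data = {c: rng.poisson(v).astype(float) for c, v in data.items()}
        tracks[(factor, condition)] = SignalTrack(
            data, config.bin_size, factor=factor, condition=condition
        )
    return tracks


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def emit_peaks(truth: TruthTable, genome: GenomeModel,
               config: SimulationConfig) -> dict[str, PeakSet]:
    """One called peak per planted site per factor.

    Pileup is the planted strength plus bounded non-negative noise (so peaks
    re-filtered at the strength floor are all retained); fold enrichment is
    drawn at or above the configured floor; the summit is the planted summit.
    """
    rng = config.rng(_SALT_PEAKS)
    s, ctl = truth.sites, truth.control_sites
    out = {}
    layout = [
        ("hmg20b", s["chrom"], s["hmg20b_summit"], s["strength_hmg20b"], s["site_id"]),
        ("lsd1", s["chrom"], s["lsd1_summit"], s["strength_lsd1"], s["site_id"]),
        ("gfi1", s["chrom"], s["gfi1_summit"], s["strength_gfi1"], s["site_id"]),
        ("cebpa", ctl["chrom"], ctl["summit"], ctl["strength"], ctl["site_id"]),
    ]
    for factor, chroms, summits, strengths, ids in layout:
        k = len(chroms)
        pileup = np.asarray(strengths, float) + rng.random(k)
        fe = config.fe_floor + rng.exponential(2.0, size=k)
        summits = np.asarray(summits, int)
        lengths = np.array([genome.lengths[c] for c in chroms])
        start = np.maximum(summits - 250, 0)
        end = np.minimum(summits + 251, lengths)
        df = pd.DataFrame({
            "chrom": np.asarray(chroms), "start": start, "end": end,
            "summit": summits, "pileup": pileup, "fold_enrichment": fe,
            "name": [f"{factor}_{i}" for i in ids],
        })
        out[factor] = PeakSet(df, factor=factor)
    return out


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------

def generate_genes_and_expression(
    truth: TruthTable, genome: GenomeModel, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Place genes and emit a knockdown-response ranked list.

    A fraction of genes get a TSS within 1 kb of a planted site (one gene per
    site, distinct sites); the rest are distal (> 5 kb from any site).  Genes
    nearest to responsive (strong) sites receive a positive expression score;
    all scores carry Gaussian noise.  Returns ``(gene_table, ranked_scores,
    gene_truth)`` where the ranked Series is sorted by descending score with
    ties broken by gene identifier, after the expressed-gene (FPKM) filter.
    """
    rng = config.rng(_SALT_GENES)
    sites = truth.sites
    n_genes = config.n_genes
    n_prom = int(round(config.promoter_gene_frac * n_genes))
    if n_prom > len(sites):
        raise ValueError(
            f"{n_prom} promoter-proximal genes requested but only "
            f"{len(sites)} planted sites available"
        )
    width = len(str(max(n_genes - 1, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]

    prom_sites = rng.choice(len(sites), size=n_prom, replace=False)
    rows = []
    site_of_gene = {}
    for gi, si in zip(range(n_prom), prom_sites):
        row = sites.iloc[si]
        tss = int(row["gfi1_summit"]) + int(rng.integers(-500, 501))
        rows.append((gene_ids[gi], row["chrom"], tss))
        site_of_gene[gene_ids[gi]] = row["site_id"]

    # distal genes: rejection-sample positions > 5 kb from every planted site
    site_pos = {
        c: np.sort(np.concatenate([
            sites.loc[sites["chrom"] == c, "gfi1_summit"].to_numpy(),
            truth.control_sites.loc[truth.control_sites["chrom"] == c, "summit"].to_numpy(),
        ]))
        for c in genome.lengths
    }
    chrom_names = list(genome.lengths)
    gi = n_prom
    while gi < n_genes:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        L = genome.lengths[chrom]
        pos = int(rng.integers(config.gene_length, L - config.gene_length))
        near = site_pos[chrom]
        k = np.searchsorted(near, pos)
        dists = [abs(pos - near[j]) for j in (k - 1, k) if 0 <= j < len(near)]
        if dists and min(dists) <= 5000:
            continue
        rows.append((gene_ids[gi], chrom, pos))
        gi += 1

    glen = config.gene_length
    records = []
    for gene_id, chrom, tss in rows:
        L = genome.lengths[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+" and tss + glen >= L:
            strand = "-"
        if strand == "-" and tss - glen < 0:
            strand = "+"
        tes = tss + glen if strand == "+" else tss - glen
        lo, hi = min(tss, tes), max(tss, tes) + 1
        exon_starts = [lo, hi - 300]
        exon_ends = [lo + 300, hi]
        cds_lo, cds_hi = lo + 100, hi - 100
        records.append({
            "gene_id": gene_id, "chrom": chrom, "strand": strand,
            "tss": tss, "tes": tes,
            "exon_starts": ",".join(map(str, exon_starts)),
            "exon_ends": ",".join(map(str, exon_ends)),
            "cds_lo": cds_lo, "cds_hi": cds_hi,
        })
    genes = pd.DataFrame(records).sort_values("gene_id").reset_index(drop=True)

    # responsiveness: the gene nearest each responsive site is upregulated
    tss_by_chrom = {
        c: grp.sort_values(["tss", "gene_id"])[["tss", "gene_id"]]
        for c, grp in genes.groupby("chrom")
    }
    responsive_genes: set[str] = set()
    for row in sites.loc[sites["responsive"]].itertuples(index=False):
        grp = tss_by_chrom.get(row.chrom)
        if grp is None or len(grp) == 0:
            continue
        tss_arr = grp["tss"].to_numpy()
        k = np.searchsorted(tss_arr, row.gfi1_summit)
        best = None
        for jj in (k - 1, k, k + 1):
            if 0 <= jj < len(grp):
                cand = (abs(int(tss_arr[jj]) - int(row.gfi1_summit)),
                        grp["gene_id"].iloc[jj])
                if best is None or cand < best:  # tie -> lower gene id
                    best = cand
        responsive_genes.add(best[1])

    resp = genes["gene_id"].isin(responsive_genes).to_numpy()
    score = config.expression_effect * resp + \
        config.expression_noise_sd * rng.standard_normal(n_genes)
    fpkm = rng.lognormal(math.log(10.0), 1.0, size=n_genes)
    gene_truth = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "site_id": genes["gene_id"].map(site_of_gene).fillna(""),
        "responsive": resp,
        "fpkm": fpkm,
        "score": score,
    })
    expressed = gene_truth[gene_truth["fpkm"] >= config.fpkm_min]
    ranked = (
        expressed.sort_values(["score", "gene_id"], ascending=[False, True])
        .set_index("gene_id")["score"]
    )
    return genes, ranked, gene_truth


def write_rnk(ranked: pd.Series, path) -> None:
    ranked.to_csv(path, sep="\t", header=False)


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"],
                     float_precision="round_trip")
    return df.set_index("gene_id")["score"]
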