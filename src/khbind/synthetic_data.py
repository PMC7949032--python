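"""Synthetic input generators for every analysis stage.

Each generator emulates the statistical structure of one experiment so the
downstream analysis is testable end to end without any external data:

* SELEX read pools — 20-nt uniform-random inserts flanked by the library's
  two 23-nt primers, with a motif planted in a configurable fraction of the
  positive pool at a uniformly random offset;
* NMR titrations — per-residue amide shifts following the single-site
  fast-exchange isotherm over the molar-ratio grid 0/0.2/0.5/1/2/5 at
  0.2 mM protein, with additive Gaussian noise;
* helicase time courses — linear-to-plateau % unwinding converted to raw
  lane intensities with background, plus no-enzyme and heat-denatured
  control lanes;
* a toy genome — genes with exons/UTRs on a single chromosome and peaks
  placed in known categories, with the truth table saved alongside.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nmr_csp import PeakList, TitrationSeries, bound_fraction
from .peak_annotation import PRIORITY
from .unwinding_kinetics import LaneQuant, UnwindingTimeCourse, timecourse_from_lanes

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "SelexSimConfig",
    "TitrationSimConfig",
    "UnwindingSimConfig",
    "GenomeSimConfig",
    "gen_selex_pools",
    "gen_titration",
    "gen_unwinding_timecourse",
    "gen_unwinding_panel",
    "gen_toy_genome",
]

#: the 23-nt PCR primers flanking the 20-nt random insert of the selection library
FORWARD_PRIMER = "TAGGGAAGAGAAGGACATATGAT"
REVERSE_PRIMER = "TCAAGTGGTCATGTACTAGTCAA"

_BASES = np.array(list("ACGT"))
_DNA = set("ACGT")


def _check_dna(s: str, what: str) -> str:
    s = s.upper()
    if not s or set(s) - _DNA:
        raise ValueError(f"{what} must be a non-empty DNA string over ACGT")
    return s


@dataclass
class SelexSimConfig:
    n_positive_reads: int = 5000
    n_control_reads: int = 5000
    insert_length: int = 20
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    planted_motif: str = "TCGT"
    enrichment_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        self.forward_primer = _check_dna(self.forward_primer, "forward_primer")
        self.reverse_primer = _check_dna(self.reverse_primer, "reverse_primer")
        self.planted_motif = _check_dna(self.planted_motif, "planted_motif")
        if not 0 <= self.enrichment_fraction <= 1:
            raise ValueError("enrichment_fraction must lie in [0, 1]")
        if self.insert_length < len(self.planted_motif):
            raise ValueError("planted motif longer than the insert")
        if min(self.n_positive_reads, self.n_control_reads) < 0:
            raise ValueError("read counts must be nonnegative")


def _random_inserts(rng, n: int, length: int) -> list[str]:
    mat = _BASES[rng.integers(0, 4, size=(n, length))]
    return ["".join(row) for row in mat]


def gen_selex_pools(cfg: SelexSimConfig, out_dir) -> tuple[Path, Path]:
    """Write positive.fastq / control.fastq pools; returns their paths.

    Every read is forward_primer + insert + reverse_primer with dummy
    Phred+33 qualities ("I").  In the positive pool an
    ``enrichment_fraction`` share of inserts carries the planted motif at a
    uniformly random offset (the motif overwrites insert positions, keeping
    read geometry fixed); control inserts are uniform random.
    """
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L, m = cfg.insert_length, len(cfg.planted_motif)

    pos_inserts = _random_inserts(rng, cfg.n_positive_reads, L)
    carries = rng.random(cfg.n_positive_reads) < cfg.enrichment_fraction
    offsets = rng.integers(0, L - m + 1, size=cfg.n_positive_reads)
    for i in np.flatnonzero(carries):
        s = pos_inserts[i]
        o = offsets[i]
        pos_inserts[i] = s[:o] + cfg.planted_motif + s[o + m :]
    ctrl_inserts = _random_inserts(rng, cfg.n_control_reads, L)

    paths = []
    for label, inserts in (("positive", pos_inserts), ("control", ctrl_inserts)):
        path = out_dir / f"{label}.fastq"
        qual = "I" * (len(cfg.forward_primer) + L + len(cfg.reverse_primer))
        with open(path, "w") as fh:
            for i, insert in enumerate(inserts):
                fh.write(
                    f"@{label}_{i + 1:06d}\n{cfg.forward_primer}{insert}{cfg.reverse_primer}\n+\n{qual}\n"
                )
        paths.append(path)
    return paths[0], paths[1]


@dataclass
class TitrationSimConfig:
    true_kd: float = 1.5  # mM
    protein_conc: float = 0.2  # mM
    molar_ratios: tuple = (0.0, 0.2, 0.5, 1.0, 2.0, 5.0)
    per_residue_max_shifts: dict = field(
        default_factory=lambda: {"84": (0.12, 0.60), "87": (0.10, 0.50)}
    )  # residue -> (ΔδH_max ppm, ΔδN_max ppm)
    noise_sd: float = 0.0  # ppm, on the proton axis (nitrogen gets 5x)
    seed: int = 0

    def __post_init__(self):
        ratios = tuple(self.molar_ratios)
        if ratios[0] != 0 or any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("molar ratios must start at 0 and be strictly increasing")
        if self.true_kd <= 0 or self.protein_conc <= 0:
            raise ValueError("true_kd and protein_conc must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.molar_ratios = ratios


def gen_titration(cfg: TitrationSimConfig) -> TitrationSeries:
    """Simulate a titration series under the fast-exchange isotherm.

    At ligand total L each residue's shift change is
    Δδ_axis = Δδ_axis_max · f_b(P, L, Kd) plus Gaussian noise of sd
    ``noise_sd`` on the proton axis and 5·``noise_sd`` on the nitrogen axis
    (matching the 1/25 weighting of nitrogen in the combined shift, so the
    combined-shift noise is ≈ noise_sd).  Noiseless when noise_sd = 0, and
    all shifts vanish at L = 0.
    """
    rng = np.random.default_rng(cfg.seed)
    residues = sorted(cfg.per_residue_max_shifts)
    # reference (free-state) peak positions, fixed per simulation
    ref = {
        r: (float(rng.uniform(7.0, 9.5)), float(rng.uniform(105.0, 130.0))) for r in residues
    }
    points = []
    for ratio in cfg.molar_ratios:
        L = ratio * cfg.protein_conc
        fb = bound_fraction(cfg.protein_conc, L, cfg.true_kd)
        entries = {}
        for r in residues:
            hmax, nmax = cfg.per_residue_max_shifts[r]
            dh = hmax * fb
            dn = nmax * fb
            if cfg.noise_sd > 0 and L > 0:
                dh += rng.normal(0.0, cfg.noise_sd)
                dn += rng.normal(0.0, 5.0 * cfg.noise_sd)
            entries[r] = (ref[r][0] + dh, ref[r][1] + dn)
        points.append(PeakList(entries=entries, ligand_total=L, protein_total=cfg.protein_conc))
    return TitrationSeries(points=points, protein_total=cfg.protein_conc)


@dataclass
class UnwindingSimConfig:
    duplex_length: int = 13  # bp
    true_rate: float = 2.17  # bp/min
    times: tuple = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0)
    plateau: float = 90.0  # %
    noise_sd: float = 0.0  # percentage points
    background_product: float = 5.0  # intensity units
    residual_substrate: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.duplex_length <= 0:
            raise ValueError("duplex_length must be positive")
        t = tuple(self.times)
        if any(x < 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be nonnegative and strictly increasing")
        if not 0 < self.plateau <= 100:
            raise ValueError("plateau must lie in (0, 100]")
        self.times = t


@dataclass
class SimulatedUnwinding:
    """A simulated unwinding experiment: raw lanes plus the corrected course."""

    timecourse: UnwindingTimeCourse
    lanes: pd.DataFrame  # time_min, P, S, P_ne, S_hd
    control_lanes: dict  # "no_enzyme" / "heat_denatured" -> LaneQuant


def gen_unwinding_timecourse(
    cfg: UnwindingSimConfig, protein: str = "WT", substrate: str = "duplex"
) -> SimulatedUnwinding:
    """Simulate raw gel intensities for a linear-to-plateau unwinding course.

    The true % unwound is min(plateau, 100·rate·t/duplex_length) plus
    Gaussian noise; raw intensities put a constant background on both bands
    (total specific signal fixed at 100 units) so the background-corrected
    quantification recovers the true course exactly at zero noise.  The
    no-enzyme control lane quantifies to 0% and the heat-denatured control
    lane to 100% by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    total = 100.0
    times = np.asarray(cfg.times)
    pct = np.minimum(cfg.plateau, 100.0 * cfg.true_rate * times / cfg.duplex_length)
    if cfg.noise_sd > 0:
        pct = pct + rng.normal(0.0, cfg.noise_sd, size=pct.shape)
    pct = np.clip(pct, 0.0, 100.0)

    lanes = [
        LaneQuant(
            P=cfg.background_product + total * p / 100.0,
            S=cfg.residual_substrate + total * (1.0 - p / 100.0),
            P_ne=cfg.background_product,
            S_hd=cfg.residual_substrate,
        )
        for p in pct
    ]
    controls = {
        "no_enzyme": LaneQuant(
            P=cfg.background_product, S=cfg.residual_substrate + total,
            P_ne=cfg.background_product, S_hd=cfg.residual_substrate,
        ),
        "heat_denatured": LaneQuant(
            P=cfg.background_product + total, S=cfg.residual_substrate,
            P_ne=cfg.background_product, S_hd=cfg.residual_substrate,
        ),
    }
    tc = timecourse_from_lanes(list(times), lanes, protein, substrate, cfg.duplex_length)
    lanes_df = pd.DataFrame(
        {
            "time_min": times,
            "P": [l.P for l in lanes],
            "S": [l.S for l in lanes],
            "P_ne": [l.P_ne for l in lanes],
            "S_hd": [l.S_hd for l in lanes],
        }
    )
    return SimulatedUnwinding(timecourse=tc, lanes=lanes_df, control_lanes=controls)


def gen_unwinding_panel(
    rates: dict,
    duplex_length: int,
    max_time: float = 45.0,
    n_points: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[UnwindingTimeCourse]:
    """Simulate a multi-protein unwinding panel on one substrate.

    ``rates`` maps protein -> true rate (bp/min).  The slowest protein is
    sampled over [0, max_time]; each faster protein is sampled within its
    own linear phase (up to the time it would reach 100% unwound), the way
    kinetic assays time fast enzymes, so every fitted line reflects the
    linear regime.  With the slowest rate equal to duplex_length/max_time
    the reference-level procedure recovers every rate exactly at zero noise.
    """
    if not rates:
        raise ValueError("rates must be non-empty")
    slow = min(rates.values())
    tcs = []
    for i, (protein, rate) in enumerate(sorted(rates.items())):
        if rate <= 0:
            raise ValueError(f"rate for {protein!r} must be positive")
        t_end = max_time if rate == slow else min(max_time, duplex_length / rate)
        times = tuple(np.round(np.linspace(0.0, t_end, n_points), 6))
        cfg = UnwindingSimConfig(
            duplex_length=duplex_length, true_rate=rate, times=times,
            plateau=100.0, noise_sd=noise_sd, seed=seed + 1000 * i,
        )
        tcs.append(gen_unwinding_timecourse(cfg, protein=protein).timecourse)
    return tcs


_DEFAULT_WEIGHTS = {
    "promoter": 0.45,
    "intergenic": 0.25,
    "intron": 0.20,
    "exon": 0.04,
    "five_prime_utr": 0.02,
    "three_prime_utr": 0.02,
    "downstream": 0.02,
}


@dataclass
class GenomeSimConfig:
    n_genes: int = 20
    chrom_length: int = 600_000
    n_peaks: int = 300
    category_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    peak_halfwidth: int = 100  # bp
    promoter_up: int = 2000
    promoter_down: int = 500
    downstream: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.chrom_length <= 0 or self.n_peaks < 0:
            raise ValueError("n_genes/chrom_length must be positive, n_peaks nonnegative")
        bad = set(self.category_weights) - set(PRIORITY)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        w = sum(self.category_weights.values())
        if not np.isclose(w, 1.0):
            raise ValueError("category weights must sum to 1")


def gen_toy_genome(cfg: GenomeSimConfig, out_dir):
    """Write genome.fa, annotation.gtf, peaks.bed and truth.tsv; return paths.

    Genes are laid out evenly on one chromosome, each with three exons (the
    first carrying a 5'UTR, the last a 3'UTR) and alternating strand.  A
    per-base category map painted in priority order (promoter last) gives
    every position its priority-resolved truth category; each peak's
    midpoint is drawn uniformly from the positions of its sampled category,
    so the truth assignment is unambiguous by construction.  Raises if a
    requested category has no available positions (overcrowded genome).
    """
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom, L = "chr1", cfg.chrom_length

    spacing = L // cfg.n_genes
    gene_len = spacing // 3
    if gene_len < 600 or spacing - gene_len <= cfg.promoter_up + cfg.downstream:
        raise ValueError("overcrowded genome: features cannot be placed with clearance")

    code = np.full(L, PRIORITY.index("intergenic"), dtype=np.int8)

    def paint(cat, s, e):
        s, e = max(0, s), min(L, e)
        if e > s:
            code[s:e] = PRIORITY.index(cat)

    gtf_lines = []
    for g in range(cfg.n_genes):
        start = g * spacing + (spacing - gene_len) // 2
        end = start + gene_len
        strand = "+" if g % 2 == 0 else "-"
        exon_len = gene_len // 5
        exons = [
            (start, start + exon_len),
            (start + 2 * exon_len, start + 3 * exon_len),
            (end - exon_len, end),
        ]
        # UTRs take half the terminal exons: long enough that the promoter
        # window reaching promoter_down into the gene cannot cover the whole
        # 5'UTR, which would leave that category with no unambiguous bases
        utr5_len, utr3_len = exon_len // 2, exon_len // 2
        if strand == "+":
            utr5 = (exons[0][0], exons[0][0] + utr5_len)
            utr3 = (exons[2][1] - utr3_len, exons[2][1])
            tss = start
            prom = (tss - cfg.promoter_up, tss + cfg.promoter_down)
            down = (end, end + cfg.downstream)
        else:
            utr5 = (exons[2][1] - utr5_len, exons[2][1])
            utr3 = (exons[0][0], exons[0][0] + utr3_len)
            tss = end - 1
            prom = (tss - cfg.promoter_down + 1, tss + cfg.promoter_up + 1)
            down = (start - cfg.downstream, start)

        # paint in ascending priority so higher priority overwrites
        paint("downstream", *down)
        paint("intron", start, end)
        for es, ee in exons:
            paint("exon", es, ee)
        paint("three_prime_utr", *utr3)
        paint("five_prime_utr", *utr5)
        paint("promoter", *prom)

        gid = f"gene{g + 1:04d}"
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'

        def gtf(feature, s, e):
            gtf_lines.append(
                f"{chrom}\tkhbind_sim\t{feature}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
            )

        gtf(("gene"), start, end)
        for es, ee in exons:
            gtf("exon", es, ee)
        gtf("five_prime_utr", *utr5)
        gtf("three_prime_utr", *utr3)

    # peaks: sample a category, then a midpoint uniformly among its bases
    cats = list(cfg.category_weights)
    probs = np.array([cfg.category_weights[c] for c in cats])
    positions = {}
    hw = cfg.peak_halfwidth
    for c in cats:
        pos = np.flatnonzero(code == PRIORITY.index(c))
        pos = pos[(pos >= hw) & (pos < L - hw)]
        positions[c] = pos
    chosen = rng.choice(len(cats), size=cfg.n_peaks, p=probs)
    bed_lines, truth_rows = [], []
    for i, ci in enumerate(chosen):
        cat = cats[ci]
        if positions[cat].size == 0:
            raise ValueError(f"overcrowded genome: no positions available for category {cat!r}")
        mid = int(rng.choice(positions[cat]))
        start, end = mid - hw, mid + hw + 1  # midpoint (start+end)//2 == mid
        name = f"peak{i + 1:05d}"
        bed_lines.append(f"{chrom}\t{start}\t{end}\t{name}\t{int(rng.integers(100, 1000))}")
        truth_rows.append({"peak": name, "chrom": chrom, "start": start, "end": end, "category": cat})

    fasta_path = out_dir / "genome.fa"
    seq = "".join(_BASES[rng.integers(0, 4, size=L)])
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, L, 80):
            fh.write(seq[i : i + 80] + "\n")

    gtf_path = out_dir / "annotation.gtf"
    gtf_path.write_text("\n".join(gtf_lines) + "\n")
    bed_path = out_dir / "peaks.bed"
    bed_path.write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    truth = pd.DataFrame(truth_rows, columns=["peak", "chrom", "start", "end", "category"])
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return {"fasta": fasta_path, "gtf": gtf_path, "bed": bed_path, "truth": truth_path}
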