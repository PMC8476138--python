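"""Synthetic two-species genome system with planted chromosome fusions.

Generates an "ancestral" karyotype of many small-to-medium chromosomes with
repeat and GC enrichment toward chromosome tails, then derives a second
genome by fusing the shortest chromosomes onto longer partners.  Diploid
variant data are planted at 4-fold degenerate third codon positions so that
expected heterozygosity follows a declining function of chromosome length,
and functional-element retention across targets follows a logistic in
chromosome length and divergence time.  Every stochastic choice is recorded
in a truth table, so each downstream stage can be tested against known
ground truth.

Chromosome lengths are drawn log-uniform over ``length_range``.  The default
range is roughly an order of magnitude below real lepidopteran chromosomes
(which run to tens of Mb) to keep whole-system simulations tractable; the
length *contrast* across the karyotype, which drives every analysis here, is
preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genetic_code import FOURFOLD_PREFIXES, transcript_codons
from .intervals import merge_intervals
from .io import FEATURE_COLUMNS, HIT_COLUMNS, ChromosomeRecord, VariantTable
from .utils import substream

logger = logging.getLogger(__name__)

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome system.

    Rates are per bp, lengths in bp, divergence times in Myr.  ``pi_model``
    is (a, b) of pi(L) = a - b*log10(L), floored at ``pi_floor``.
    ``element_retention_model`` is (c0, c_len, c_time) of the logistic
    retention probability sigmoid(c0 - c_len*L_Mb - c_time*T_Myr).
    """

    n_chromosomes: int = 31
    length_range: tuple[int, int] = (500_000, 4_000_000)
    n_fusions: int = 10
    tail_enrichment: float = 3.0
    gc_center: float = 0.32
    gc_tail_step: float = 0.05  # GC gain per unit tail_enrichment excess
    gc_length_slope: float = 0.02  # GC gain per decade of length below typical
    repeat_intensity: float = 4e-4  # interval starts per bp at chromosome center
    repeat_mean_length: float = 400.0
    repeat_length_exponent: float = 0.5  # short-chromosome repeat excess
    gene_density: float = 1e-4  # genes per bp
    pi_model: tuple[float, float] = (0.16, 0.02)
    pi_floor: float = 1e-4
    n_individuals: int = 4
    mean_dp: int = 30
    low_quality_rate: float = 0.05
    element_retention_model: tuple[float, float, float] = (2.5, 0.8, 0.03)
    divergence_times: tuple[float, ...] = (11.0, 19.0, 26.0, 65.0, 85.0)
    elements_per_mb: float = 600.0
    min_elements_per_chrom: int = 600
    random_pairing: bool = False
    breakpoint_repeat_loss: float = 0.8
    breakpoint_loss_radius_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fusions > self.n_chromosomes // 2:
            raise ValueError("n_fusions must be <= floor(n_chromosomes / 2)")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")
        if self.tail_enrichment < 1:
            raise ValueError("tail_enrichment must be >= 1")
        if not 0 <= self.breakpoint_repeat_loss <= 1:
            raise ValueError("breakpoint_repeat_loss must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth of one realization of the synthetic system."""

    fusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_pi: dict[str, float] = field(default_factory=dict)
    retention: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SimulatedGenome:
    species: str
    records: list[ChromosomeRecord]
    features: pd.DataFrame  # gene/mRNA/exon/CDS/repeat rows

    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.records}

    def record(self, chrom: str) -> ChromosomeRecord:
        return next(r for r in self.records if r.id == chrom)


def _tail_factor(centers_frac: np.ndarray, enrichment: float) -> np.ndarray:
    u = 2.0 * np.abs(centers_frac - 0.5)
    return 1.0 + (enrichment - 1.0) * u**2


def _reference_length(config: SimulationConfig) -> float:
    """Geometric mean of the length range: the 'typical' chromosome."""
    lo, hi = config.length_range
    return float(np.sqrt(lo * hi))


def _random_sequence(length: int, config: SimulationConfig,
                     rng: np.random.Generator) -> str:
    block = 1000
    n_blocks = -(-length // block)
    centers = (np.arange(n_blocks) + 0.5) * block / length
    u = 2.0 * np.abs(np.clip(centers, 0, 1) - 0.5)
    center_gc = config.gc_center + config.gc_length_slope * np.log10(
        _reference_length(config) / length)
    gc = center_gc + (config.tail_enrichment - 1.0) * config.gc_tail_step * u**2
    gc_per_base = np.repeat(np.clip(gc, 0.05, 0.9), block)[:length]
    r_gc = rng.random(length)
    r_pick = rng.random(length) < 0.5
    is_gc = r_gc < gc_per_base
    codes = np.where(is_gc,
                     np.where(r_pick, ord("G"), ord("C")),
                     np.where(r_pick, ord("A"), ord("T"))).astype(np.uint8)
    return codes.tobytes().decode("ascii")


def _place_repeats(length: int, config: SimulationConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    block = 1000
    n_blocks = -(-length // block)
    centers = (np.arange(n_blocks) + 0.5) * block / length
    # shorter chromosomes carry denser repeats, as observed across
    # lepidopteran karyotypes; exponent 0 switches the excess off
    density_scale = (_reference_length(config) / length) \
        ** config.repeat_length_exponent
    lam = config.repeat_intensity * density_scale * _tail_factor(
        np.clip(centers, 0, 1), config.tail_enrichment)
    n_total = rng.poisson(lam.sum() * block)
    if n_total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    blocks = rng.choice(n_blocks, size=n_total, p=lam / lam.sum())
    starts = blocks * block + rng.integers(0, block, size=n_total)
    lens = rng.lognormal(np.log(config.repeat_mean_length), 0.5, size=n_total)
    ends = np.minimum(starts + np.maximum(lens.astype(np.int64), 20), length)
    keep = starts < length
    starts, ends = starts[keep], ends[keep]
    order = np.argsort(starts, kind="stable")
    return starts[order], ends[order]


def _make_gene_rows(chrom: str, homolog: str, gene_idx: int, start: int,
                    strand: str, exon_lens: list[int], intron_lens: list[int]
                    ) -> tuple[list[dict], int]:
    """Feature rows (gene/mRNA/exon/CDS) for one coding gene; returns rows, end."""
    gid = f"{homolog}_g{gene_idx:04d}"
    tid = gid + ".t1"
    rows = []
    pos = start
    exon_rows = []
    for i, elen in enumerate(exon_lens):
        exon_rows.append((pos, pos + elen))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    end = exon_rows[-1][1]
    rows.append({"chrom": chrom, "start": start, "end": end, "strand": strand,
                 "kind": "gene", "id": gid, "parent": "", "phase": -1})
    rows.append({"chrom": chrom, "start": start, "end": end, "strand": strand,
                 "kind": "mRNA", "id": tid, "parent": gid, "phase": -1})
    # phase: bases to skip at the start of each CDS piece, in transcript order
    ordered = exon_rows if strand == "+" else exon_rows[::-1]
    cum = 0
    phases = {}
    for (s, e) in ordered:
        phases[(s, e)] = (3 - cum % 3) % 3
        cum += e - s
    for i, (s, e) in enumerate(exon_rows):
        rows.append({"chrom": chrom, "start": s, "end": e, "strand": strand,
                     "kind": "exon", "id": f"{tid}.exon{i + 1}", "parent": tid,
                     "phase": -1})
        rows.append({"chrom": chrom, "start": s, "end": e, "strand": strand,
                     "kind": "CDS", "id": f"{tid}.cds{i + 1}", "parent": tid,
                     "phase": phases[(s, e)]})
    return rows, end


def simulate_ancestral_genome(config: SimulationConfig
                              ) -> tuple[SimulatedGenome, TruthTable]:
    """Generate the ancestral karyotype with tail-enriched repeats and GC.

    Repeat interval starts follow a position-dependent Poisson intensity
    lambda(x) = lambda0 * (1 + (tail_enrichment - 1) * (2|x/L - 0.5|)^2);
    genes (multi-exon, both strands, CDS length a multiple of 3) are placed
    in repeat-free gaps.  Raises if gene packing is infeasible.
    """
    rng = substream(config.seed, "ancestral")
    lo, hi = config.length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_chromosomes))
    lengths = np.sort(lengths.astype(np.int64))[::-1]  # longest first
    records: list[ChromosomeRecord] = []
    all_rows: list[dict] = []
    for k, length in enumerate(lengths, start=1):
        homolog = f"anc{k:02d}"
        seq = _random_sequence(int(length), config, rng)
        records.append(ChromosomeRecord(id=homolog, species="ancestral",
                                        sequence=seq, homology_group=homolog))
        # genes first: sequential placement with exponential spacing, so a
        # target density is met without rejection sampling
        mean_span = 4 * 375 + 3 * 440  # expected gene span under the draws
        if config.gene_density * mean_span > 0.7:
            raise ValueError(
                "infeasible packing: expected gene span exceeds 70% of the "
                "chromosome; lower gene_density")
        mean_gap = max(200.0, 1.0 / config.gene_density - mean_span)
        n_target = max(2, int(round(length * config.gene_density)))
        gene_spans: list[tuple[int, int]] = []
        pos = int(rng.integers(200, 2000))
        gi = 0
        while True:
            n_ex = int(rng.integers(2, 7))
            exon_lens = [int(rng.integers(50, 201)) * 3 for _ in range(n_ex)]
            intron_lens = [int(rng.integers(80, 801)) for _ in range(n_ex - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            if pos + span + 200 > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            rows, gend = _make_gene_rows(homolog, homolog, gi, pos, strand,
                                         exon_lens, intron_lens)
            all_rows.extend(rows)
            gene_spans.append((pos, gend))
            gi += 1
            pos = gend + 1 + int(rng.exponential(mean_gap))
        if gi < max(2, n_target // 2):
            raise ValueError(
                f"infeasible packing on {homolog}: placed {gi} of "
                f"{n_target} genes; lower gene_density or lengthen "
                "chromosomes")
        # repeats outside gene spans (tail-enriched intensity, then thinned)
        r_starts, r_ends = _place_repeats(int(length), config, rng)
        if gene_spans and r_starts.size:
            g_s = np.array([s for s, _ in gene_spans], dtype=np.int64)
            g_e = np.array([e for _, e in gene_spans], dtype=np.int64)
            # genes are sorted and disjoint: the only candidate overlap for a
            # repeat is the first gene ending after the repeat's start
            i = np.searchsorted(g_e, r_starts, side="right")
            overlaps = (i < len(g_s)) & (g_s[np.minimum(i, len(g_s) - 1)]
                                         < r_ends)
            r_starts, r_ends = r_starts[~overlaps], r_ends[~overlaps]
        r_starts, r_ends = merge_intervals(r_starts, r_ends)
        for i, (s, e) in enumerate(zip(r_starts, r_ends)):
            all_rows.append({"chrom": homolog, "start": int(s), "end": int(e),
                             "strand": ".", "kind": "repeat",
                             "id": f"{homolog}_rep{i:05d}", "parent": "",
                             "phase": -1})
    features = pd.DataFrame(all_rows, columns=FEATURE_COLUMNS)
    genome = SimulatedGenome(species="ancestral", records=records,
                             features=features)
    truth = TruthTable()
    return genome, truth


def apply_fusions(ancestral: SimulatedGenome, config: SimulationConfig,
                  truth: TruthTable | None = None
                  ) -> tuple[SimulatedGenome, TruthTable]:
    """Derive a fused genome: the shortest chromosomes join longer partners.

    By default the k-th shortest chromosome fuses with the k-th longest
    (``random_pairing`` draws partners at random instead, for null
    experiments); orientation (short component at head or tail) is random and
    recorded.  Repeat intervals near the new junction are thinned with
    probability ``breakpoint_repeat_loss``, emulating post-fusion repeat
    loss in the derived lineage.
    """
    rng = substream(config.seed, "fusions")
    truth = truth or TruthTable()
    by_len = sorted(ancestral.records, key=lambda r: r.length)
    n_f = config.n_fusions
    shorts = by_len[:n_f]
    if config.random_pairing:
        partners = list(rng.permutation(len(by_len) - n_f)[:n_f] + n_f)
        longs = [by_len[i] for i in partners]
    else:
        longs = by_len[::-1][:n_f]
    used = {r.id for r in shorts} | {r.id for r in longs}
    unfused = [r for r in ancestral.records if r.id not in used]

    records: list[ChromosomeRecord] = []
    feat = ancestral.features
    out_feats: list[pd.DataFrame] = []
    fusion_rows = []
    chrom_no = 0
    for short, long_ in zip(shorts, longs):
        chrom_no += 1
        new_id = f"chr{chrom_no:02d}"
        short_first = bool(rng.random() < 0.5)
        first, second = (short, long_) if short_first else (long_, short)
        breakpoint = first.length
        seq = first.sequence + second.sequence
        records.append(ChromosomeRecord(
            id=new_id, species="derived", sequence=seq,
            homology_group=f"{first.homology_group}|{second.homology_group}"))
        f1 = feat[feat["chrom"] == first.id].copy()
        f2 = feat[feat["chrom"] == second.id].copy()
        f2["start"] = f2["start"] + breakpoint
        f2["end"] = f2["end"] + breakpoint
        part = pd.concat([f1, f2], ignore_index=True)
        part["chrom"] = new_id
        if config.breakpoint_repeat_loss > 0:
            radius_left = int(first.length * config.breakpoint_loss_radius_frac)
            radius_right = int(second.length * config.breakpoint_loss_radius_frac)
            mid = (part["start"] + part["end"]) // 2
            near = ((mid >= breakpoint - radius_left)
                    & (mid < breakpoint + radius_right)
                    & (part["kind"] == "repeat"))
            drop = near & (rng.random(len(part)) < config.breakpoint_repeat_loss)
            part = part[~drop]
        out_feats.append(part)
        fusion_rows.append({
            "derived_chrom": new_id,
            "left_homolog": first.homology_group,
            "right_homolog": second.homology_group,
            "breakpoint": breakpoint,
            "short_side": "left" if short_first else "right",
            "short_homolog": short.homology_group,
            "long_homolog": long_.homology_group,
            "short_length": short.length,
            "long_length": long_.length,
        })
    for rec in unfused:
        chrom_no += 1
        new_id = f"chr{chrom_no:02d}"
        records.append(ChromosomeRecord(id=new_id, species="derived",
                                        sequence=rec.sequence,
                                        homology_group=rec.homology_group))
        part = feat[feat["chrom"] == rec.id].copy()
        part["chrom"] = new_id
        out_feats.append(part)
    features = (pd.concat(out_feats, ignore_index=True)
                if out_feats else feat.iloc[0:0].copy())
    truth = replace(truth, fusions=pd.DataFrame(fusion_rows))
    derived = SimulatedGenome(species="derived", records=records,
                              features=features)
    return derived, truth


# ---------------------------------------------------------------------------
# variants

# E[2f(1-f)] for f ~ Uniform(0.05, 0.95) = 2*(E[f] - E[f^2]) = 0.365;
# scales target heterozygosity into a segregating-site probability
_MEAN_HET_PER_SEG = 2 * (0.5 - ((0.95 - 0.05) ** 2 / 12 + 0.25))


def fourfold_eligible_positions(genome: SimulatedGenome,
                                chrom: str) -> tuple[np.ndarray, list[str]]:
    """Third-codon positions of 4D-family codons on one chromosome.

    Positions are genome coordinates; the accompanying list holds the
    reference base at each position (in genome orientation).
    """
    rec = genome.record(chrom)
    feats = genome.features
    cds = feats[(feats["chrom"] == chrom) & (feats["kind"] == "CDS")]
    positions: list[np.ndarray] = []
    for tid, grp in cds.groupby("parent", sort=False):
        strand = grp["strand"].iloc[0]
        ivs = list(zip(grp["start"], grp["end"]))
        # generated genes always start at a codon boundary (first phase 0)
        codons, pos = transcript_codons(rec.sequence, ivs, strand, 0)
        if not codons:
            continue
        keep = np.array([c[:2] in FOURFOLD_PREFIXES and "N" not in c
                         for c in codons], dtype=bool)
        positions.append(pos[keep, 2])
    if not positions:
        return np.empty(0, dtype=np.int64), []
    all_pos = np.unique(np.concatenate(positions))
    bases = [rec.sequence[p] for p in all_pos]
    return all_pos, bases


def planted_pi(length: int, config: SimulationConfig) -> float:
    a, b = config.pi_model
    return max(config.pi_floor, a - b * np.log10(length))


def simulate_variants(genome: SimulatedGenome, config: SimulationConfig,
                      truth: TruthTable | None = None
                      ) -> tuple[VariantTable, TruthTable]:
    """Plant diploid variation at 4D-eligible third codon positions.

    Per chromosome, each eligible site segregates with probability chosen so
    expected per-site heterozygosity equals pi(L) of the chromosome it
    currently resides on; allele frequencies are Uniform(0.05, 0.95) and the
    ``n_individuals`` diploid genotypes are binomial draws at that frequency.
    DP is Poisson around ``mean_dp``; a small fraction of genotypes get low
    DP/GQ to exercise downstream filters.
    """
    rng = substream(config.seed, f"variants:{genome.species}")
    truth = truth or TruthTable()
    n_ind = config.n_individuals
    samples = [f"{genome.species}_ind{i + 1}" for i in range(n_ind)]
    chroms_out, pos_out, ref_out, alts_out = [], [], [], []
    gt_blocks, dp_blocks, gq_blocks = [], [], []
    true_pi = dict(truth.true_pi)
    other = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for rec in genome.records:
        pi_target = planted_pi(rec.length, config)
        true_pi[rec.id] = pi_target
        sites, bases = fourfold_eligible_positions(genome, rec.id)
        if sites.size == 0:
            continue
        theta = min(1.0, pi_target / _MEAN_HET_PER_SEG)
        seg = rng.random(sites.size) < theta
        seg_pos = sites[seg]
        n_seg = seg_pos.size
        if n_seg == 0:
            continue
        freqs = rng.uniform(0.05, 0.95, n_seg)
        alt_pick = rng.integers(0, 3, n_seg)
        gts = (rng.random((n_seg, n_ind, 2)) < freqs[:, None, None]).astype(np.int8)
        dp = rng.poisson(config.mean_dp, (n_seg, n_ind)).astype(np.int32)
        gq = np.full((n_seg, n_ind), 99, dtype=np.int32)
        low = rng.random((n_seg, n_ind)) < config.low_quality_rate
        dp[low] = rng.poisson(5, low.sum())
        gq[low] = rng.integers(0, 31, low.sum())
        seg_idx = np.flatnonzero(seg)
        for j in range(n_seg):
            refb = bases[seg_idx[j]]
            chroms_out.append(rec.id)
            pos_out.append(int(seg_pos[j]))
            ref_out.append(refb)
            alts_out.append((other[refb][alt_pick[j]],))
        gt_blocks.append(gts)
        dp_blocks.append(dp)
        gq_blocks.append(gq)
    table = VariantTable(
        samples=samples,
        chroms=np.array(chroms_out, dtype=object),
        pos=np.array(pos_out, dtype=np.int64),
        ref=ref_out, alts=alts_out,
        genotypes=(np.concatenate(gt_blocks) if gt_blocks else None),
        dp=(np.concatenate(dp_blocks) if dp_blocks else None),
        gq=(np.concatenate(gq_blocks) if gq_blocks else None),
    )
    truth = replace(truth, true_pi=true_pi)
    return table, truth


# ---------------------------------------------------------------------------
# functional elements and similarity hits


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_elements_and_hits(genome: SimulatedGenome, config: SimulationConfig,
                               truth: TruthTable | None = None,
                               kinds: tuple[str, ...] = ("CRE", "exon"),
                               ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame],
                                          dict[str, pd.DataFrame], TruthTable]:
    """Plant functional elements and reciprocal-hit tables per divergence time.

    Each element is retained in a target with probability
    sigmoid(c0 - c_len*L_Mb - c_time*T_Myr) where L is the length of the
    chromosome the element sits on.  Retained elements yield a reciprocal
    best-hit pair with evalue well below 1e-10; lost elements yield nothing,
    a one-directional decoy hit, or a reciprocal pair at evalue 1e-5 that any
    compliant threshold must reject.  Divergence is book-kept through these
    hit rows; no sequence mutation or alignment is performed.

    Returns (elements, hits_forward_by_target, hits_reverse_by_target, truth).
    """
    rng = substream(config.seed, f"elements:{genome.species}")
    truth = truth or TruthTable()
    c0, c_len, c_time = config.element_retention_model
    el_rows = []
    for rec in genome.records:
        n_el = max(config.min_elements_per_chrom,
                   int(round(rec.length / 1e6 * config.elements_per_mb)))
        for kind in kinds:
            starts = np.sort(rng.integers(0, max(1, rec.length - 800), n_el))
            lens = rng.integers(200, 801, n_el)
            for i, (s, ln) in enumerate(zip(starts, lens)):
                el_rows.append({
                    "chrom": rec.id, "start": int(s),
                    "end": int(min(s + ln, rec.length)), "strand": ".",
                    "kind": kind, "id": f"{genome.species}_{kind}_{rec.id}_{i:04d}",
                    "parent": "", "phase": -1,
                })
    elements = pd.DataFrame(el_rows, columns=FEATURE_COLUMNS)
    lengths = genome.lengths()
    l_mb = elements["chrom"].map(lengths).to_numpy() / 1e6

    fwd: dict[str, pd.DataFrame] = {}
    rev: dict[str, pd.DataFrame] = {}
    ret_rows = []
    for t in config.divergence_times:
        target = f"target_T{t:g}"
        p = _sigmoid(c0 - c_len * l_mb - c_time * t)
        retained = rng.random(len(elements)) < p
        f_rows, r_rows = [], []
        for eid, kind, chrom, is_ret in zip(elements["id"], elements["kind"],
                                            elements["chrom"], retained):
            subject = f"{target}:{eid}_locus"
            if is_ret:
                ev = 10.0 ** (-rng.uniform(15, 60))
                bs = float(rng.uniform(100, 500))
                f_rows.append((eid, subject, 98.0, 400, 5, 0, 1, 400, 1, 400, ev, bs))
                r_rows.append((subject, eid, 98.0, 400, 5, 0, 1, 400, 1, 400, ev, bs))
            else:
                u = rng.random()
                if u < 0.3:  # one-directional decoy: never an RBH
                    ev = 10.0 ** (-rng.uniform(12, 30))
                    f_rows.append((eid, subject + "_decoy", 90.0, 300, 20, 2,
                                   1, 300, 1, 300, ev, 150.0))
                elif u < 0.5:  # reciprocal but above the e-value threshold
                    f_rows.append((eid, subject, 85.0, 200, 30, 3,
                                   1, 200, 1, 200, 1e-5, 60.0))
                    r_rows.append((subject, eid, 85.0, 200, 30, 3,
                                   1, 200, 1, 200, 1e-5, 60.0))
            ret_rows.append({"element_id": eid, "kind": kind, "chrom": chrom,
                             "target": target, "time": t,
                             "retained": bool(is_ret)})
        fwd[target] = pd.DataFrame(f_rows, columns=HIT_COLUMNS)
        rev[target] = pd.DataFrame(r_rows, columns=HIT_COLUMNS)
    truth = replace(truth, retention=pd.DataFrame(ret_rows))
    return elements, fwd, rev, truth


def write_simulation_outputs(out_dir: str, genome: SimulatedGenome,
                             truth: TruthTable,
                             variants: VariantTable | None = None,
                             elements: pd.DataFrame | None = None,
                             hits_fwd: dict[str, pd.DataFrame] | None = None,
                             hits_rev: dict[str, pd.DataFrame] | None = None,
                             config: SimulationConfig | None = None) -> None:
    """Write one simulated genome and its companions as standard files.

    Emits FASTA, GFF3, repeat BED, VCF, element BED, per-target hit TSVs and
    the truth tables; the config is echoed as key=value lines.
    """
    import dataclasses
    import os

    from .io import write_bed, write_fasta, write_gff3, write_hits, write_vcf

    os.makedirs(out_dir, exist_ok=True)
    tag = genome.species
    write_fasta(genome.records, os.path.join(out_dir, f"{tag}.fa"))
    write_gff3(genome.features, os.path.join(out_dir, f"{tag}.gff3"))
    write_bed(genome.features[genome.features["kind"] == "repeat"],
              os.path.join(out_dir, f"{tag}_repeats.bed"))
    if variants is not None:
        write_vcf(variants, os.path.join(out_dir, f"{tag}.vcf"),
                  contigs=genome.lengths())
    if elements is not None:
        write_bed(elements, os.path.join(out_dir, f"{tag}_elements.bed"))
    for name, tables in (("fwd", hits_fwd), ("rev", hits_rev)):
        for target, table in (tables or {}).items():
            write_hits(table, os.path.join(
                out_dir, f"{tag}_hits_{name}_{target}.tsv"))
    if len(truth.fusions):
        truth.fusions.to_csv(os.path.join(out_dir, "truth_fusions.tsv"),
                             sep="\t", index=False)
    if truth.true_pi:
        pd.DataFrame(sorted(truth.true_pi.items()),
                     columns=["chrom", "pi"]).to_csv(
            os.path.join(out_dir, "truth_pi.tsv"), sep="\t", index=False)
    if len(truth.retention):
        truth.retention.to_csv(os.path.join(out_dir, "truth_retention.tsv"),
                               sep="\t", index=False)
    if config is not None:
        with open(os.path.join(out_dir, f"{tag}_config.txt"), "w") as fh:
            for k, v in dataclasses.asdict(config).items():
                fh.write(f"{k}={v}\n")
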