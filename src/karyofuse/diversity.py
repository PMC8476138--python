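"""Conservative 4-fold degenerate site calling, windowed nucleotide
diversity, per-homolog normalization, and the fixed-map-length
recombination model.

The 4D caller is deliberately conservative: a codon is only scanned if it
falls in the cross-gene non-overlapping CDS set; a codon with observed
variants at more than one of its three positions is discarded outright; and
with a single variant position the third codon position must be 4-fold
degenerate under *every* observed allele, not just the reference.

Diversity is the standard mean-pairwise-difference estimator over all
called alleles at a site, averaged in windows of a fixed number of 4D
sites.  The recombination model assumes one obligate crossover per bivalent
per meiosis, i.e. a fixed genetic map length (default 50 cM) regardless of
physical chromosome length, so the per-bp rate is r = M / L and a fusion
dilutes the rate of both components.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import FOURFOLD_PREFIXES, is_fourfold, transcript_codons
from .io import ChromosomeRecord, VariantTable

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: DP/GQ filter profiles; genotypes are kept on strict inequalities
FILTER_PROFILES = {"default": (10, 30), "low-coverage": (5, 20)}


@dataclass
class FourfoldSiteSet:
    """Validated 4D third-codon positions with provenance counts."""

    sites: pd.DataFrame  # chrom, pos, gene, codon_index, strand
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


# ---------------------------------------------------------------------------
# coding-interval preparation


def nonoverlapping_coding_intervals(annotation: pd.DataFrame
                                    ) -> tuple[pd.DataFrame, int]:
    """Select one transcript per gene and drop cross-gene overlapping CDS.

    The transcript with the longest total CDS wins (ties broken by id); any
    CDS interval of a selected transcript that overlaps a CDS interval of a
    different gene is wholly removed from both.  Returns the retained CDS
    rows and the number of intervals removed for overlap.
    """
    cds = annotation[annotation["kind"] == "CDS"].copy()
    mrna = annotation[annotation["kind"] == "mRNA"]
    gene_of = dict(zip(mrna["id"], mrna["parent"]))
    cds["gene"] = cds["parent"].map(gene_of).fillna(cds["parent"])
    lengths = (cds["end"] - cds["start"]).groupby(cds["parent"]).sum()
    best: dict[str, str] = {}
    for tid in sorted(lengths.index):
        gene = gene_of.get(tid, tid)
        if gene not in best or lengths[tid] > lengths[best[gene]]:
            best[gene] = tid
    cds = cds[cds["parent"].isin(best.values())].reset_index(drop=True)

    drop = np.zeros(len(cds), dtype=bool)
    for _, grp in cds.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        idx = idx[order]
        starts = cds.loc[idx, "start"].to_numpy()
        ends = cds.loc[idx, "end"].to_numpy()
        genes = cds.loc[idx, "gene"].to_numpy()
        active_end = -1
        active_i = -1
        for i in range(len(idx)):
            if i > 0 and starts[i] < active_end and genes[i] != genes[active_i]:
                drop[idx[i]] = True
                drop[idx[active_i]] = True
            if ends[i] > active_end:
                active_end = ends[i]
                active_i = i
    n_removed = int(drop.sum())
    if n_removed:
        logger.info("removed %d CDS intervals overlapping another gene",
                    n_removed)
    return cds[~drop].reset_index(drop=True), n_removed


# ---------------------------------------------------------------------------
# genotype filtering


def filter_genotypes(variants: VariantTable, min_dp: int = 10,
                     min_gq: int = 30) -> VariantTable:
    """Set genotypes failing DP > min_dp AND GQ > min_gq (strict) to missing."""
    out = variants.copy()
    fail = ~((out.dp > min_dp) & (out.gq > min_gq))
    out.genotypes[fail] = -1
    return out


# ---------------------------------------------------------------------------
# 4D site calling


def _observed_allele_map(variants: VariantTable) -> dict[str, dict[int, set[str]]]:
    """Per chromosome, positions carrying an observed alternate allele,
    mapped to the full set of observed bases (reference included)."""
    obs: dict[str, dict[int, set[str]]] = {}
    if variants.n_sites == 0:
        return obs
    g = variants.genotypes.reshape(variants.n_sites, -1)
    max_allele = int(g.max()) if g.size else 0
    present = [None] + [(g == k).any(axis=1) for k in range(1, max_allele + 1)]
    any_alt = (np.logical_or.reduce(present[1:])
               if max_allele >= 1 else np.zeros(variants.n_sites, dtype=bool))
    for i in np.flatnonzero(any_alt):
        alleles = (variants.ref[i],) + tuple(variants.alts[i])
        bases = {variants.ref[i]}
        for k in range(1, max_allele + 1):
            if k < len(alleles) and present[k][i]:
                bases.add(alleles[k])
        obs.setdefault(str(variants.chroms[i]), {})[int(variants.pos[i])] = bases
    return obs


def call_fourfold_sites(records: list[ChromosomeRecord],
                        coding_intervals: pd.DataFrame,
                        variants: VariantTable | None = None,
                        n_overlap_removed: int = 0) -> FourfoldSiteSet:
    """Call conservative 4D sites from reference codons plus observed variants.

    Per codon (strand- and phase-aware): codons containing N are discarded;
    codons with observed variants at more than one position are discarded;
    otherwise every allele combination at the single variant position must
    leave the third position 4-fold degenerate.  CDS runs whose length is
    not a multiple of 3 lose their trailing partial codon (logged by
    ``transcript_codons``).
    """
    seq_of = {r.id: r.sequence for r in records}
    obs = _observed_allele_map(variants) if variants is not None else {}
    counts = {"codons_scanned": 0, "rejected_multi_variant": 0,
              "rejected_non_4d": 0, "rejected_n": 0,
              "rejected_overlap_intervals": n_overlap_removed}
    cols: dict[str, list] = {k: [] for k in
                             ("chrom", "pos", "gene", "codon_index", "strand")}

    def _emit(chrom, gene, strand, keep_idx, pos):
        n = len(keep_idx)
        if not n:
            return
        cols["chrom"].append(np.full(n, chrom, dtype=object))
        cols["pos"].append(pos[keep_idx, 2])
        cols["gene"].append(np.full(n, gene, dtype=object))
        cols["codon_index"].append(np.asarray(keep_idx, dtype=np.int64))
        cols["strand"].append(np.full(n, strand, dtype=object))

    ci = coding_intervals.sort_values(["chrom", "parent", "start"],
                                      kind="stable").reset_index(drop=True)
    c_chrom = ci["chrom"].to_numpy(dtype=object)
    c_parent = ci["parent"].to_numpy(dtype=object)
    c_start = ci["start"].to_numpy(dtype=np.int64)
    c_end = ci["end"].to_numpy(dtype=np.int64)
    c_strand = ci["strand"].to_numpy(dtype=object)
    c_phase = ci["phase"].to_numpy(dtype=np.int64)
    c_gene = (ci["gene"].to_numpy(dtype=object) if "gene" in ci
              else c_parent)
    changed = np.flatnonzero((c_chrom[1:] != c_chrom[:-1])
                             | (c_parent[1:] != c_parent[:-1])) + 1
    bounds = np.concatenate(([0], changed, [len(ci)])) if len(ci) \
        else np.array([0, 0])
    var_pos_sorted = {c: np.array(sorted(d), dtype=np.int64)
                      for c, d in obs.items()}
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b0 == b1:
            continue
        chrom, strand, gene = c_chrom[b0], c_strand[b0], c_gene[b0]
        if chrom not in seq_of:
            raise ValueError(f"chromosome {chrom} absent from genome")
        ivs = list(zip(c_start[b0:b1], c_end[b0:b1]))
        first_phase = int(c_phase[b1 - 1] if strand == "-" else c_phase[b0])
        phase = first_phase if first_phase >= 0 else 0
        codons, pos = transcript_codons(seq_of[chrom], ivs, strand, phase)
        if not codons:
            continue
        counts["codons_scanned"] += len(codons)
        var_at = obs.get(chrom, {})
        vp = var_pos_sorted.get(chrom)
        if vp is not None and vp.size:
            loc = np.searchsorted(vp, pos)
            has_var = (loc < vp.size) & (vp[np.minimum(loc, vp.size - 1)]
                                         == pos)
            n_var = has_var.sum(axis=1)
        else:
            has_var = np.zeros_like(pos, dtype=bool)
            n_var = np.zeros(len(codons), dtype=np.int64)
        has_n = np.fromiter(("N" in c for c in codons), bool, len(codons))
        counts["rejected_n"] += int(has_n.sum())
        multi = ~has_n & (n_var > 1)
        counts["rejected_multi_variant"] += int(multi.sum())
        # invariant codons: membership in the 4D dinucleotide-prefix set
        plain = ~has_n & (n_var == 0)
        ok_prefix = np.fromiter((c[:2] in FOURFOLD_PREFIXES for c in codons),
                                bool, len(codons))
        _emit(chrom, gene, strand, np.flatnonzero(plain & ok_prefix), pos)
        counts["rejected_non_4d"] += int((plain & ~ok_prefix).sum())
        # codons with exactly one observed variant position: explicit check
        # of every observed allele
        keep_var = []
        for ci in np.flatnonzero(~has_n & (n_var == 1)):
            codon = codons[ci]
            k = int(np.flatnonzero(has_var[ci])[0])
            genome_bases = var_at[int(pos[ci, k])]
            codon_bases = ({_COMP[b] for b in genome_bases}
                           if strand == "-" else set(genome_bases))
            if all(is_fourfold(codon[:k] + b + codon[k + 1:])
                   for b in codon_bases):
                keep_var.append(int(ci))
            else:
                counts["rejected_non_4d"] += 1
        _emit(chrom, gene, strand, np.asarray(keep_var, dtype=np.int64), pos)
    sites = pd.DataFrame(
        {k: (np.concatenate(v) if v else np.array([], dtype=object))
         for k, v in cols.items()},
        columns=["chrom", "pos", "gene", "codon_index", "strand"])
    sites["pos"] = sites["pos"].astype(np.int64)
    sites["codon_index"] = sites["codon_index"].astype(np.int64)
    sites = sites.drop_duplicates(["chrom", "pos"]).sort_values(
        ["chrom", "pos"]).reset_index(drop=True)
    return FourfoldSiteSet(sites=sites, provenance=counts)


# ---------------------------------------------------------------------------
# diversity estimators


def _pairwise_pi_from_alleles(alleles: np.ndarray) -> float:
    """Mean pairwise difference among an allele-index vector (brute-free form:
    1 - sum_i C(c_i,2)/C(n,2))."""
    n = alleles.size
    if n < 2:
        return float("nan")
    _, counts = np.unique(alleles, return_counts=True)
    same = (counts * (counts - 1) // 2).sum()
    total = n * (n - 1) // 2
    return 1.0 - same / total


def _site_pi_arrays(site_set: FourfoldSiteSet, variants: VariantTable,
                    min_called_fraction: float
                    ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-4D-site pi and inclusion mask.

    Sites absent from the variant table are invariant and fully called
    (pi = 0, included); variant sites use all called alleles.
    """
    sites = site_set.sites
    pi = np.zeros(len(sites))
    included = np.ones(len(sites), dtype=bool)
    n_samples = len(variants.samples)
    if variants.n_sites == 0 or len(sites) == 0:
        return sites, pi, included
    matched = sites.reset_index()[["index", "chrom", "pos"]].merge(
        pd.DataFrame({"chrom": variants.chroms, "pos": variants.pos,
                      "vidx": np.arange(variants.n_sites)}),
        on=["chrom", "pos"])
    if not len(matched):
        return sites, pi, included
    sj = matched["index"].to_numpy()
    g = variants.genotypes[matched["vidx"].to_numpy()].reshape(len(matched), -1)
    called = g >= 0
    n_called = called.sum(axis=1)
    low = (n_called / (2 * n_samples) < min_called_fraction) if n_samples \
        else np.zeros(len(matched), dtype=bool)
    same = np.zeros(len(matched), dtype=np.int64)
    for k in range(int(g.max()) + 1):
        c = (g == k).sum(axis=1)
        same += c * (c - 1) // 2
    total = n_called * (n_called - 1) // 2
    ok = ~low & (total > 0)
    included[sj[low | (total == 0)]] = False
    pi[sj[ok]] = 1.0 - same[ok] / total[ok]
    return sites, pi, included


def _windows_from_site_pi(sites: pd.DataFrame, pi: np.ndarray,
                          included: np.ndarray, sites_per_window: int
                          ) -> pd.DataFrame:
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for w, lo in enumerate(range(0, len(idx), sites_per_window)):
            chunk = idx[lo:lo + sites_per_window]
            if len(chunk) < sites_per_window and len(chunk) < sites_per_window / 2:
                continue  # trailing window below half full
            inc = included[chunk]
            if inc.sum() == 0:
                continue
            rows.append({"chrom": chrom, "window_index": w,
                         "n_sites": int(len(chunk)),
                         "n_included": int(inc.sum()),
                         "pi": float(pi[chunk][inc].mean())})
    return pd.DataFrame(rows,
                        columns=["chrom", "window_index", "n_sites",
                                 "n_included", "pi"])


def pi_windows(site_set: FourfoldSiteSet, variants: VariantTable,
               sites_per_window: int = 500,
               min_called_fraction: float = 0.5) -> pd.DataFrame:
    """Windowed pi over 4D sites (windows of a fixed site count).

    Per site, pi is the fraction of differing pairs among all called alleles
    (within plus between individuals).  Sites with called-allele fraction
    below ``min_called_fraction`` are excluded from the window mean.  The
    trailing window is kept if at least half full.
    """
    if site_set.n_sites == 0:
        logger.warning("no 4D sites: empty diversity table")
        return pd.DataFrame(columns=["chrom", "window_index", "n_sites",
                                     "n_included", "pi"])
    sites, pi, included = _site_pi_arrays(site_set, variants,
                                          min_called_fraction)
    return _windows_from_site_pi(sites, pi, included, sites_per_window)


def pairwise_pi(site_set: FourfoldSiteSet, variants: VariantTable,
                two_samples: tuple[str, str],
                sites_per_window: int = 500) -> pd.DataFrame:
    """Windowed between-sample pi for exactly two designated samples.

    Per site, the mean proportion of differing alleles over the cross-sample
    allele pairs (a low-sample-count fallback when within-population
    diversity cannot be estimated).
    """
    if len(two_samples) != 2:
        raise ValueError("pairwise mode needs exactly two samples")
    for s in two_samples:
        if s not in variants.samples:
            raise ValueError(f"sample {s} not in variant table")
    ia, ib = (variants.samples.index(two_samples[0]),
              variants.samples.index(two_samples[1]))
    sites = site_set.sites
    pi = np.zeros(len(sites))
    included = np.ones(len(sites), dtype=bool)
    site_index = {(c, int(p)): j for j, (c, p)
                  in enumerate(zip(sites["chrom"], sites["pos"]))}
    for i in range(variants.n_sites):
        j = site_index.get((str(variants.chroms[i]), int(variants.pos[i])))
        if j is None:
            continue
        a = variants.genotypes[i, ia]
        b = variants.genotypes[i, ib]
        a = a[a >= 0]
        b = b[b >= 0]
        if a.size == 0 or b.size == 0:
            included[j] = False
            continue
        diffs = sum(1 for x in a for y in b if x != y)
        pi[j] = diffs / (a.size * b.size)
    return _windows_from_site_pi(sites, pi, included, sites_per_window)


# ---------------------------------------------------------------------------
# per-homolog summaries and the recombination model


def chromosome_diversity_summary(windows: pd.DataFrame,
                                 class_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-homolog mean of window pi, normalized to the NFC mean.

    ``windows`` must already be in ancestral coordinates (chrom = homolog
    label, e.g. after AncestralView mapping).  Homologs with no windows get
    NA rows.
    """
    means = windows.groupby("chrom")["pi"].agg(["mean", "size"])
    rows = []
    for r in class_table.itertuples():
        if r.homolog in means.index:
            rows.append({"homolog": r.homolog, "chrom_class": r.chrom_class,
                         "mean_pi": float(means.loc[r.homolog, "mean"]),
                         "n_windows": int(means.loc[r.homolog, "size"])})
        else:
            rows.append({"homolog": r.homolog, "chrom_class": r.chrom_class,
                         "mean_pi": np.nan, "n_windows": 0})
    out = pd.DataFrame(rows)
    nfc_mean = out.loc[out["chrom_class"] == "NFC", "mean_pi"].mean()
    out["pi_norm"] = out["mean_pi"] / nfc_mean
    return out


def relative_diversity_change(extant: pd.DataFrame,
                              ancestor: pd.DataFrame) -> pd.DataFrame:
    """Per-homolog relative change (ratio form) of NFC-normalized pi."""
    merged = extant.merge(ancestor, on=["homolog", "chrom_class"],
                          suffixes=("_extant", "_ancestor"))
    merged["delta_pi_rel"] = (
        (merged["pi_norm_extant"] - merged["pi_norm_ancestor"])
        / merged["pi_norm_ancestor"])
    return merged


def recombination_model(ancestral_lengths: dict[str, int],
                        extant_lengths: dict[str, int],
                        map_length_anc: float = 50.0,
                        map_length_extant: float | dict[str, float] = 50.0
                        ) -> pd.DataFrame:
    """Per-homolog recombination rates under the fixed-map-length model.

    ``extant_lengths`` maps each homolog to the length of the chromosome it
    now resides on (for fused homologs, the full fused chromosome).  Rates
    are in cM/Mb; delta_r_rel = 1 - r_extant / r_anc is positive for a rate
    decrease and negative for an increase (e.g. after genome shrinkage).
    Observed map lengths may override the 50 cM default per homolog.
    """
    rows = []
    for homolog in sorted(ancestral_lengths):
        l_anc = ancestral_lengths[homolog]
        l_ext = extant_lengths.get(homolog)
        m_ext = (map_length_extant.get(homolog, 50.0)
                 if isinstance(map_length_extant, dict) else map_length_extant)
        if l_ext is None:
            rows.append({"homolog": homolog, "L_anc": l_anc, "L_extant": np.nan,
                         "M_anc": map_length_anc, "M_extant": m_ext,
                         "r_anc": np.nan, "r_extant": np.nan,
                         "delta_r_rel": np.nan})
            continue
        r_anc = map_length_anc / (l_anc / 1e6)
        r_ext = m_ext / (l_ext / 1e6)
        rows.append({"homolog": homolog, "L_anc": l_anc, "L_extant": l_ext,
                     "M_anc": map_length_anc, "M_extant": m_ext,
                     "r_anc": r_anc, "r_extant": r_ext,
                     "delta_r_rel": 1.0 - r_ext / r_anc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation P for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    n = len(rx)
    count = 0
    total = 0
    sy = ry.std()
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            arr = np.asarray(chunk)
            rhos = (rx @ ((ry[arr] - ry.mean()) / sy).T) / n
            count += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        arr = np.asarray(chunk)
        rhos = (rx @ ((ry[arr] - ry.mean()) / sy).T) / n
        count += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
        total += len(chunk)
    return count / total


def diversity_recombination_correlation(delta_pi_rel, delta_r_rel) -> dict:
    """Spearman correlation of diversity change against recombination change.

    Uses average ranks for ties; exact permutation P for n <= 10, the normal
    approximation otherwise.  The orientation convention (a positive
    delta_r_rel is a rate *decrease*; delta_pi_rel is signed) is recorded in
    the output.
    """
    x = np.asarray(delta_pi_rel, dtype=float)
    y = np.asarray(delta_r_rel, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 5:
        raise ValueError("need >= 5 paired homolog values")
    rho, p = stats.spearmanr(x, y)
    if len(x) <= 10:
        p = _exact_spearman_p(x, y, rho)
        method = "exact-permutation"
    else:
        method = "normal-approximation"
    return {"rho": float(rho), "p_value": float(p), "n": int(len(x)),
            "method": method,
            "orientation": "delta_r_rel = 1 - r_extant/r_anc (positive = "
                           "rate decrease); delta_pi_rel signed ratio change"}
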