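"""Windowed genome composition, fusion-centred normalized profiles,
chromosome-class contrasts, and standardized major axis (SMA) scaling.

SMA regression is the standard line-fitting choice for allometric scaling
where both variables carry error: slope = sign(r) * sd(y)/sd(x), intercept
through the means.  Group comparisons (common slope, elevation) use
seeded permutation tests rather than likelihood-ratio machinery.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import FusionEvent
from .intervals import intersect_lengths, complement_intervals, merge_intervals
from .io import ChromosomeRecord

logger = logging.getLogger(__name__)

ALPHA = 0.005  # stringent significance threshold used throughout


@dataclass
class SMAFit:
    slope: float
    intercept: float
    r: float
    n: int
    group: str | None = None


# ---------------------------------------------------------------------------
# windowed composition


def _coverage_at_boundaries(starts: np.ndarray, ends: np.ndarray,
                            boundaries: np.ndarray) -> np.ndarray:
    """F(x) = covered bp in [0, x) of merged intervals, at each boundary."""
    if starts.size == 0:
        return np.zeros(len(boundaries), dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(ends - starts)))
    idx = np.searchsorted(ends, boundaries, side="right")
    full = cum[idx]
    partial = np.where(
        (idx < len(starts)) & (starts[np.minimum(idx, len(starts) - 1)] < boundaries),
        boundaries - starts[np.minimum(idx, len(starts) - 1)], 0)
    return full + np.maximum(partial, 0)


def window_composition(records: list[ChromosomeRecord], repeats: pd.DataFrame,
                       annotation: pd.DataFrame, window_size: int = 100_000,
                       coding_kind: str = "CDS") -> pd.DataFrame:
    """GC / repeat / coding percentages in non-overlapping windows.

    Coverage is computed on merged (union) intervals per kind, so overlapping
    features are not double-counted; GC is a percentage of non-N bases.  The
    terminal remainder window is kept only if at least half a window long
    (dropped count logged).
    """
    if window_size < 1000:
        raise ValueError("window_size must be >= 1 kb")
    known = {r.id for r in records}
    for df, name in ((repeats, "repeat"), (annotation, "annotation")):
        unknown = set(df["chrom"].unique()) - known
        if unknown:
            raise ValueError(f"{name} intervals on chromosomes absent from "
                             f"genome: {sorted(unknown)[:5]}")
    rows = []
    n_dropped = 0
    for rec in records:
        seq = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        is_gc = np.cumsum((seq == ord("G")) | (seq == ord("C")))
        is_n = np.cumsum(seq == ord("N"))
        rep = repeats[repeats["chrom"] == rec.id]
        cds = annotation[(annotation["chrom"] == rec.id)
                         & (annotation["kind"] == coding_kind)]
        rep_s, rep_e = merge_intervals(rep["start"].to_numpy(),
                                       rep["end"].to_numpy())
        cds_s, cds_e = merge_intervals(cds["start"].to_numpy(),
                                       cds["end"].to_numpy())
        edges = list(range(0, rec.length, window_size)) + [rec.length]
        edges = np.unique(np.asarray(edges, dtype=np.int64))
        rep_cov = np.diff(_coverage_at_boundaries(rep_s, rep_e, edges))
        cds_cov = np.diff(_coverage_at_boundaries(cds_s, cds_e, edges))
        for i in range(len(edges) - 1):
            w_s, w_e = int(edges[i]), int(edges[i + 1])
            w_len = w_e - w_s
            if w_len < window_size / 2:
                n_dropped += 1
                continue
            gc_bp = int(is_gc[w_e - 1]) - (int(is_gc[w_s - 1]) if w_s else 0)
            n_bp = int(is_n[w_e - 1]) - (int(is_n[w_s - 1]) if w_s else 0)
            denom = w_len - n_bp
            rows.append({
                "chrom": rec.id, "start": w_s, "end": w_e,
                "gc": 100.0 * gc_bp / denom if denom else float("nan"),
                "repeat": 100.0 * rep_cov[i] / w_len,
                "coding": 100.0 * cds_cov[i] / w_len,
            })
    if n_dropped:
        logger.info("dropped %d terminal windows shorter than half window "
                    "size", n_dropped)
    return pd.DataFrame(rows)


def normalized_positions(windows: pd.DataFrame, fusions: list[FusionEvent],
                         chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Attach fusion-centred normalized coordinates to composition windows.

    Unfused chromosomes map linearly onto [0, 1]; fused chromosomes map
    piecewise-linearly so the breakpoint lands at exactly 0.5 (left
    component onto [0, 0.5], right onto [0.5, 1]).  Adds ``norm_pos`` and a
    ``fused`` flag.
    """
    bp_of = {e.derived_chrom: e.breakpoint for e in fusions}
    out = windows.copy()
    norm = np.empty(len(out))
    fused_flag = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples()):
        length = chrom_lengths[row.chrom]
        center = (row.start + row.end) / 2
        if row.chrom in bp_of:
            bp = bp_of[row.chrom]
            fused_flag[i] = True
            if center < bp:
                norm[i] = 0.5 * center / bp
            else:
                norm[i] = 0.5 + 0.5 * (center - bp) / (length - bp)
        else:
            norm[i] = center / length
    out["norm_pos"] = norm
    out["fused"] = fused_flag
    return out


def normalized_profile(windows: pd.DataFrame, fusions: list[FusionEvent],
                       chrom_lengths: dict[str, int], n_bins: int = 20
                       ) -> pd.DataFrame:
    """Bin-averaged composition along normalized coordinates, per set.

    Returns one row per (set, bin, metric) with mean and SD across windows,
    where set is "fused" or "unfused".
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    pos = normalized_positions(windows, fusions, chrom_lengths)
    pos["bin"] = np.minimum((pos["norm_pos"] * n_bins).astype(int), n_bins - 1)
    rows = []
    for fused_val, set_name in ((True, "fused"), (False, "unfused")):
        sub = pos[pos["fused"] == fused_val]
        for metric in ("gc", "repeat", "coding"):
            g = sub.groupby("bin")[metric]
            for b, (mean, sd, n) in pd.concat(
                    [g.mean(), g.std(), g.size()], axis=1).iterrows():
                rows.append({"set": set_name, "bin": int(b),
                             "bin_center": (int(b) + 0.5) / n_bins,
                             "metric": metric, "mean": mean, "sd": sd,
                             "n_windows": int(n)})
    return pd.DataFrame(rows)


def fusion_point_contrast(windows_with_norm: pd.DataFrame,
                          metric: str = "repeat", width: float = 0.05
                          ) -> dict[str, float]:
    """Contrasts diagnosing a residual peak at the fusion point (0.5).

    Over fused chromosomes only: mean metric near the chromosome edges
    (within ``width`` of 0 or 1), near the fusion point (within ``width`` of
    0.5), and in flanking regions around 0.25/0.75.  ``peak_contrast`` > 0
    indicates a local peak at the junction (a W-shaped profile);
    ``edge_minus_center`` > 0 indicates tails exceeding the junction.
    """
    sub = windows_with_norm[windows_with_norm["fused"]]
    x = sub["norm_pos"].to_numpy()
    v = sub[metric].to_numpy()
    edge = v[(x <= width) | (x >= 1 - width)]
    center = v[np.abs(x - 0.5) <= width]
    flank = v[(np.abs(x - 0.25) <= width) | (np.abs(x - 0.75) <= width)]
    return {
        "edge_mean": float(np.mean(edge)) if edge.size else float("nan"),
        "center_mean": float(np.mean(center)) if center.size else float("nan"),
        "flank_mean": float(np.mean(flank)) if flank.size else float("nan"),
        "peak_contrast": float(np.mean(center) - np.mean(flank))
        if center.size and flank.size else float("nan"),
        "edge_minus_center": float(np.mean(edge) - np.mean(center))
        if center.size and edge.size else float("nan"),
    }


# ---------------------------------------------------------------------------
# class contrasts


def class_contrasts(per_chromosome: pd.DataFrame, metrics: list[str],
                    class_column: str = "chrom_class",
                    alpha: float = ALPHA) -> pd.DataFrame:
    """One-sided rank-sum contrasts between chromosome classes.

    For every metric and every ordered pair of classes (A, B), tests the
    alternative that A's values are stochastically less than B's
    (Wilcoxon-Mann-Whitney, exact where sample sizes permit).  Classes with
    fewer than 3 members yield NA rows.
    """
    classes = sorted(per_chromosome[class_column].dropna().unique())
    rows = []
    for metric in metrics:
        for a, b in itertools.permutations(classes, 2):
            va = per_chromosome.loc[per_chromosome[class_column] == a,
                                    metric].dropna().to_numpy()
            vb = per_chromosome.loc[per_chromosome[class_column] == b,
                                    metric].dropna().to_numpy()
            if len(va) < 3 or len(vb) < 3:
                rows.append({"metric": metric, "group_a": a, "group_b": b,
                             "alternative": "less", "statistic": np.nan,
                             "p_value": np.nan, "n_a": len(va), "n_b": len(vb),
                             "significant": False})
                continue
            method = "exact" if (len(va) + len(vb) <= 25
                                 and len(np.unique(np.concatenate([va, vb])))
                                 == len(va) + len(vb)) else "asymptotic"
            res = stats.mannwhitneyu(va, vb, alternative="less", method=method)
            rows.append({"metric": metric, "group_a": a, "group_b": b,
                         "alternative": "less", "statistic": float(res.statistic),
                         "p_value": float(res.pvalue), "n_a": len(va),
                         "n_b": len(vb),
                         "significant": bool(res.pvalue <= alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SMA


def sma_fit(x, y, log_transform: bool = False, group: str | None = None) -> SMAFit:
    """Standardized major axis fit: slope = sign(r) * sd(y)/sd(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("SMA needs n >= 3 paired observations")
    if log_transform:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log transform requires positive values")
        x, y = np.log10(x), np.log10(y)
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAFit(slope=float(slope), intercept=intercept, r=r, n=len(x),
                  group=group)


def sma_group_compare(groups: dict[str, tuple[np.ndarray, np.ndarray]],
                      n_permutations: int = 999, seed: int = 0,
                      log_transform: bool = False) -> dict:
    """Permutation tests for common SMA slope and pairwise elevation shifts.

    Common-slope test: the statistic is the variance of per-group SMA slopes
    under permutation of group labels.  Elevation test (per pair): residual
    scores y - b_common * x (b_common from the pooled SMA) are permuted
    between the two groups; the statistic is the absolute difference of
    group mean scores.  Pairwise P-values are Holm-adjusted.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rng = np.random.default_rng(seed)
    prep: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label, (x, y) in groups.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if log_transform:
            x, y = np.log10(x), np.log10(y)
        if len(x) < 3:
            raise ValueError(f"group {label}: n >= 3 required")
        prep[label] = (x, y)

    labels = sorted(prep)
    all_x = np.concatenate([prep[g][0] for g in labels])
    all_y = np.concatenate([prep[g][1] for g in labels])
    sizes = [len(prep[g][0]) for g in labels]
    splits = np.cumsum(sizes)[:-1]

    def slope_var(xs: np.ndarray, ys: np.ndarray) -> float:
        slopes = []
        for xg, yg in zip(np.split(xs, splits), np.split(ys, splits)):
            sx, sy = np.std(xg, ddof=1), np.std(yg, ddof=1)
            if sx == 0 or sy == 0:
                return np.nan
            r = np.corrcoef(xg, yg)[0, 1]
            slopes.append((1 if r >= 0 else -1) * sy / sx)
        return float(np.var(slopes))

    obs_var = slope_var(all_x, all_y)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(all_x))
        v = slope_var(all_x[perm], all_y[perm])
        if not np.isnan(v) and v >= obs_var:
            n_ge += 1
    common_slope_p = (1 + n_ge) / (1 + n_permutations)

    pooled = sma_fit(all_x, all_y)
    b_common = pooled.slope
    pair_rows = []
    for a, b in itertools.combinations(labels, 2):
        xa, ya = prep[a]
        xb, yb = prep[b]
        za = ya - b_common * xa
        zb = yb - b_common * xb
        obs = abs(za.mean() - zb.mean())
        z_all = np.concatenate([za, zb])
        n_a = len(za)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(z_all))
            stat = abs(z_all[perm[:n_a]].mean() - z_all[perm[n_a:]].mean())
            if stat >= obs:
                count += 1
        pair_rows.append({"group_a": a, "group_b": b,
                          "elevation_diff": float(za.mean() - zb.mean()),
                          "p_value": (1 + count) / (1 + n_permutations)})
    pairs = pd.DataFrame(pair_rows)
    if len(pairs):
        order = np.argsort(pairs["p_value"].to_numpy())
        m = len(pairs)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pairs["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        pairs["p_adjusted"] = adj
    return {
        "common_slope_p": common_slope_p,
        "common_slope": b_common,
        "group_fits": {g: sma_fit(*prep[g], group=g) for g in labels},
        "elevation": pairs,
    }


# ---------------------------------------------------------------------------
# intron / intergenic repeat scaling


def region_repeat_scaling(annotation: pd.DataFrame, repeats: pd.DataFrame,
                          chrom_lengths: dict[str, int],
                          n_permutations: int = 999, seed: int = 0) -> dict:
    """SMA scaling of repeat content within introns vs intergenic regions.

    One point per chromosome and region kind: (log10 region bp, log10 repeat
    bp within the region).  Intergenic regions are the strandless complement
    of gene spans; repeat overlap is computed strandlessly.  Chromosomes
    with zero intron bp or zero repeat overlap in a region are excluded
    (logged).  Elevation between the two kinds is compared by permutation.
    """
    introns = annotation[annotation["kind"] == "intron"]
    genes = annotation[annotation["kind"] == "gene"]
    rows = []
    n_excluded = 0
    for chrom, length in chrom_lengths.items():
        rep = repeats[repeats["chrom"] == chrom]
        rep_s, rep_e = rep["start"].to_numpy(), rep["end"].to_numpy()
        intr = introns[introns["chrom"] == chrom]
        gn = genes[genes["chrom"] == chrom]
        ig_s, ig_e = complement_intervals(gn["start"].to_numpy(),
                                          gn["end"].to_numpy(), length)
        for kind, (s, e) in (("intron", (intr["start"].to_numpy(),
                                         intr["end"].to_numpy())),
                             ("intergenic", (ig_s, ig_e))):
            ms, me = merge_intervals(s, e)
            region_bp = int((me - ms).sum())
            rep_bp = intersect_lengths(ms, me, rep_s, rep_e)
            if region_bp == 0 or rep_bp == 0:
                n_excluded += 1
                continue
            rows.append({"chrom": chrom, "kind": kind,
                         "region_bp": region_bp, "repeat_bp": rep_bp})
    if n_excluded:
        logger.info("region_repeat_scaling: excluded %d chromosome/region "
                    "cells with zero span or zero repeat bp", n_excluded)
    points = pd.DataFrame(rows)
    fits = {}
    groups = {}
    for kind in ("intron", "intergenic"):
        sub = points[points["kind"] == kind]
        x = np.log10(sub["region_bp"].to_numpy(dtype=float))
        y = np.log10(sub["repeat_bp"].to_numpy(dtype=float))
        fits[kind] = sma_fit(x, y, group=kind)
        groups[kind] = (x, y)
    compare = sma_group_compare(groups, n_permutations=n_permutations,
                                seed=seed)
    return {"points": points, "fits": fits, "compare": compare}
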