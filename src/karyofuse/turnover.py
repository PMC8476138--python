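"""Reciprocal-best-hit conservation of functional elements, its correlation
with chromosome length, and multiple regression on length and divergence
time.

Conservation of an element set against a target genome is the percentage of
source elements recovered as reciprocal best hits (RBH) at a stringent
e-value threshold.  Turnover increases with divergence time; the analyses
here quantify how much of the remaining variance chromosome length (a proxy
for per-bp recombination rate under a fixed map length) explains.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Deterministic best hit per query: lowest e-value, then highest
    bitscore, then lexicographically smallest subject id."""
    if len(hits) == 0:
        return hits
    ordered = hits.sort_values(
        ["query_id", "evalue", "bitscore", "subject_id"],
        ascending=[True, True, False, True], kind="stable")
    return ordered.drop_duplicates("query_id", keep="first")


def reciprocal_best_hits(hits_forward: pd.DataFrame,
                         hits_reverse: pd.DataFrame,
                         evalue_max: float = 1e-10) -> set[tuple[str, str]]:
    """RBH pairs: each sequence is the other's best hit, both e-values pass.

    Empty tables yield an empty set.  The tie-break (e-value, bitscore,
    subject id) makes the result deterministic and symmetric.
    """
    best_f = _best_hits(hits_forward)
    best_r = _best_hits(hits_reverse)
    fwd = {(q, s): e for q, s, e in zip(best_f["query_id"],
                                        best_f["subject_id"],
                                        best_f["evalue"])}
    rev = {(q, s): e for q, s, e in zip(best_r["query_id"],
                                        best_r["subject_id"],
                                        best_r["evalue"])}
    pairs = set()
    for (q, s), ev_f in fwd.items():
        ev_r = rev.get((s, q))
        if ev_r is not None and ev_f <= evalue_max and ev_r <= evalue_max:
            pairs.add((q, s))
    return pairs


def conservation_by_chromosome(elements: pd.DataFrame,
                               rbh_pairs: set[tuple[str, str]],
                               chrom_lengths: dict[str, int],
                               ancestral_view=None) -> pd.DataFrame:
    """Percent of elements with an RBH, per source chromosome.

    ``elements`` is a feature table (chrom, start, end, kind, id).  With an
    ``ancestral_view`` (see fusion module), conservation is instead computed
    per ancestral homolog segment of fused chromosomes, and lengths are
    segment lengths.  Chromosomes with zero elements are absent (NA by
    omission).
    """
    conserved_ids = {q for q, _ in rbh_pairs}
    el = elements.copy()
    if ancestral_view is not None:
        el = ancestral_view.map_features(el)
        lengths = ancestral_view.homolog_lengths()
    else:
        lengths = chrom_lengths
    rows = []
    for (chrom, kind), grp in el.groupby(["chrom", "kind"], sort=False):
        n = len(grp)
        n_cons = int(grp["id"].isin(conserved_ids).sum())
        rows.append({"chrom": str(chrom), "kind": kind, "n_elements": n,
                     "n_conserved": n_cons,
                     "conservation": 100.0 * n_cons / n,
                     "length": lengths[str(chrom)]})
    return pd.DataFrame(rows).sort_values(["kind", "chrom"]).reset_index(drop=True)


def conservation_length_correlation(results: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of conservation % with chromosome length.

    One row per (target, kind) group present in ``results`` (grouping
    columns are used when present).  Constant conservation yields NA.
    """
    group_cols = [c for c in ("target", "kind") if c in results.columns]
    rows = []
    grouped = results.groupby(group_cols) if group_cols else [((), results)]
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        if len(grp) < 5:
            raise ValueError("need >= 5 chromosomes per comparison")
        c = grp["conservation"].to_numpy(dtype=float)
        length = grp["length"].to_numpy(dtype=float)
        if np.std(c) == 0 or np.std(length) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.pearsonr(c, length)
        row = dict(zip(group_cols, key))
        row.update({"rho": float(rho) if rho == rho else np.nan,
                    "p_value": float(p) if p == p else np.nan,
                    "n": len(grp)})
        rows.append(row)
    return pd.DataFrame(rows)


def turnover_multiple_regression(results: pd.DataFrame) -> dict:
    """OLS of conservation % on chromosome length (Mb) and divergence time
    (Myr), pooling targets, plus per-target simple length slopes.

    ``results`` needs columns conservation, length, time, target.  A single
    divergence time leaves the time coefficient NA with a warning.
    """
    df = results.dropna(subset=["conservation", "length", "time"])
    n_times = df["time"].nunique()
    if df["target"].nunique() < 2 or n_times < 1:
        raise ValueError("need conservation results for >= 2 targets")
    y = df["conservation"].to_numpy(dtype=float)
    l_mb = df["length"].to_numpy(dtype=float) / 1e6
    t = df["time"].to_numpy(dtype=float)
    if n_times == 1:
        logger.warning("single divergence time: time coefficient undefined")
        X = sm.add_constant(np.column_stack([l_mb]))
        fit = sm.OLS(y, X).fit()
        beta0, beta_len = fit.params
        beta_time = np.nan
    else:
        X = sm.add_constant(np.column_stack([l_mb, t]))
        fit = sm.OLS(y, X).fit()
        beta0, beta_len, beta_time = fit.params
    slopes = {}
    for target, grp in df.groupby("target"):
        lg = grp["length"].to_numpy(dtype=float) / 1e6
        cg = grp["conservation"].to_numpy(dtype=float)
        slopes[target] = float(np.polyfit(lg, cg, 1)[0])
    return {"beta0": float(beta0), "beta_length": float(beta_len),
            "beta_time": float(beta_time) if beta_time == beta_time else np.nan,
            "r_squared": float(fit.rsquared),
            "length_slopes_by_target": slopes, "n": int(len(df))}


def compare_effect_sizes(slopes_a: dict[str, float],
                         slopes_b: dict[str, float]) -> dict:
    """Paired t-test on per-comparison length slopes of two element sources.

    Slopes are paired by target comparison; unpaired inputs or fewer than
    two shared pairs raise.  Also reports the ratio of mean |slopes|.
    """
    shared = sorted(set(slopes_a) & set(slopes_b))
    if set(slopes_a) != set(slopes_b):
        raise ValueError("slope dictionaries are not paired by target")
    if len(shared) < 2:
        raise ValueError("paired t-test needs >= 2 paired comparisons")
    a = np.array([slopes_a[k] for k in shared], dtype=float)
    b = np.array([slopes_b[k] for k in shared], dtype=float)
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    mean_abs_b = np.mean(np.abs(b))
    ratio = float(np.mean(np.abs(a)) / mean_abs_b) if mean_abs_b else np.nan
    return {"t_statistic": float(t), "p_value": float(p),
            "slope_ratio": ratio, "n_pairs": len(shared),
            "targets": shared}
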