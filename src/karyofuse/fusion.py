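"""Fusion-point detection from ortholog anchors, chromosome splitting, and
NFC/LFC/SFC classification.

An anchor ties a position on a derived (possibly fused) chromosome to the
ancestral homolog its ortholog lives on.  A fused chromosome shows a clean
two-block arrangement of anchors; the junction is estimated by an exhaustive
single-changepoint scan that minimizes the number of anchors on the wrong
side, and the breakpoint is placed at the floor of the midpoint between the
two anchors flanking the chosen changepoint.  The gap between those anchors
is retained as the breakpoint's uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VariantTable

logger = logging.getLogger(__name__)

ANCHOR_COLUMNS = ["chrom", "pos", "homolog", "anchor_id"]


@dataclass
class FusionEvent:
    derived_chrom: str
    left_homolog: str
    right_homolog: str
    breakpoint: int
    flanking_gap: int
    n_discordant: int
    n_anchors: int = 0
    confidence: str = "high"


def anchor_map_from_positions(anchors: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort an anchor table (chrom, pos, homolog, anchor_id).

    Homolog claims supported by fewer than two anchors on a chromosome are
    dropped with a logged count.
    """
    df = anchors[ANCHOR_COLUMNS].copy()
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    counts = df.groupby(["chrom", "homolog"])["anchor_id"].transform("size")
    weak = counts < 2
    if weak.any():
        logger.warning("dropped %d anchors from homolog claims with < 2 anchors",
                       int(weak.sum()))
        df = df[~weak].reset_index(drop=True)
    return df


def anchor_map_from_hits(hits: pd.DataFrame, homolog_of: dict[str, str],
                         bitscore_margin: float = 2.0) -> pd.DataFrame:
    """Build an anchor map from a similarity-hit table.

    Each query (an ortholog with a known ancestral homolog) is placed at the
    midpoint of its best hit on the derived genome (subject = derived
    chromosome, 1-based inclusive coordinates).  Queries whose two best
    placements are within ``bitscore_margin`` bits of bitscore, or have equal
    e-values, are ambiguous and dropped with a logged count.
    """
    rows = []
    n_ambiguous = 0
    for query, grp in hits.groupby("query_id", sort=False):
        grp = grp.sort_values(["evalue", "bitscore", "subject_id"],
                              ascending=[True, False, True], kind="stable")
        best = grp.iloc[0]
        if len(grp) > 1:
            second = grp.iloc[1]
            if (best["bitscore"] - second["bitscore"] < bitscore_margin
                    or best["evalue"] == second["evalue"]):
                n_ambiguous += 1
                continue
        if query not in homolog_of:
            continue
        mid = (int(best["s_start"]) - 1 + int(best["s_end"])) // 2
        rows.append({"chrom": best["subject_id"], "pos": mid,
                     "homolog": homolog_of[query], "anchor_id": query})
    if n_ambiguous:
        logger.warning("dropped %d ambiguously placed anchors", n_ambiguous)
    df = pd.DataFrame(rows, columns=ANCHOR_COLUMNS)
    return anchor_map_from_positions(df)


def _best_changepoint(pos: np.ndarray, hom: np.ndarray,
                      hom_a: str, hom_b: str) -> tuple[int, int, int, int]:
    """Exhaustive scan for the single changepoint minimizing misassignments.

    Returns (cut_index, n_discordant, left_is_a, flanking_gap); the cut lies
    between anchors cut_index-1 and cut_index.  Ties prefer the widest
    flanking gap.
    """
    n = len(pos)
    is_a = (hom == hom_a)
    prefix_a = np.concatenate(([0], np.cumsum(is_a)))
    total_a = int(prefix_a[-1])
    best = None
    for cut in range(1, n):
        # A on the left: discordant = B's on left + A's on right
        mis_a_left = (cut - prefix_a[cut]) + (total_a - prefix_a[cut])
        mis_b_left = n - mis_a_left
        gap = int(pos[cut] - pos[cut - 1])
        for mis, left_a in ((mis_a_left, True), (mis_b_left, False)):
            key = (mis, -gap)
            if best is None or key < best[0]:
                best = (key, cut, int(mis), left_a, gap)
    _, cut, mis, left_a, gap = best
    return cut, mis, left_a, gap


def detect_fusions(anchor_map: pd.DataFrame,
                   max_discordant_frac: float = 0.10) -> list[FusionEvent]:
    """Detect fusion junctions on every derived chromosome of an anchor map.

    Chromosomes whose anchors all come from one homolog yield no event.  A
    chromosome carrying anchors from more than two homologs is segmented
    between each consecutive homolog block (events flagged low-confidence),
    as is any event whose best changepoint still leaves more than
    ``max_discordant_frac`` of anchors on the wrong side.
    """
    if len(anchor_map) == 0:
        raise ValueError("empty anchor map: nothing to detect")
    events: list[FusionEvent] = []
    for chrom, grp in anchor_map.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        hom = grp["homolog"].to_numpy(dtype=object)
        homologs = list(pd.unique(hom))
        if len(homologs) == 1:
            continue
        multi = len(homologs) > 2
        if multi:
            logger.warning("%s: anchors from %d homologs; segmenting pairwise",
                           chrom, len(homologs))
            order = sorted(homologs,
                           key=lambda h: float(np.median(pos[hom == h])))
            pairs = list(zip(order[:-1], order[1:]))
        else:
            pairs = [(homologs[0], homologs[1])]
        for hom_a, hom_b in pairs:
            mask = (hom == hom_a) | (hom == hom_b)
            p, h = pos[mask], hom[mask]
            cut, mis, left_a, gap = _best_changepoint(p, h, hom_a, hom_b)
            breakpoint = int((p[cut - 1] + p[cut]) // 2)
            confidence = "high"
            if mis > max_discordant_frac * len(p) or multi:
                confidence = "low"
            events.append(FusionEvent(
                derived_chrom=str(chrom),
                left_homolog=hom_a if left_a else hom_b,
                right_homolog=hom_b if left_a else hom_a,
                breakpoint=breakpoint,
                flanking_gap=gap,
                n_discordant=mis,
                n_anchors=int(len(p)),
                confidence=confidence,
            ))
    return events


def fusions_to_frame(events: list[FusionEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "derived_chrom": e.derived_chrom, "left_homolog": e.left_homolog,
        "right_homolog": e.right_homolog, "breakpoint": e.breakpoint,
        "flanking_gap": e.flanking_gap, "n_discordant": e.n_discordant,
        "n_anchors": e.n_anchors, "confidence": e.confidence,
    } for e in events])


def fusions_from_frame(df: pd.DataFrame) -> list[FusionEvent]:
    return [FusionEvent(
        derived_chrom=str(r.derived_chrom), left_homolog=str(r.left_homolog),
        right_homolog=str(r.right_homolog), breakpoint=int(r.breakpoint),
        flanking_gap=int(getattr(r, "flanking_gap", 0)),
        n_discordant=int(getattr(r, "n_discordant", 0)),
        n_anchors=int(getattr(r, "n_anchors", 0)),
        confidence=str(getattr(r, "confidence", "high")),
    ) for r in df.itertuples()]


class AncestralView:
    """Coordinate view relabeling fused chromosomes to ancestral homologs.

    Built from fusion events plus the homolog identity of unfused
    chromosomes; maps positions, feature tables, and variant tables from
    derived coordinates into per-homolog coordinates (right-hand components
    have the breakpoint offset subtracted).
    """

    def __init__(self, fusions: list[FusionEvent],
                 chrom_lengths: dict[str, int],
                 unfused_homologs: dict[str, str]):
        rows = []
        fused_chroms = set()
        for e in fusions:
            if e.breakpoint <= 0 or e.breakpoint >= chrom_lengths[e.derived_chrom]:
                raise ValueError(
                    f"breakpoint {e.breakpoint} outside {e.derived_chrom}")
            fused_chroms.add(e.derived_chrom)
            rows.append({"chrom": e.derived_chrom, "seg_start": 0,
                         "seg_end": e.breakpoint, "homolog": e.left_homolog})
            rows.append({"chrom": e.derived_chrom, "seg_start": e.breakpoint,
                         "seg_end": chrom_lengths[e.derived_chrom],
                         "homolog": e.right_homolog})
        for chrom, homolog in unfused_homologs.items():
            if chrom in fused_chroms:
                continue
            rows.append({"chrom": chrom, "seg_start": 0,
                         "seg_end": chrom_lengths[chrom], "homolog": homolog})
        self.segments = pd.DataFrame(rows)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for c, g in self.segments.groupby("chrom"):
            g = g.sort_values("seg_start")
            self._by_chrom[str(c)] = (
                g["seg_start"].to_numpy(dtype=np.int64),
                g["seg_end"].to_numpy(dtype=np.int64),
                g["homolog"].to_numpy(dtype=object),
            )

    def homolog_lengths(self) -> dict[str, int]:
        segs = self.segments
        return {str(r.homolog): int(r.seg_end - r.seg_start)
                for r in segs.itertuples()}

    def map_position(self, chrom: str, pos: int) -> tuple[str, int]:
        starts, ends, homs = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            raise ValueError(f"position {pos} outside {chrom}")
        return str(homs[i]), int(pos - starts[i])

    def map_positions(self, chroms: np.ndarray, pos: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        chroms = np.asarray(chroms, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out_hom = np.empty(len(pos), dtype=object)
        out_pos = np.empty(len(pos), dtype=np.int64)
        for c in pd.unique(chroms):
            mask = chroms == c
            starts, ends, homs = self._by_chrom[str(c)]
            idx = np.searchsorted(starts, pos[mask], side="right") - 1
            if (idx < 0).any() or (pos[mask] >= ends[idx]).any():
                raise ValueError(f"positions outside {c}")
            out_hom[mask] = homs[idx]
            out_pos[mask] = pos[mask] - starts[idx]
        return out_hom, out_pos

    def map_features(self, features: pd.DataFrame) -> pd.DataFrame:
        """Relabel features to homolog coordinates.

        A feature spanning a breakpoint is assigned to the side holding its
        midpoint (a midpoint exactly at the breakpoint goes left) and flagged
        in the ``spans_breakpoint`` column; its coordinates are clipped to
        the assigned segment.
        """
        out = features.copy().reset_index(drop=True)
        homs = np.empty(len(out), dtype=object)
        new_s = np.empty(len(out), dtype=np.int64)
        new_e = np.empty(len(out), dtype=np.int64)
        spans = np.zeros(len(out), dtype=bool)
        chrom_arr = out["chrom"].to_numpy(dtype=object)
        start_arr = out["start"].to_numpy(dtype=np.int64)
        end_arr = out["end"].to_numpy(dtype=np.int64)
        mid_arr = (start_arr + end_arr) // 2
        for c in pd.unique(chrom_arr):
            mask = chrom_arr == c
            starts, ends, seg_homs = self._by_chrom[str(c)]
            mid = mid_arr[mask]
            # a midpoint exactly on an internal boundary goes left, hence
            # side="left" (mid == seg_start of the right segment -> index-1)
            idx = np.searchsorted(starts, mid, side="left") - 1
            idx = np.maximum(idx, 0)
            on_boundary = (mid == starts[np.minimum(idx + 1, len(starts) - 1)])
            inside = (mid >= starts[idx]) & (mid < ends[idx])
            if not (inside | on_boundary | (mid == starts[idx])).all():
                raise ValueError(f"feature midpoint outside {c}")
            homs[mask] = seg_homs[idx]
            spans[mask] = ((start_arr[mask] < starts[idx])
                           | (end_arr[mask] > ends[idx]))
            new_s[mask] = np.maximum(start_arr[mask], starts[idx]) - starts[idx]
            new_e[mask] = np.minimum(end_arr[mask], ends[idx]) - starts[idx]
        out["derived_chrom"] = out["chrom"]
        out["chrom"] = homs
        out["start"] = new_s
        out["end"] = new_e
        out["spans_breakpoint"] = spans
        return out

    def map_variants(self, table: VariantTable) -> VariantTable:
        out = table.copy()
        homs, pos = self.map_positions(out.chroms, out.pos)
        out.chroms = homs
        out.pos = pos
        return out


def classify_chromosomes(fusions: list[FusionEvent],
                         ancestral_lengths: dict[str, int],
                         all_homologs: list[str] | None = None) -> pd.DataFrame:
    """Assign NFC/LFC/SFC classes to ancestral homologs.

    For each fusion, the component with the smaller ancestral (outgroup)
    homolog length is the SFC and the other the LFC; everything else is NFC.
    Equal component lengths are broken by lexicographic homolog label with a
    logged warning.
    """
    rows = []
    fused: set[str] = set()
    for e in fusions:
        for h in (e.left_homolog, e.right_homolog):
            if h not in ancestral_lengths:
                raise ValueError(f"missing ancestral length for homolog {h}")
        la = ancestral_lengths[e.left_homolog]
        lb = ancestral_lengths[e.right_homolog]
        if la == lb:
            logger.warning("fusion on %s: equal component lengths; breaking "
                           "tie lexicographically", e.derived_chrom)
            short = min(e.left_homolog, e.right_homolog)
        else:
            short = e.left_homolog if la < lb else e.right_homolog
        for h in (e.left_homolog, e.right_homolog):
            rows.append({"homolog": h,
                         "chrom_class": "SFC" if h == short else "LFC",
                         "derived_chrom": e.derived_chrom,
                         "ancestral_length": ancestral_lengths[h]})
            fused.add(h)
    homolog_universe = all_homologs if all_homologs is not None \
        else sorted(ancestral_lengths)
    for h in homolog_universe:
        if h not in fused:
            rows.append({"homolog": h, "chrom_class": "NFC",
                         "derived_chrom": "",
                         "ancestral_length": ancestral_lengths.get(h, -1)})
    return pd.DataFrame(rows).sort_values("homolog").reset_index(drop=True)
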