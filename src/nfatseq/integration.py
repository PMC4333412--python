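"""Integration of binding with expression: occupancy curves, direct-target
calling, peak-height stratification, and TSS-proximity vs fold change.

The central definitions:

* a gene is *bound* when any peak summit lies within ``occupancy_distance_bp``
  (20 kb) of its TSS, in either direction, boundary inclusive;
* the *occupancy curve* ranks genes by log2 fold change (descending, ties by
  gene id) and slides a 50-gene window (step 1) reporting the window's mean
  fold change and bound fraction;
* a *direct target* is a gene with a site within 30 kb of its TSS whose
  height increases >= 1.5-fold on stimulation (curdlan vs untreated) and
  decreases to <= 1/1.5 of the stimulated height under calcineurin
  inhibition (curdlan+FK506 vs curdlan).  Heights get a pseudocount of 1
  before ratios so absent (height 0) peaks behave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import signed_tss_distance
from .io_formats import GeneModel, Peak, RunConfig, ValidationError, log

MATCH_TOLERANCE_BP = 200  # reciprocal-nearest summit matching window


@dataclass(frozen=True)
class DirectTargetCall:
    gene_id: str
    supporting_peak_id: str
    tss_distance_bp: int
    ratio_stim: float
    ratio_inhib: float


# ---------------------------------------------------------------------------
# bound indicator and occupancy curve
# ---------------------------------------------------------------------------

def _summits_by_chrom(peaks: list[Peak]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for p in peaks:
        out.setdefault(p.chrom, []).append(p.summit)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}

def bound_indicator(gene: GeneModel, peaks: list[Peak], distance_bp: int,
                    _summits: dict[str, np.ndarray] | None = None) -> bool:
    """True iff any peak summit lies within ``distance_bp`` of the gene TSS."""
    summits = _summits if _summits is not None else _summits_by_chrom(peaks)
    s = summits.get(gene.chrom)
    if s is None or len(s) == 0:
        return False
    i = np.searchsorted(s, gene.tss)
    best = min(
        abs(int(s[j]) - gene.tss) for j in (i - 1, i) if 0 <= j < len(s)
    )
    return best <= distance_bp


def occupancy_curve(de: pd.DataFrame, genes: list[GeneModel], peaks: list[Peak],
                    config: RunConfig) -> pd.DataFrame:
    """Moving-average bound fraction over expression-ranked genes.

    ``de`` is a frame indexed by gene_id with a ``log2fc`` column (one
    contrast).  Genes are sorted by log2fc descending (ties by gene id,
    rank 0 = most up-regulated); each window of ``occupancy_window_genes``
    contributes one point: (rank_center, mean log2fc, fraction bound).
    """
    gene_map = {g.gene_id: g for g in genes}
    missing = [gid for gid in de.index if gid not in gene_map]
    if missing:
        raise ValidationError(f"{len(missing)} DE genes lack a gene model (e.g. {missing[0]!r})")
    w = config.occupancy_window_genes
    if len(de) < w:
        raise ValidationError(f"need >= {w} genes for a {w}-gene window, got {len(de)}")
    order = de.assign(_gid=de.index.astype(str)).sort_values(
        ["log2fc", "_gid"], ascending=[False, True])
    ranked = order.index.to_list()
    l2fc = order["log2fc"].to_numpy(dtype=float)
    summits = _summits_by_chrom(peaks)
    bound = np.array(
        [bound_indicator(gene_map[g], peaks, config.occupancy_distance_bp, _summits=summits)
         for g in ranked], dtype=float)
    kernel = np.ones(w) / w
    mean_fc = np.convolve(l2fc, kernel, mode="valid")
    frac = np.convolve(bound, kernel, mode="valid")
    centers = np.arange(len(mean_fc)) + (w - 1) / 2
    return pd.DataFrame({
        "rank_center": centers,
        "mean_log2fc": mean_fc,
        "fraction_bound": frac,
    })


# ---------------------------------------------------------------------------
# cross-condition peak matching and direct-target calling
# ---------------------------------------------------------------------------

def match_peaks_across_conditions(peaks_by_condition: dict[str, list[Peak]]
                                  ) -> pd.DataFrame:
    """Match peaks across conditions into height tuples.

    Peaks sharing a ``peak_id`` are matched directly.  Remaining peaks are
    matched to the first condition's unmatched peaks by reciprocal-nearest
    summits within 200 bp on the same chromosome.  Unmatched conditions get
    height 0.  Returns one row per matched group with the reference summit
    (first condition present, preferring 'curdlan') and per-condition heights.
    """
    conditions = list(peaks_by_condition)
    if len(conditions) < 2:
        raise ValidationError("need >= 2 conditions to match")
    ref_cond = "curdlan" if "curdlan" in conditions else conditions[0]

    groups: dict[str, dict] = {}
    shared: dict[str, set[str]] = {}
    for cond in conditions:
        for p in peaks_by_condition[cond]:
            shared.setdefault(p.peak_id, set()).add(cond)
    id_matched = {pid for pid, cs in shared.items() if len(cs) > 1}

    leftovers: dict[str, list[Peak]] = {c: [] for c in conditions}
    for cond in conditions:
        for p in peaks_by_condition[cond]:
            if p.peak_id in id_matched:
                g = groups.setdefault(p.peak_id, {"chrom": p.chrom, "heights": {}, "summits": {}})
                g["heights"][cond] = p.height
                g["summits"][cond] = p.summit
            else:
                leftovers[cond].append(p)

    # reciprocal-nearest matching of leftovers against the reference condition
    ref_left = leftovers[ref_cond]
    ref_groups = [
        {"peak_id": p.peak_id, "chrom": p.chrom,
         "heights": {ref_cond: p.height}, "summits": {ref_cond: p.summit}}
        for p in ref_left
    ]
    ref_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in ref_left}:
        idx = np.array([i for i, p in enumerate(ref_left) if p.chrom == chrom])
        s = np.array([ref_left[i].summit for i in idx], dtype=np.int64)
        o = np.argsort(s)
        ref_by_chrom[chrom] = (s[o], idx[o])

    def nearest(sorted_pos: np.ndarray, pos: int) -> tuple[int, int]:
        """(index into sorted_pos, distance) of the nearest entry."""
        i = int(np.searchsorted(sorted_pos, pos))
        best_j, best_d = -1, np.iinfo(np.int64).max
        for j in (i - 1, i):
            if 0 <= j < len(sorted_pos):
                d = abs(int(sorted_pos[j]) - pos)
                if d < best_d:
                    best_j, best_d = j, d
        return best_j, best_d

    for cond in conditions:
        if cond == ref_cond:
            continue
        cond_left = leftovers[cond]
        cond_by_chrom: dict[str, np.ndarray] = {}
        for chrom in {p.chrom for p in cond_left}:
            cond_by_chrom[chrom] = np.sort(np.array(
                [p.summit for p in cond_left if p.chrom == chrom], dtype=np.int64))
        for p in cond_left:
            matched = False
            if p.chrom in ref_by_chrom:
                spos, sidx = ref_by_chrom[p.chrom]
                j, dist = nearest(spos, p.summit)
                if j >= 0 and dist <= MATCH_TOLERANCE_BP:
                    # reciprocal: the ref summit's nearest cond summit is p's
                    ref_summit = int(spos[j])
                    k, back_d = nearest(cond_by_chrom[p.chrom], ref_summit)
                    if back_d == dist:
                        g = ref_groups[int(sidx[j])]
                        g["heights"][cond] = p.height
                        g["summits"][cond] = p.summit
                        matched = True
            if not matched:
                groups[f"{p.peak_id}@{cond}"] = {
                    "chrom": p.chrom, "heights": {cond: p.height}, "summits": {cond: p.summit}}
    for g in ref_groups:
        groups[g.pop("peak_id")] = g

    rows = []
    for pid, g in groups.items():
        summit = g["summits"].get(ref_cond)
        if summit is None:  # fall back to any condition's summit
            summit = next(iter(g["summits"].values()))
        row = {"peak_id": pid, "chrom": g["chrom"], "summit": int(summit)}
        for cond in conditions:
            row[f"height_{cond}"] = g["heights"].get(cond, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("peak_id").reset_index(drop=True)
    return df


def call_direct_targets(genes: list[GeneModel], matched_peaks: pd.DataFrame,
                        config: RunConfig,
                        stim: str = "curdlan", inhib: str = "curdlan_fk506",
                        baseline: str = "untreated") -> pd.DataFrame:
    """Call direct targets from matched peak height tuples.

    One call per (gene, qualifying peak); a gene is a direct target iff it
    has >= 1 call.  Ratios use a pseudocount of 1 on heights.
    """
    needed = {f"height_{c}" for c in (stim, inhib, baseline)}
    if not needed <= set(matched_peaks.columns):
        raise ValidationError(f"matched peak table lacks columns {sorted(needed)}")
    h0 = matched_peaks[f"height_{baseline}"].to_numpy(dtype=float) + 1.0
    h1 = matched_peaks[f"height_{stim}"].to_numpy(dtype=float) + 1.0
    h2 = matched_peaks[f"height_{inhib}"].to_numpy(dtype=float) + 1.0
    ratio_stim = h1 / h0
    ratio_inhib = h2 / h1
    qualifies = (ratio_stim >= config.binding_up_ratio) & (ratio_inhib <= config.binding_down_ratio)

    q = matched_peaks.loc[qualifies].reset_index(drop=True)
    q_ratio_stim = ratio_stim[qualifies]
    q_ratio_inhib = ratio_inhib[qualifies]

    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(q["chrom"]):
        by_chrom.setdefault(c, []).append(i)

    rows = []
    for g in genes:
        for i in by_chrom.get(g.chrom, ()):
            summit = int(q.at[i, "summit"])
            if abs(summit - g.tss) <= config.direct_target_distance_bp:
                rows.append({
                    "gene_id": g.gene_id,
                    "supporting_peak_id": q.at[i, "peak_id"],
                    "tss_distance_bp": signed_tss_distance(summit, g),
                    "ratio_stim": q_ratio_stim[i],
                    "ratio_inhib": q_ratio_inhib[i],
                })
    cols = ["gene_id", "supporting_peak_id", "tss_distance_bp", "ratio_stim", "ratio_inhib"]
    return pd.DataFrame(rows, columns=cols).sort_values(["gene_id", "supporting_peak_id"]
                                                        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# peak-height strata and distance vs fold change
# ---------------------------------------------------------------------------

class _TSSIndex:
    """Sorted per-chromosome TSS positions for nearest-gene lookup.

    Ties at equal distance resolve to the lexicographically smaller gene id.
    """

    def __init__(self, genes: list[GeneModel]):
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._sorted: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._sorted[chrom] = (np.array([g.tss for g in gs], dtype=np.int64), gs)

    def nearest(self, chrom: str, pos: int, max_bp: int) -> GeneModel | None:
        entry = self._sorted.get(chrom)
        if entry is None:
            return None
        tss, gs = entry
        i = int(np.searchsorted(tss, pos))
        best, best_key = None, (max_bp + 1, "")
        for j in range(max(0, i - 2), min(len(gs), i + 2)):
            key = (abs(int(tss[j]) - pos), gs[j].gene_id)
            if key < best_key:
                best, best_key = gs[j], key
        return best


def height_strata_report(peaks: list[Peak], genes: list[GeneModel],
                         activated: set[str], config: RunConfig) -> pd.DataFrame:
    """Fraction of activated genes per peak-height stratum.

    Strata are half-open [lo, hi) with the last stratum closed; heights
    outside all strata go to an ``overflow`` stratum with a warning.  Each
    peak is associated to the nearest TSS within ``flank_distal_bp``;
    ``fraction_activated`` = |associated ∩ activated| / |associated| (NA
    when a stratum has no associated genes).
    """
    strata = config.height_strata
    tss_index = _TSSIndex(genes)

    labels = ["low", "medium", "high", "very_high"]
    if len(strata) != len(labels):
        labels = [f"stratum_{i}" for i in range(len(strata))]
    assigned: dict[str, list[Peak]] = {lab: [] for lab in labels}
    assigned["overflow"] = []
    last = len(strata) - 1
    for p in peaks:
        for i, (lo, hi) in enumerate(strata):
            if (lo <= p.height < hi) or (i == last and p.height == hi):
                assigned[labels[i]].append(p)
                break
        else:
            assigned["overflow"].append(p)
    if assigned["overflow"]:
        log.warning("height_strata_report: %d peaks outside all strata",
                    len(assigned["overflow"]))

    rows = []
    for i, lab in enumerate(labels + ["overflow"]):
        ps = assigned[lab]
        bounds = strata[i] if i < len(strata) else (np.nan, np.nan)
        assoc: set[str] = set()
        for p in ps:
            g = tss_index.nearest(p.chrom, p.summit, config.flank_distal_bp)
            if g is not None:
                assoc.add(g.gene_id)
        frac = len(assoc & activated) / len(assoc) if assoc else np.nan
        rows.append({
            "stratum": lab, "lo": bounds[0], "hi": bounds[1],
            "n_peaks": len(ps), "n_associated_genes": len(assoc),
            "fraction_activated": frac,
        })
    df = pd.DataFrame(rows)
    if df.loc[df["stratum"] == "overflow", "n_peaks"].iat[0] == 0:
        df = df[df["stratum"] != "overflow"].reset_index(drop=True)
    return df


def distance_vs_foldchange(genes: list[GeneModel], peaks: list[Peak],
                           de: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Signed distance of the nearest summit to each gene's TSS vs its log2fc.

    One record per gene with >= 1 peak within ``flank_distal_bp`` of its TSS
    and a DE measurement; the nearest summit is chosen by absolute distance.
    """
    sorted_peaks: dict[str, tuple[np.ndarray, list[Peak]]] = {}
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        ps = sorted(ps, key=lambda p: (p.summit, p.peak_id))
        sorted_peaks[chrom] = (np.array([p.summit for p in ps], dtype=np.int64), ps)
    rows = []
    de_ids = set(de.index)
    for g in genes:
        if g.gene_id not in de_ids or g.chrom not in sorted_peaks:
            continue
        summits, ps = sorted_peaks[g.chrom]
        i = int(np.searchsorted(summits, g.tss))
        cands = [ps[j] for j in range(max(0, i - 2), min(len(ps), i + 2))]
        nearest = min(cands, key=lambda p: (abs(p.summit - g.tss), p.peak_id))
        if abs(nearest.summit - g.tss) > config.flank_distal_bp:
            continue
        rows.append({
            "gene_id": g.gene_id,
            "nearest_peak_id": nearest.peak_id,
            "signed_tss_distance_bp": signed_tss_distance(nearest.summit, g),
            "log2fc": float(de.at[g.gene_id, "log2fc"]),
        })
    return pd.DataFrame(rows, columns=["gene_id", "nearest_peak_id",
                                       "signed_tss_distance_bp", "log2fc"])
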