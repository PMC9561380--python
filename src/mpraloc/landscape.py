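"""Positional localization landscapes, peak detection and gene classes.

Wild-type tiles of a gene are assembled into a per-gene logFC(neurite/soma)
profile along the 3'UTR.  Peaks are maximal runs of consecutive tiles whose
fold change exceeds 1.5 and whose mean P-value is below 0.05; genes are then
classed as *focused* (>= 1 peak), *broadly encoded* (net neurite enrichment
or significant positive skew of the per-tile signed significance without a
peak), or *not enriched*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TileProfile:
    gene_id: str
    tile_starts: np.ndarray
    logfc: np.ndarray
    pvalue: np.ndarray
    condition_label: str = ""
    tile_length: int = 150
    utr_length: int | None = None

    def __post_init__(self):
        self.tile_starts = np.asarray(self.tile_starts, dtype=int)
        self.logfc = np.asarray(self.logfc, dtype=float)
        self.pvalue = np.asarray(self.pvalue, dtype=float)
        if not (len(self.tile_starts) == len(self.logfc) == len(self.pvalue)):
            raise ValueError("profile arrays differ in length")
        if len(self.tile_starts) > 1 and (np.diff(self.tile_starts) <= 0).any():
            raise ValueError("tile starts must be strictly increasing")

    def __len__(self):
        return len(self.tile_starts)


@dataclass
class Peak:
    gene_id: str
    start: int
    end: int  # half-open UTR coordinates
    member_tile_starts: tuple[int, ...]
    mean_logfc: float
    mean_pvalue: float
    condition_label: str = ""

    def overlaps(self, other: "Peak") -> bool:
        return self.gene_id == other.gene_id and self.start < other.end and other.start < self.end


@dataclass
class GeneSummary:
    gene_id: str
    n_tiles: int
    mean_logfc_significant: float  # NaN when no significant tile
    n_significant: int
    frac_neurite_sig: float
    frac_soma_sig: float
    skew: float
    skew_pvalue: float
    n_peaks: int
    gene_class: str = ""
    excluded: bool = False
    condition_label: str = ""


def build_profiles(
    records: pd.DataFrame,
    design: pd.DataFrame,
    condition_label: str = "",
    tile_length: int = 150,
) -> list[TileProfile]:
    """One profile per gene from wild-type tile variants.

    Multi-barcode groups (wildtype + barcode_control rows sharing a tile)
    collapse to the mean logfc and the median pvalue.
    """
    wt = design[design.alteration_kind.isin(["wildtype", "barcode_control"])]
    merged = wt.merge(records[["variant_id", "logfc", "pvalue"]], on="variant_id")
    merged = merged.dropna(subset=["logfc"])
    profiles = []
    for gid, grp in merged.groupby("gene_id", sort=True):
        coll = (
            grp.groupby("tile_start")
            .agg(logfc=("logfc", "mean"), pvalue=("pvalue", "median"))
            .sort_index()
        )
        if len(coll) == 0:
            continue
        profiles.append(
            TileProfile(
                gene_id=gid,
                tile_starts=coll.index.to_numpy(),
                logfc=coll.logfc.to_numpy(),
                pvalue=coll.pvalue.to_numpy(),
                condition_label=condition_label,
                tile_length=tile_length,
            )
        )
    return profiles


def detect_peaks(
    profile: TileProfile,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> list[Peak]:
    """Maximal consecutive-tile runs with logfc >= log2(fc_threshold) whose
    mean pvalue < p_threshold; a single qualifying tile is a valid peak."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    thr = np.log2(fc_threshold)
    above = profile.logfc >= thr
    peaks = []
    i = 0
    n = len(profile)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        run = slice(i, j + 1)
        if np.mean(profile.pvalue[run]) < p_threshold:
            starts = profile.tile_starts[run]
            peaks.append(
                Peak(
                    gene_id=profile.gene_id,
                    start=int(starts.min()),
                    end=int(starts.max()) + profile.tile_length,
                    member_tile_starts=tuple(int(s) for s in starts),
                    mean_logfc=float(profile.logfc[run].mean()),
                    mean_pvalue=float(profile.pvalue[run].mean()),
                    condition_label=profile.condition_label,
                )
            )
        i = j + 1
    return peaks


def overlap_peaks(
    peaks_a: list[Peak], peaks_b: list[Peak]
) -> tuple[int, int, int]:
    """(shared, only_a, only_b): a peak is shared when it overlaps (>= 1 nt) a
    same-gene peak of the other set; overlapping clusters count as one merged
    shared event so the tally is symmetric."""
    hit_a = [any(p.overlaps(q) for q in peaks_b) for p in peaks_a]
    hit_b = [any(q.overlaps(p) for p in peaks_a) for q in peaks_b]
    only_a = sum(not h for h in hit_a)
    only_b = sum(not h for h in hit_b)
    # merged events: connected components of the bipartite overlap graph
    shared = 0
    unseen_b = {id(q): q for q, h in zip(peaks_b, hit_b) if h}
    for p, h in zip(peaks_a, hit_a):
        if not h:
            continue
        partners = [id(q) for q in unseen_b.values() if p.overlaps(q)]
        if partners:
            shared += 1
            stack = partners
            while stack:  # absorb the whole component
                q = unseen_b.pop(stack.pop(), None)
                if q is None:
                    continue
                for p2 in peaks_a:
                    if p2.overlaps(q):
                        stack.extend(
                            [id(q2) for q2 in unseen_b.values() if p2.overlaps(q2)]
                        )
    return shared, only_a, only_b


def signed_significance(logfc: np.ndarray, pvalue: np.ndarray) -> np.ndarray:
    """-log10(p) signed by the direction of the fold change."""
    p = np.clip(pvalue, 1e-300, 1.0)
    return np.sign(logfc) * (-np.log10(p))


def summarize_gene(
    profile: TileProfile,
    peaks: list[Peak],
    min_utr_length: int = 350,
    min_tiles: int = 10,
    p_threshold: float = 0.05,
    utr_length: int | None = None,
) -> GeneSummary:
    """Aggregate a gene's tile landscape into the classification inputs.

    Genes with a 3'UTR shorter than ``min_utr_length`` or fewer than
    ``min_tiles`` analyzed tiles are flagged excluded.  Skew is the adjusted
    Fisher-Pearson sample skewness of the signed significances, with the
    D'Agostino skewness-test p-value (NaN below n = 8 where the test is
    undefined).
    """
    n = len(profile)
    L = utr_length or profile.utr_length
    if L is None:
        L = int(profile.tile_starts.max()) + profile.tile_length
    excluded = L < min_utr_length or n < min_tiles

    sig = profile.pvalue < p_threshold
    neu = sig & (profile.logfc > 0)
    som = sig & (profile.logfc < 0)
    mean_sig = float(profile.logfc[sig].mean()) if sig.any() else np.nan
    v = signed_significance(profile.logfc, profile.pvalue)
    skew = float(sps.skew(v, bias=False)) if n >= 3 else np.nan
    if n >= 8 and np.ptp(v) > 0:
        skew_p = float(sps.skewtest(v).pvalue)
    else:
        skew_p = np.nan
    return GeneSummary(
        gene_id=profile.gene_id,
        n_tiles=n,
        mean_logfc_significant=mean_sig,
        n_significant=int(sig.sum()),
        frac_neurite_sig=float(neu.mean()),
        frac_soma_sig=float(som.mean()),
        skew=skew,
        skew_pvalue=skew_p,
        n_peaks=len(peaks),
        excluded=excluded,
        condition_label=profile.condition_label,
    )


def classify_gene(summary: GeneSummary) -> str:
    """focused (>= 1 peak) / broad / not_enriched, per the category rules."""
    if summary.excluded:
        raise ValueError(f"{summary.gene_id} is excluded from classification")
    if summary.n_peaks >= 1:
        return "focused"
    skew_sig = (
        np.isfinite(summary.skew_pvalue)
        and summary.skew_pvalue < 0.05
        and summary.skew > 0
    )
    net_neurite = (
        np.isfinite(summary.mean_logfc_significant)
        and summary.mean_logfc_significant > 0
        and summary.frac_neurite_sig > 0
    )
    return "broad" if (skew_sig or net_neurite) else "not_enriched"


def classify_genes(
    profiles: list[TileProfile],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    min_utr_length: int = 350,
    min_tiles: int = 10,
    utr_lengths: dict | None = None,
) -> pd.DataFrame:
    """Peaks + summaries + classes for a set of profiles, as one table."""
    rows = []
    for prof in profiles:
        peaks = detect_peaks(prof, fc_threshold, p_threshold)
        L = (utr_lengths or {}).get(prof.gene_id)
        summ = summarize_gene(
            prof, peaks, min_utr_length, min_tiles, p_threshold, utr_length=L
        )
        summ.gene_class = "" if summ.excluded else classify_gene(summ)
        rows.append(vars(summ))
    return pd.DataFrame(rows)


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene_id=p.gene_id,
                start=p.start,
                end=p.end,
                mean_logfc=p.mean_logfc,
                mean_pvalue=p.mean_pvalue,
                condition=p.condition_label,
            )
            for p in peaks
        ],
        columns=["gene_id", "start", "end", "mean_logfc", "mean_pvalue", "condition"],
    )


def moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average for display curves (edges shrink the window)."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    h = window // 2
    for i in range(len(v)):
        out[i] = v[max(0, i - h) : i + h + 1].mean()
    return out
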