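"""RBP motif models, cumulative binding scores and motif effect estimation.

Motifs are position probability matrices (PFM/PWM, MEME minimal format; RNA
alphabets are mapped to DNA).  A sequence's *cumulative binding score* for a
motif is the sum over all windows of the positive part of the log2-odds
against the background — it grows with both the number and the strength of
matches.  Planted insertion/deletion designs are evaluated by paired
differences against the wild-type context (Wilcoxon signed-rank), and
per-copy dose-response summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass
class Pwm:
    motif_id: str
    matrix: np.ndarray  # width x 4, columns A,C,G,T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be width x 4")
        bad = np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-6
        if bad.any():
            raise ValueError(
                f"{self.motif_id}: rows {np.nonzero(bad)[0].tolist()} do not sum to 1"
            )
        if self.width < 4:
            raise ValueError(f"{self.motif_id}: width must be >= 4")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2(p / background) per position and base; -inf at p = 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    def max_log_odds(self) -> float:
        return float(self.log_odds().max(axis=1).sum())


# ---------------------------------------------------------------------------
# MEME minimal format


def read_meme_motifs(path) -> list[Pwm]:
    """Parse MEME minimal motif format (U treated as T, row-sum checked to
    0.01 then renormalized)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    background = np.full(4, 0.25)
    motifs: list[Pwm] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[k].upper().replace("U", "T"): float(toks[k + 1])
                    for k in range(0, len(toks) - 1, 2)}
            background = np.array([freq.get(b, 0.25) for b in BASE_ORDER])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            rows = []
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            if i == len(lines):
                raise ValueError(f"{motif_id}: missing letter-probability matrix")
            i += 1
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) == 4 and all(_is_float(t) for t in toks):
                    rows.append([float(t) for t in toks])
                    i += 1
                else:
                    break
            mat = np.array(rows)
            sums = mat.sum(axis=1)
            if (np.abs(sums - 1.0) > 0.01).any():
                raise ValueError(f"{motif_id}: probability rows do not sum to 1")
            motifs.append(Pwm(motif_id, mat / sums[:, None], background.copy()))
            continue
        i += 1
    return motifs


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_meme_motifs(motifs: list[Pwm], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(BASE_ORDER, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alphlength= 4 w= {m.width} nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# k-mers and scores


def top_n_kmers(pwm: Pwm, n: int = 10) -> list[str]:
    """The n width-length k-mers with the highest product of per-position
    probabilities, ties broken lexicographically."""
    if pwm.width > 12:
        raise ValueError("k-mer enumeration limited to width <= 12")
    with np.errstate(divide="ignore"):
        logp = np.log(pwm.matrix)
    scores = np.zeros(1)
    for w in range(pwm.width):
        scores = (scores[:, None] + logp[w][None, :]).ravel()
    order = np.argsort(-scores, kind="stable")  # index order is lexicographic
    top = order[: min(n, len(scores))]
    kmers = []
    for idx in top:
        digits = []
        for _ in range(pwm.width):
            digits.append(BASE_ORDER[idx % 4])
            idx //= 4
        kmers.append("".join(reversed(digits)))
    return kmers


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[b] for b in sequence.upper().replace("U", "T")],
                        dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-ACGT character {e} in sequence") from None


def cumulative_score(sequence: str, pwm: Pwm) -> float:
    """Sum over all windows of max(0, log2 P_pwm(window)/P_bg(window)).

    Evaluated on the given strand only (the reporter RNA is single
    stranded); callers must pass the variable region without barcode or
    primer sequence.  Returns 0 for sequences shorter than the motif.
    """
    w = pwm.width
    if len(sequence) < w:
        return 0.0
    idx = encode(sequence)
    lo = pwm.log_odds()
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    scores = lo[np.arange(w)[None, :], windows].sum(axis=1)
    return float(np.clip(scores, 0.0, None).sum())


def score_matrix(sequences: dict, pwms: list[Pwm]) -> pd.DataFrame:
    """Cumulative scores, sequences (rows, keyed by id) x motifs (columns)."""
    data = {
        p.motif_id: [cumulative_score(s, p) for s in sequences.values()] for p in pwms
    }
    return pd.DataFrame(data, index=list(sequences.keys()))


# ---------------------------------------------------------------------------
# enrichment and correlation


def _has_hit(sequence: str, kmers: list[str]) -> bool:
    return any(k in sequence for k in kmers)


def motif_enrichment(
    fg_sequences: list[str],
    bg_sequences: list[str],
    kmers_by_motif: dict,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Fisher's exact test of per-sequence motif presence, foreground vs
    background; enriched = p < threshold and higher foreground proportion."""
    if not fg_sequences or not bg_sequences:
        raise ValueError("both sequence sets must be nonempty")
    rows = []
    for motif_id, kmers in kmers_by_motif.items():
        a = sum(_has_hit(s, kmers) for s in fg_sequences)
        c = sum(_has_hit(s, kmers) for s in bg_sequences)
        table = [[a, len(fg_sequences) - a], [c, len(bg_sequences) - c]]
        _, p = sps.fisher_exact(table, alternative="two-sided")
        fg_prop = a / len(fg_sequences)
        bg_prop = c / len(bg_sequences)
        rows.append(
            dict(
                motif_id=motif_id,
                fg_hits=a,
                bg_hits=c,
                fg_prop=fg_prop,
                bg_prop=bg_prop,
                pvalue=float(p),
                enriched=bool(p < p_threshold and fg_prop > bg_prop),
            )
        )
    return pd.DataFrame(rows)


def correlate_scores(
    scores: pd.DataFrame, logfc: pd.Series, fdr: float = 0.1
) -> pd.DataFrame:
    """Pearson correlation of each motif's cumulative score with logFC, with
    Benjamini-Hochberg q-values across motifs."""
    common = scores.index.intersection(logfc.dropna().index)
    y = logfc.loc[common].to_numpy()
    rows = []
    for motif_id in scores.columns:
        x = scores.loc[common, motif_id].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            rows.append(dict(motif_id=motif_id, pearson_r=np.nan, pvalue=np.nan,
                             n=int(ok.sum())))
            continue
        r, p = sps.pearsonr(x[ok], y[ok])
        rows.append(dict(motif_id=motif_id, pearson_r=float(r), pvalue=float(p),
                         n=int(ok.sum())))
    out = pd.DataFrame(rows)
    out["qvalue"] = np.nan
    ok = out.pvalue.notna()
    if ok.any():
        rej, q, _, _ = multipletests(out.pvalue[ok], alpha=fdr, method="fdr_bh")
        out.loc[ok, "qvalue"] = q
        out["significant"] = False
        out.loc[ok, "significant"] = rej
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact via rank-weight DP for small n)


def wilcoxon_exact_p(deltas: np.ndarray) -> float:
    """Two-sided exact signed-rank p-value over all 2^n sign assignments.

    Computed by dynamic programming over the (tie-averaged, doubled-to-
    integer) rank weights, which enumerates the full sign-flip null without
    expanding 2^n terms.  Zeros are dropped (Wilcoxon's treatment).
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w2 = np.rint(ranks * 2).astype(int)  # doubled ranks are integers
    wpos = int(np.rint((ranks[d > 0] * 2).sum()))
    total = int(w2.sum())
    # DP: number of sign subsets reaching each doubled-rank sum
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for w in w2:
        nxt = dist.copy()
        nxt[w:] += dist[: total + 1 - w]
        dist = nxt
    dist /= 2.0**n
    lower = dist[: wpos + 1].sum()
    upper = dist[wpos:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def signed_rank_test(deltas: np.ndarray, exact_max_n: int = 25) -> float:
    """Exact two-sided signed-rank p for n <= exact_max_n, else the normal
    approximation with continuity correction."""
    d = np.asarray(deltas, dtype=float)
    nz = d[d != 0]
    if len(nz) == 0:
        return 1.0
    if len(nz) <= exact_max_n:
        return wilcoxon_exact_p(d)
    return float(sps.wilcoxon(nz, correction=True, method="approx").pvalue)


@dataclass
class MotifEffectRecord:
    motif_id: str
    direction: str  # insertion | deletion
    n_pairs: int
    mean_delta_logfc: float
    wilcoxon_pvalue: float
    n_dropped: int = 0
    per_copy_means: dict = field(default_factory=dict)


def _paired_deltas(
    records: pd.DataFrame,
    design: pd.DataFrame,
    motif_id: str,
    kinds: tuple[str, ...],
) -> pd.DataFrame:
    """Per-context logfc difference altered - wildtype, matched on
    (gene_id, tile_start)."""
    merged = design.merge(records[["variant_id", "logfc"]], on="variant_id")
    wt = (
        merged[merged.alteration_kind == "wildtype"]
        .groupby(["gene_id", "tile_start"], as_index=False)
        .agg(wt_logfc=("logfc", "mean"))
    )
    alt = merged[
        (merged.alteration_kind.isin(kinds)) & (merged.motif == motif_id)
    ]
    alt = (
        alt.groupby(["gene_id", "tile_start", "copies"], as_index=False)
        .agg(alt_logfc=("logfc", "mean"))
    )
    return alt.merge(wt, on=["gene_id", "tile_start"])


def paired_motif_effect(
    records: pd.DataFrame,
    design: pd.DataFrame,
    motif_id: str,
    direction: str,
) -> MotifEffectRecord:
    """Mean paired effect of inserting or deleting a motif, with the
    signed-rank p-value; each (gene, tile) context contributes one pair."""
    if direction == "insertion":
        kinds = ("motif_insertion", "synthetic_insertion")
    elif direction == "deletion":
        kinds = ("motif_mutation",)
    else:
        raise ValueError("direction must be 'insertion' or 'deletion'")
    pairs = _paired_deltas(records, design, motif_id, kinds)
    n_dropped = int(pairs.alt_logfc.isna().sum() + pairs.wt_logfc.isna().sum())
    pairs = pairs.dropna(subset=["alt_logfc", "wt_logfc"])
    if len(pairs) == 0:
        raise ValueError(f"no valid pairs for motif {motif_id} ({direction})")
    delta = (pairs.alt_logfc - pairs.wt_logfc).to_numpy()
    return MotifEffectRecord(
        motif_id=motif_id,
        direction=direction,
        n_pairs=len(delta),
        mean_delta_logfc=float(delta.mean()),
        wilcoxon_pvalue=signed_rank_test(delta),
        n_dropped=n_dropped,
    )


def dose_response(
    records: pd.DataFrame, design: pd.DataFrame, motif_id: str
) -> tuple[dict, float]:
    """Mean paired effect per inserted copy number (0 = wild-type context,
    mean 0 by construction) and the Spearman rho of copies vs effect."""
    pairs = _paired_deltas(
        records, design, motif_id, ("motif_insertion", "synthetic_insertion")
    ).dropna(subset=["alt_logfc", "wt_logfc"])
    pairs["delta"] = pairs.alt_logfc - pairs.wt_logfc
    per_copy = {0: 0.0} if (design.alteration_kind == "wildtype").any() else {}
    for c, grp in pairs.groupby("copies"):
        per_copy[int(c)] = float(grp.delta.mean())
    if len(pairs) >= 3 and pairs.copies.nunique() > 1:
        rho = float(sps.spearmanr(pairs.copies, pairs.delta).statistic)
    else:
        rho = np.nan
    return per_copy, rho


def pwm_hit_threshold(pwm: Pwm, fraction: float = 0.6) -> float:
    """Window log-odds threshold for calling a PWM hit (fraction of the
    maximum achievable log-odds)."""
    return fraction * pwm.max_log_odds()
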