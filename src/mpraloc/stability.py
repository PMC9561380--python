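"""Relative RNA decay from the transcription-shutoff series.

Abundance log2 fold changes at 4 h and 24 h after transcription inhibition
(vs 0 h) are fit with the same NB GLM used for the localization contrast.
Because size factors absorb the population-average decay, these logFCs are
*relative* stabilities: positive means more stable than the library
population, negative less stable.  Absolute half-lives are not recoverable
without spike-ins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import UmiCountMatrix
from .stats import glm_lrt


def compute_decay(matrix: UmiCountMatrix, min_total: int = 10) -> pd.DataFrame:
    """StabilityRecords: per-variant logfc_4h / logfc_24h with p-values."""
    conds = set(matrix.samples.condition)
    if not {"t0", "t4"} <= conds:
        raise ValueError("decay matrix must contain t0 and t4 samples")
    r4 = glm_lrt(matrix, "t4_vs_t0", min_total=min_total)
    out = r4.rename(columns={"logfc": "logfc_4h", "pvalue": "pvalue_4h"})[
        ["variant_id", "logfc_4h", "pvalue_4h", "mean_count"]
    ]
    if "t24" in conds:
        r24 = glm_lrt(matrix, "t24_vs_t0", min_total=min_total)
        out = out.merge(
            r24.rename(columns={"logfc": "logfc_24h", "pvalue": "pvalue_24h"})[
                ["variant_id", "logfc_24h", "pvalue_24h"]
            ],
            on="variant_id",
        )
    return out


def distribution_skew(values) -> tuple[float, float]:
    """Adjusted Fisher-Pearson sample skewness and the D'Agostino
    skewness-test p-value; requires n >= 8 (test undefined below)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 8:
        raise ValueError("skewness test requires n >= 8")
    return float(sps.skew(v, bias=False)), float(sps.skewtest(v).pvalue)


def stratified_localization_stability(
    loc_records: pd.DataFrame,
    stab_records: pd.DataFrame,
    stability_col: str = "logfc_4h",
) -> tuple[dict, pd.DataFrame]:
    """Correlation of localization with stability, overall and stratified by
    localization direction, plus per-variant z-scores of both readouts.

    Returns ({'all': r, 'soma_biased': r, 'neurite_biased': r}, table); a
    stratum with fewer than 3 variants reports NaN.  z-scores standardize
    each readout over the analyzed population (mean 0, SD 1).
    """
    merged = loc_records[["variant_id", "logfc"]].merge(
        stab_records[["variant_id", stability_col]], on="variant_id"
    )
    merged = merged.dropna()
    loc = merged.logfc.to_numpy()
    stab = merged[stability_col].to_numpy()

    def _r(mask) -> float:
        if mask.sum() < 3:
            return np.nan
        return float(sps.pearsonr(loc[mask], stab[mask]).statistic)

    result = {
        "all": _r(np.ones(len(merged), dtype=bool)),
        "soma_biased": _r(loc < 0),
        "neurite_biased": _r(loc > 0),
    }
    table = merged.copy()
    table["z_logfc_loc"] = (loc - loc.mean()) / loc.std(ddof=0)
    table["z_stability"] = (stab - stab.mean()) / stab.std(ddof=0)
    return result, table
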