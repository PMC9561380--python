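"""Per-variant negative-binomial GLM enrichment statistics.

The neurite/soma contrast (and the decay contrasts t4/t0, t24/t0) are tested
per library variant with a log-link NB GLM: counts ~ condition with
log(size factor) offsets, dispersion phi held fixed at a moderated
method-of-moments estimate, and a likelihood-ratio test (chi-square, 1 df)
of the condition term.  Size factors are median-of-ratios; because a
constant fold change in all variants is absorbed by normalization, every
logFC here is relative to the library population.

For a single two-group factor the GLM decomposes into two independent
one-parameter fits (one mean rate per group), which we solve with a
vectorized Newton iteration across all variants at once; the log-link NB
log-likelihood is concave in the linear predictor, so this converges to the
MLE that an IRLS fit of the full design matrix would reach.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import UmiCountMatrix

CONTRASTS = {
    "neurite_vs_soma": ("neurite", "soma"),
    "t4_vs_t0": ("t4", "t0"),
    "t24_vs_t0": ("t24", "t0"),
}

_LN2 = np.log(2.0)
_PHI_FLOOR = 1e-8  # numerically Poisson


# ---------------------------------------------------------------------------
# normalization


def normalize(matrix: UmiCountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median_i counts_ij / geomean_i(counts_i.), over variants with
    all-positive counts.
    """
    y = matrix.counts.to_numpy(dtype=float)
    allpos = (y > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no variant with positive counts in every sample")
    yp = y[allpos]
    log_geo = np.log(yp).mean(axis=1, keepdims=True)
    s = np.exp(np.median(np.log(yp) - log_geo, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=matrix.counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersion(
    matrix: UmiCountMatrix,
    size_factors: pd.Series | None = None,
    n_prior: float = 10.0,
    phi_max: float = 10.0,
) -> pd.DataFrame:
    """Moderated per-variant NB dispersion (variance = mu + phi mu^2).

    Raw method-of-moments phi from within-condition variance of normalized
    counts is shrunk toward a lowess mean-dispersion trend with weight
    n_rep / (n_rep + n_prior).
    """
    s = (size_factors if size_factors is not None else normalize(matrix)).to_numpy()
    y = matrix.counts.to_numpy(dtype=float)
    z = y / s  # normalized counts
    conds = matrix.samples.condition.to_numpy()

    num = np.zeros(len(y))
    den = 0.0
    n_rep = []
    shot = np.zeros(len(y))  # Poisson component of Var(z)
    mean_all = z.mean(axis=1)
    for c in np.unique(conds):
        cols = conds == c
        n_c = int(cols.sum())
        if n_c < 2:
            continue
        m = z[:, cols].mean(axis=1)
        v = z[:, cols].var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / s[cols]))
        num += (n_c - 1) * (v - m * inv_s)
        den += n_c - 1
        shot += (n_c - 1) * m**2
        n_rep.append(n_c)
    if den == 0:
        raise ValueError("need >= 2 replicates in at least one condition")
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.clip((num / den) / (shot / den), 0.0, phi_max)
    phi_raw = np.where(np.isfinite(phi_raw), phi_raw, np.nan)

    ok = np.isfinite(phi_raw) & (mean_all > 0)
    logm = np.log10(np.maximum(mean_all, 1e-8))
    if ok.sum() >= 10:
        # it=0: robustifying iterations would chase the mode of the skewed
        # raw estimates and bias the trend low
        fit = lowess(phi_raw[ok], logm[ok], frac=0.4, it=0, return_sorted=True)
        trend = np.interp(logm, fit[:, 0], fit[:, 1])
    else:
        trend = np.full(len(y), np.nanmedian(phi_raw) if ok.any() else 0.0)
    trend = np.clip(trend, 0.0, phi_max)

    w = np.mean(n_rep) / (np.mean(n_rep) + n_prior)
    phi = np.where(np.isfinite(phi_raw), w * phi_raw + (1 - w) * trend, trend)
    phi = np.clip(phi, 0.0, phi_max)
    return pd.DataFrame(
        {"phi_raw": phi_raw, "phi_trend": trend, "phi": phi},
        index=matrix.counts.index,
    )


# ---------------------------------------------------------------------------
# NB group fits


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; mu, y are (n_var, n_samp),
    phi (n_var,). Safe at mu = 0 (only y = 0 has support there)."""
    phi = np.maximum(phi, _PHI_FLOOR)[:, None]
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + y * (np.log(phi * mu) - np.log1p(phi * mu))
        - r * np.log1p(phi * mu)
    )
    return ll.sum(axis=1)


def _fit_common_rate(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray, max_iter: int = 50, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE of a single rate lambda with mu_ij = lambda_i s_j, NB(phi_i).

    Returns (log lambda, loglik, converged).  Rows with zero total get
    lambda = 0 and loglik 0 (their likelihood is degenerate but finite).
    """
    tot = y.sum(axis=1)
    S = s.sum()
    beta = np.log(np.maximum(tot, 0.5) / S)
    phi_ = np.maximum(phi, _PHI_FLOOR)
    active = tot > 0
    converged = np.ones(len(y), dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        mu = np.exp(beta)[:, None] * s[None, :]
        denom = 1.0 + phi_[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(active, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -3.0, 3.0)
        beta = beta + step
        active = active & (np.abs(step) > tol)
    converged = ~active
    zero = tot == 0
    beta = np.where(zero, -np.inf, beta)
    mu = np.exp(np.where(zero, -700.0, beta))[:, None] * s[None, :]
    ll = _nb_loglik(y, np.where(zero[:, None], 0.0, mu), phi_)
    return beta, ll, converged | zero


def glm_lrt(
    matrix: UmiCountMatrix,
    contrast: str = "neurite_vs_soma",
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    min_total: int = 10,
) -> pd.DataFrame:
    """Per-variant log2 fold change and LRT p-value for a two-group contrast.

    Variants with total count < ``min_total`` across the contrast's samples
    are reported with pvalue 1 and logfc NaN.  When one group has zero total,
    the reported logfc uses a 0.5 pseudocount so it stays finite; the test
    itself uses the exact zero-group likelihood.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    g1, g0 = CONTRASTS[contrast]
    sub = matrix.subset_conditions([g1, g0])
    s = (size_factors if size_factors is not None else normalize(sub)).loc[
        sub.counts.columns
    ]
    if dispersions is None:
        phi = estimate_dispersion(sub, s)["phi"]
    else:
        phi = dispersions.loc[sub.counts.index]
    y = sub.counts.to_numpy(dtype=float)
    conds = sub.samples.condition.to_numpy()
    sv = s.to_numpy()
    m1, m0 = conds == g1, conds == g0
    phiv = phi.to_numpy(dtype=float)

    b1, ll1, c1 = _fit_common_rate(y[:, m1], sv[m1], phiv)
    b0, ll0, c0 = _fit_common_rate(y[:, m0], sv[m0], phiv)
    _, llr, cr = _fit_common_rate(y, sv, phiv)
    lrt = np.maximum(2.0 * (ll1 + ll0 - llr), 0.0)
    pval = chi2.sf(lrt, df=1)

    logfc = (b1 - b0) / _LN2
    # pseudocount rescue for one-sided zero groups
    t1, t0 = y[:, m1].sum(axis=1), y[:, m0].sum(axis=1)
    need = ~np.isfinite(logfc)
    if need.any():
        lam1 = (t1 + 0.5) / sv[m1].sum()
        lam0 = (t0 + 0.5) / sv[m0].sum()
        logfc = np.where(need, np.log2(lam1 / lam0), logfc)

    total = y.sum(axis=1)
    low = total < min_total
    mean_count = (y / sv).mean(axis=1)
    out = pd.DataFrame(
        {
            "variant_id": sub.counts.index,
            "contrast": contrast,
            "logfc": np.where(low, np.nan, logfc),
            "pvalue": np.where(low, 1.0, pval),
            "mean_count": mean_count,
            "converged": c1 & c0 & cr,
        }
    )
    return out


# ---------------------------------------------------------------------------
# multi-barcode concordance


def multibarcode_concordance(
    records: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Agreement of logFC across variants sharing a variable region.

    Groups are sets of >= 2 design rows with identical (gene_id, tile_start,
    variable_region); per group we report the fraction of members carrying
    the majority sign and the within-group SD of logfc.
    """
    merged = design.merge(records[["variant_id", "logfc"]], on="variant_id")
    rows = []
    for (gid, start, _vr), grp in merged.groupby(
        ["gene_id", "tile_start", "variable_region"], dropna=False
    ):
        if len(grp) < 2 or grp.logfc.isna().any():
            continue
        v = grp.logfc.to_numpy()
        agree = max((v > 0).sum(), (v <= 0).sum()) / len(v)
        rows.append(
            dict(
                gene_id=gid,
                tile_start=start,
                n=len(v),
                sign_agreement=agree,
                logfc_sd=float(np.std(v, ddof=1)),
                mean_logfc=float(v.mean()),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "tile_start", "n", "sign_agreement", "logfc_sd", "mean_logfc"],
    )
    summary = {
        "n_groups": len(table),
        "mean_sign_agreement": float(table.sign_agreement.mean()) if len(table) else np.nan,
        "mean_within_group_sd": float(table.logfc_sd.mean()) if len(table) else np.nan,
    }
    return table, summary
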