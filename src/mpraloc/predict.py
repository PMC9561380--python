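"""Dual-classifier prediction of neurite vs soma localization.

Two gradient-boosted tree classifiers are trained on MPRA outcomes observed
in two cell lines: one for neurite enrichment (positive class: logFC > 0 and
P < 0.05 in both lines) and one for soma enrichment (logFC < 0 and P < 0.05
in both).  Features are overlapping fourmer counts of the variable region
(barcode and primers excluded) and/or cumulative RBP binding scores.  The
combined localization score of a sequence is P(neurite) - P(soma); a native
3'UTR is scored by tiling it (150 nt / 50 nt step) and taking the median
tile neurite probability minus the maximum tile soma probability — a single
strong soma-retention tile can veto an otherwise neurite-leaning 3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .motifs import Pwm, cumulative_score

FOURMERS = ["".join(k) for k in product("ACGT", repeat=4)]  # lexicographic
_K_IDX = {k: i for i, k in enumerate(FOURMERS)}

DEFAULT_HYPERPARAMS = {
    "n_estimators": 200,
    "max_depth": 4,
    "learning_rate": 0.1,
    "subsample": 0.8,
}

#: small grid searched by cross-validation when no hyperparameters are given
CV_GRID = [
    {"n_estimators": n, "max_depth": d, "learning_rate": 0.1, "subsample": 0.8}
    for n, d in product((100, 200), (3, 4))
]


def extract_fourmers(effective_sequence: str) -> np.ndarray:
    """256-vector of overlapping fourmer counts, lexicographic order.

    The caller passes the effective sequence (variable region only; no
    barcode or primers).  Sequences shorter than 4 give the zero vector.
    """
    out = np.zeros(256, dtype=np.int64)
    s = effective_sequence.upper()
    if set(s) - set("ACGT"):
        raise ValueError(f"non-ACGT character in {s[:20]!r}...")
    for i in range(len(s) - 3):
        out[_K_IDX[s[i : i + 4]]] += 1
    return out


def feature_matrix(
    sequences: dict,
    feature_set: str = "fourmers",
    pwms: list[Pwm] | None = None,
) -> pd.DataFrame:
    """Features x sequences; feature_set in {fourmers, rbp, both}."""
    ids = list(sequences)
    blocks = []
    if feature_set in ("fourmers", "both"):
        X = np.vstack([extract_fourmers(sequences[i]) for i in ids])
        blocks.append(pd.DataFrame(X, index=ids, columns=FOURMERS))
    if feature_set in ("rbp", "both"):
        if not pwms:
            raise ValueError("rbp features require a PWM list")
        X = np.array(
            [[cumulative_score(sequences[i], p) for p in pwms] for i in ids]
        )
        blocks.append(
            pd.DataFrame(X, index=ids, columns=[f"rbp_{p.motif_id}" for p in pwms])
        )
    if not blocks:
        raise ValueError(f"unknown feature set {feature_set!r}")
    out = pd.concat(blocks, axis=1)
    out.attrs["feature_set"] = feature_set
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def prepare_dataset(
    enrichment_a: pd.DataFrame,
    enrichment_b: pd.DataFrame,
    design: pd.DataFrame,
    counts=None,
    min_total_reads: int = 500,
    holdout_frac: float = 0.10,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, dedupe, label and split variants for training.

    Variants need ``min_total_reads`` UMIs summed over the six localization
    samples (taken from ``counts`` when given, else 6 x mean_count);
    duplicate variable regions keep one seeded-random representative; labels
    require the same significant direction in both cell lines; the holdout
    split is stratified on the label pair.  Returns (train, test) tables
    with columns variant_id, variable_region, neurite_positive,
    soma_positive.
    """
    rng = np.random.default_rng(seed)
    a = enrichment_a.set_index("variant_id")
    b = enrichment_b.set_index("variant_id")
    common = a.index.intersection(b.index)
    df = design[design.variant_id.isin(common)][
        ["variant_id", "variable_region"]
    ].copy()
    if counts is not None:
        cm = counts.counts if hasattr(counts, "counts") else counts
        total = cm.sum(axis=1)
        df["total_reads"] = df.variant_id.map(total)
    else:
        df["total_reads"] = df.variant_id.map(a.mean_count * 6.0)
    df = df[df.total_reads >= min_total_reads]

    # one seeded-random representative per duplicated variable region
    df = df.sample(frac=1.0, random_state=rng.integers(0, 2**31)).drop_duplicates(
        "variable_region"
    )

    la, lb = a.loc[df.variant_id], b.loc[df.variant_id]
    sig_a = (la.pvalue < p_threshold).to_numpy()
    sig_b = (lb.pvalue < p_threshold).to_numpy()
    up = (la.logfc > 0).to_numpy() & (lb.logfc > 0).to_numpy()
    down = (la.logfc < 0).to_numpy() & (lb.logfc < 0).to_numpy()
    df["neurite_positive"] = sig_a & sig_b & up
    df["soma_positive"] = sig_a & sig_b & down
    assert not (df.neurite_positive & df.soma_positive).any()
    if len(df) < 10:
        raise ValueError("too few variants after filtering")

    strata = df.neurite_positive.astype(int) * 2 + df.soma_positive.astype(int)
    if strata.value_counts().min() < 2:
        strata = None  # stratification impossible for singleton label groups
    train, test = train_test_split(
        df,
        test_size=holdout_frac,
        stratify=strata,
        random_state=int(rng.integers(0, 2**31)),
    )
    if len(train) == 0:
        raise ValueError("empty training set")
    return train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# models


@dataclass
class DualModels:
    """The two binary classifiers plus the feature manifest."""

    model_neurite: XGBClassifier
    model_soma: XGBClassifier
    feature_names: list[str]
    feature_set: str = "fourmers"
    version: str = "1"
    cv_auroc: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "DualModels":
        return joblib.load(path)


def _make_xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        tree_method="hist",
    )


def _cv_auroc(X, y, params, seed, n_splits=3) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        m = _make_xgb(params, seed)
        m.fit(X[tr], y[tr])
        aucs.append(evaluate_auroc(m.predict_proba(X[va])[:, 1], y[va]))
    return float(np.mean(aucs))


def train_dual_models(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
    feature_set: str = "fourmers",
) -> DualModels:
    """Fit the neurite and soma classifiers.

    ``features`` is indexed by variant_id; ``labels`` carries variant_id,
    neurite_positive, soma_positive.  When no hyperparameters are given a
    small grid is scored by stratified 3-fold cross-validation on the
    training data only, separately per model.
    """
    lab = labels.set_index("variant_id").loc[features.index]
    X = features.to_numpy(dtype=float)
    models, cv_scores = {}, {}
    for name in ("neurite", "soma"):
        y = lab[f"{name}_positive"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} labels contain a single class")
        if hyperparams is not None:
            params = dict(hyperparams)
        else:
            scored = [(_cv_auroc(X, y, p, seed), i, p) for i, p in enumerate(CV_GRID)]
            best = max(scored)
            params, cv_scores[name] = best[2], best[0]
        m = _make_xgb(params, seed)
        m.fit(X, y)
        models[name] = m
    return DualModels(
        model_neurite=models["neurite"],
        model_soma=models["soma"],
        feature_names=list(features.columns),
        feature_set=feature_set,
        cv_auroc=cv_scores,
    )


def predict_probabilities(models: DualModels, features: pd.DataFrame) -> pd.DataFrame:
    if list(features.columns) != models.feature_names:
        raise ValueError("feature columns do not match the model manifest")
    X = features.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "p_neurite": models.model_neurite.predict_proba(X)[:, 1],
            "p_soma": models.model_soma.predict_proba(X)[:, 1],
        },
        index=features.index,
    )


def combined_score(p_neurite: float, p_soma: float) -> float:
    """P(neurite enriched) - P(soma enriched), in [-1, 1]."""
    pn, ps = np.asarray(p_neurite, dtype=float), np.asarray(p_soma, dtype=float)
    if ((pn < 0) | (pn > 1) | (ps < 0) | (ps > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    out = pn - ps
    return float(out) if out.ndim == 0 else out


@dataclass
class NativePrediction:
    gene_id: str
    tile_starts: list[int]
    p_neurite: np.ndarray
    p_soma: np.ndarray
    combined: float  # median(p_neurite) - max(p_soma)


def predict_native(
    utr_sequence: str,
    models: DualModels,
    gene_id: str = "",
    tile_length: int = 150,
    step: int = 50,
    pwms: list[Pwm] | None = None,
) -> NativePrediction:
    """Score a native 3'UTR: tile it, score each tile with both models, and
    aggregate as median neurite probability minus maximum soma probability."""
    if len(utr_sequence) < tile_length:
        raise ValueError("UTR shorter than one tile")
    starts = list(range(0, len(utr_sequence) - tile_length + 1, step))
    tiles = {s: utr_sequence[s : s + tile_length] for s in starts}
    feats = feature_matrix(tiles, models.feature_set, pwms)
    feats = feats[models.feature_names]
    probs = predict_probabilities(models, feats)
    pn, ps = probs.p_neurite.to_numpy(), probs.p_soma.to_numpy()
    return NativePrediction(
        gene_id=gene_id,
        tile_starts=starts,
        p_neurite=pn,
        p_soma=ps,
        combined=float(np.median(pn) - np.max(ps)),
    )


def evaluate_auroc(scores, labels) -> float:
    """Rank-based auROC: P(random positive outscores a random negative),
    ties counted 1/2 (Mann-Whitney U / (n1 n0))."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    r = rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))
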