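"""Ground-truthed simulation of the tiled-3'UTR localization MPRA.

The generator emulates the statistical structure the downstream analysis
assumes: genes fall into localization classes (focused peak / broadly
encoded / soma-restricted / null), short RBP-like motifs carry additive
per-occurrence log2(neurite/soma) effects, UMI counts are negative-binomial
over three biological replicates per compartment, and a transcription-shutoff
series (0/4/24 h, two replicates each) encodes relative decay.  Optionally
the counts are expanded into paired FASTQ reads (read 2 starts with the
variant barcode, read 1 with a 15-nt UMI).
"""

from __future__ import annotations

import gzip as _gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import UmiCountMatrix
from .design import (
    BASES,
    AlterationSpec,
    DesignConfig,
    GeneUtr,
    OligoVariant,
    _find_all,
    build_design,
)

GENE_CLASSES = ("focused", "broad", "soma_restricted", "null")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated assay.

    Effects are log2(neurite/soma) units per motif occurrence; decay rates
    are per hour.  Defaults describe a pilot-scale validation study sized so the planted
    structure is recoverable at the assay's error rates: 10 genes with
    1.6-2.6 kb 3'UTRs, three barcodes per designed variant, tight biological
    replicates (NB dispersion 0.02, i.e. BCV ~ 0.14) and 1e5 UMIs per
    sample.
    """

    n_genes: int = 10
    class_proportions: dict = field(
        default_factory=lambda: {
            "focused": 0.25,
            "broad": 0.35,
            "soma_restricted": 0.15,
            "null": 0.25,
        }
    )
    utr_length_range: tuple[int, int] = (1600, 2600)
    neurite_motifs: dict = field(
        default_factory=lambda: {"AGGTAA": 0.4, "GTTCAG": 0.3}
    )
    soma_motifs: dict = field(default_factory=lambda: {"TCTTCT": -0.4})
    focused_peak_effect: float = 1.5
    broad_per_tile_effect: float = 0.3
    baseline_abundance_log_mean: float = 0.0
    baseline_abundance_log_sd: float = 0.5
    dispersion: float = 0.02
    replicates_loc: int = 3
    replicates_decay: int = 2
    depth: float = 100_000.0
    base_decay_rate: float = 0.10
    decay_rate_per_soma_motif: float = 0.05
    decay_timepoints: tuple[float, ...] = (0.0, 4.0, 24.0)
    n_barcodes: int = 3
    umi_length: int = 15
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if set(self.class_proportions) - set(GENE_CLASSES):
            raise ValueError("unknown gene class in proportions")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")

    @property
    def effect_motifs(self) -> dict:
        return {**self.neurite_motifs, **self.soma_motifs}


@dataclass
class GroundTruth:
    """Planted truth: per-gene class, peak windows and motif placements;
    per-variant effects are derived later by :func:`true_effects`."""

    gene_class: dict
    peak_windows: dict  # gene_id -> list of (start, end) half-open
    planted: dict  # gene_id -> list of (position, motif)


# ---------------------------------------------------------------------------
# gene simulation


def _random_clean_utr(length: int, avoid: tuple[str, ...], rng) -> str:
    """Uniform-random UTR with every occurrence of the avoided substrings
    (PAS signals and effect motifs) scrubbed by redrawing."""
    seq = list(BASES[c] for c in rng.integers(0, 4, size=length))
    for _ in range(200):
        s = "".join(seq)
        hits = [(p, m) for m in avoid for p in _find_all(s, m)]
        if not hits:
            return s
        for p, m in hits:
            for k in range(p, p + len(m)):
                seq[k] = BASES[rng.integers(0, 4)]
    raise RuntimeError("could not scrub avoided motifs")


def _plant(seq: str, motif: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p : p + len(motif)] = motif
    return "".join(out)


def _spaced_positions(lo: int, hi: int, n: int, spacing: int, rng) -> list[int]:
    """n random positions in [lo, hi) pairwise at least ``spacing`` apart:
    one per equal-width bin, jittered within the slack the spacing allows."""
    width = (hi - lo) / n
    if width < spacing and n > 1:
        raise ValueError(f"cannot place {n} positions with spacing {spacing} in [{lo},{hi})")
    slack = max(1, int(width - spacing) if n > 1 else int(width))
    return [lo + int(i * width) + int(rng.integers(0, slack)) for i in range(n)]


def simulate_genes(
    config: SimConfig, design_config: DesignConfig | None = None
) -> tuple[list[GeneUtr], GroundTruth]:
    """Draw random 3'UTRs and plant class-specific motif structure.

    focused: strongest neurite motif concentrated in one 200-nt window (the
    recorded peak window); broad: the weak neurite motif scattered with >=200
    nt spacing so no single tile accumulates peak-level signal;
    soma_restricted: soma motifs scattered; null: nothing planted.  Chance
    occurrences of PAS signals and of any effect motif are scrubbed from the
    background so the planted occurrences are the only ones.
    """
    rng = np.random.default_rng(config.seed)
    design_config = design_config or DesignConfig()
    avoid = tuple(design_config.pas_motifs) + tuple(config.effect_motifs)

    classes = list(config.class_proportions)
    counts = np.floor(
        np.array([config.class_proportions[c] for c in classes]) * config.n_genes
    ).astype(int)
    while counts.sum() < config.n_genes:  # distribute rounding remainder
        counts[int(rng.integers(0, len(classes)))] += 1
    labels = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(labels)

    strong_neurite = max(config.neurite_motifs, key=config.neurite_motifs.get)
    weak_neurite = min(
        config.neurite_motifs,
        key=lambda m: abs(config.neurite_motifs[m] - config.broad_per_tile_effect),
    )

    genes, gclass, windows, planted = [], {}, {}, {}
    for i, label in enumerate(labels):
        gid = f"gene{i:03d}_{label}"
        L = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        seq = _random_clean_utr(L, avoid, rng)
        placed: list[tuple[int, str]] = []
        if label == "focused":
            w0 = int(rng.integers(0, L - 200 + 1))
            pos = _spaced_positions(w0, w0 + 200 - len(strong_neurite), 3, 12, rng)
            seq = _plant(seq, strong_neurite, pos)
            windows[gid] = [(w0, w0 + 200)]
            placed += [(p, strong_neurite) for p in pos]
        elif label == "broad":
            n = max(2, L // 250)
            pos = _spaced_positions(0, L - len(weak_neurite), n, 200, rng)
            seq = _plant(seq, weak_neurite, pos)
            placed += [(p, weak_neurite) for p in pos]
        elif label == "soma_restricted":
            motif = list(config.soma_motifs)[0]
            n = max(2, L // 250)
            pos = _spaced_positions(0, L - len(motif), n, 200, rng)
            seq = _plant(seq, motif, pos)
            placed += [(p, motif) for p in pos]
        genes.append(GeneUtr(gid, seq, label))
        gclass[gid] = label
        windows.setdefault(gid, [])
        planted[gid] = placed
    return genes, GroundTruth(gclass, windows, planted)


# ---------------------------------------------------------------------------
# per-variant truth


def true_effects(
    variants: list[OligoVariant], truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Additive per-variant truth derived by scanning each variable region.

    true_logfc_loc = sum over motif occurrences of the motif effect, plus the
    focused-peak bonus when the tile overlaps a planted peak window (so
    mutation variants lose and insertion variants gain contributions
    automatically).  true_decay_rate grows with the soma-motif count.
    """
    rows = []
    for v in variants:
        lfc = 0.0
        n_soma = 0
        for motif, eff in config.effect_motifs.items():
            k = len(_find_all(v.variable_region, motif))
            lfc += k * eff
            if motif in config.soma_motifs:
                n_soma += k
        if v.gene_id in truth.peak_windows and v.tile_start is not None:
            t0, t1 = v.tile_start, v.tile_start + len(v.variable_region)
            for w0, w1 in truth.peak_windows[v.gene_id]:
                if t0 < w1 and w0 < t1:
                    lfc += config.focused_peak_effect
        decay = config.base_decay_rate + n_soma * config.decay_rate_per_soma_motif
        rows.append((v.variant_id, lfc, decay))
    return pd.DataFrame(
        rows, columns=["variant_id", "true_logfc_loc", "true_decay_rate"]
    ).set_index("variant_id")


# ---------------------------------------------------------------------------
# counts


def _nb_draw(mu: np.ndarray, phi: float, rng) -> np.ndarray:
    """NB with variance mu + phi*mu^2 (gamma-Poisson mixture); Poisson at
    phi = 0."""
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def simulate_counts(
    variants: list[OligoVariant],
    effects: pd.DataFrame,
    config: SimConfig,
    experiment: str = "localization",
    rng: np.random.Generator | None = None,
) -> UmiCountMatrix:
    """Draw the UMI count matrix for one experiment.

    Per variant i and sample s the NB mean is
    ``depth * a_i * f_is / sum_j a_j f_js`` with baseline abundance
    ``a_i = exp(N(log_mean, log_sd))`` and compartment factor
    ``f = 2^(+lfc/2)`` (neurite) / ``2^(-lfc/2)`` (soma), or decay factor
    ``f = exp(-rate * t)`` at shutoff timepoint t.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ids = [v.variant_id for v in variants]
    eff = effects.loc[ids]
    a = np.exp(
        rng.normal(
            config.baseline_abundance_log_mean,
            config.baseline_abundance_log_sd,
            size=len(ids),
        )
    )
    if experiment == "localization":
        lfc = eff.true_logfc_loc.to_numpy()
        sheet = []
        factors = []
        for comp, sign in (("neurite", +0.5), ("soma", -0.5)):
            for r in range(1, config.replicates_loc + 1):
                sheet.append((f"{comp}_{r}", comp, r))
                factors.append(2.0 ** (sign * lfc))
    elif experiment == "decay":
        rate = eff.true_decay_rate.to_numpy()
        sheet = []
        factors = []
        for t in config.decay_timepoints:
            cond = f"t{int(t)}"
            for r in range(1, config.replicates_decay + 1):
                sheet.append((f"{cond}_{r}", cond, r))
                factors.append(np.exp(-rate * t))
    else:
        raise ValueError(f"unknown experiment {experiment!r}")

    counts = np.empty((len(ids), len(sheet)), dtype=np.int64)
    for j, f in enumerate(factors):
        w = a * f
        mu = config.depth * w / w.sum()
        counts[:, j] = _nb_draw(mu, config.dispersion, rng)
    samples = pd.DataFrame(sheet, columns=["sample_id", "condition", "replicate"])
    cdf = pd.DataFrame(counts, index=pd.Index(ids, name="variant_id"),
                       columns=samples.sample_id)
    return UmiCountMatrix(cdf, samples)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    variants: list[OligoVariant],
    matrix: UmiCountMatrix,
    outdir,
    config: SimConfig | None = None,
    error_rate: float = 0.0,
    duplication: int = 1,
    read1_length: int = 30,
    read2_length: int = 84,
    compress: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Expand a count matrix into paired FASTQ files, one pair per sample.

    Each UMI of each variant yields ``duplication`` read pairs (PCR
    duplicates share the UMI).  Read 1 starts with the UMI, read 2 with the
    variant barcode followed by variable-region sequence.  Substitution
    errors are applied per base at ``error_rate``.
    """
    import pathlib

    config = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {v.variant_id: v for v in variants}
    ul = config.umi_length

    def maybe_err(seq: str) -> str:
        if error_rate <= 0:
            return seq
        s = list(seq)
        for k in np.nonzero(rng.random(len(s)) < error_rate)[0]:
            s[k] = BASES[(BASES.index(s[k]) + int(rng.integers(1, 4))) % 4]
        return "".join(s)

    files = {}
    for _, srow in matrix.samples.iterrows():
        sid = srow.sample_id
        suffix = ".fastq.gz" if compress else ".fastq"
        p1 = outdir / f"{sid}_R1{suffix}"
        p2 = outdir / f"{sid}_R2{suffix}"
        opener = _gzip.open if compress else open
        with opener(p1, "wt") as f1, opener(p2, "wt") as f2:
            ridx = 0
            for vid, n_umis in matrix.counts[sid].items():
                if n_umis == 0:
                    continue
                v = by_id[vid]
                seen: set[str] = set()
                while len(seen) < n_umis:
                    seen.add("".join(BASES[c] for c in rng.integers(0, 4, size=ul)))
                r2_tmpl = (v.barcode + v.variable_region)[:read2_length]
                for umi in sorted(seen):
                    r1_tmpl = (umi + "T" * read1_length)[:read1_length]
                    for _ in range(duplication):
                        ridx += 1
                        name = f"@{sid}:{ridx}"
                        r1, r2 = maybe_err(r1_tmpl), maybe_err(r2_tmpl)
                        f1.write(f"{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                        f2.write(f"{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
        files[sid] = (str(p1), str(p2))
    return files


# ---------------------------------------------------------------------------
# convenience bundles


@dataclass
class Simulation:
    """A complete simulated study: genes, truth, design and count matrices."""

    config: SimConfig
    design_config: DesignConfig
    genes: list[GeneUtr]
    truth: GroundTruth
    variants: list[OligoVariant]
    effects: pd.DataFrame
    localization: UmiCountMatrix
    decay: UmiCountMatrix | None = None


def simulate_study(
    config: SimConfig,
    design_config: DesignConfig | None = None,
    alteration_plan: list[AlterationSpec] | None = None,
    with_decay: bool = False,
) -> Simulation:
    """Run gene simulation -> library design -> truth -> counts end to end."""
    design_config = design_config or DesignConfig(seed=config.seed)
    genes, truth = simulate_genes(config, design_config)
    plan = alteration_plan or [AlterationSpec(kind="wildtype", n_barcodes=config.n_barcodes)]
    variants = build_design(genes, plan, design_config)
    effects = true_effects(variants, truth, config)
    rng = np.random.default_rng(config.seed + 1)
    loc = simulate_counts(variants, effects, config, "localization", rng)
    dec = simulate_counts(variants, effects, config, "decay", rng) if with_decay else None
    return Simulation(config, design_config, genes, truth, variants, effects, loc, dec)


def write_ground_truth(truth: GroundTruth, effects: pd.DataFrame, path) -> None:
    eff = effects.reset_index()
    eff.to_csv(path, sep="\t", index=False)
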