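"""Rational design of a tiled 3'UTR reporter library.

Each reporter oligo is a constant-length (198 nt) construct: an 18-nt forward
primer, a 12-nt variant-identifying barcode, a 150-nt variable region taken
from (or derived from) a native 3'UTR, and an 18-nt reverse primer.  3'UTRs
are tiled with 150-nt windows every 50 nt starting at the first base after the
stop codon; tiles containing a polyadenylation signal are excluded so the
reporter is not cleaved internally.  Variable regions may carry alterations:
all occurrences of a motif replaced by random sequence ("mutation"), motif
copies substituted in at fixed offsets ("insertion", optionally embedded in a
9-bp hairpin), or multi-barcode control groups sharing one variable region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")

# M13 universal primers, 18 nt each; free of PAS motifs and default sites.
DEFAULT_FWD_PRIMER = "GTAAAACGACGGCCAGTG"
DEFAULT_REV_PRIMER = "CAGGAAACAGCTATGACC"

#: 9-nt GC-balanced hairpin arm; the payload is arm + motif + revcomp(arm).
HAIRPIN_ARM = "GCACGTGGC"

DEFAULT_PAS_MOTIFS = ("AATAAA", "ATTAAA")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not seq or set(seq) - set(BASES):
        raise ValueError(f"{what} must be non-empty A/C/G/T, got {seq!r}")


@dataclass(frozen=True)
class GeneUtr:
    """A 3'UTR on the sense strand; position 0 is the first base after the
    stop codon."""

    gene_id: str
    sequence: str
    group_label: str = ""

    def __post_init__(self):
        _check_dna(self.sequence, f"UTR of {self.gene_id}")


@dataclass(frozen=True)
class DesignConfig:
    tile_length: int = 150
    step: int = 50
    barcode_length: int = 12
    min_barcode_distance: int = 3
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    forbidden_sites: tuple[str, ...] = ()
    pas_motifs: tuple[str, ...] = DEFAULT_PAS_MOTIFS
    oligo_length: int = 198
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "forbidden_sites", tuple(self.forbidden_sites))
        object.__setattr__(self, "pas_motifs", tuple(self.pas_motifs))
        expected = (
            len(self.fwd_primer)
            + self.barcode_length
            + self.tile_length
            + len(self.rev_primer)
        )
        if self.oligo_length != expected:
            raise ValueError(
                f"oligo_length {self.oligo_length} != primers+barcode+tile {expected}"
            )
        if self.min_barcode_distance < 1:
            raise ValueError("min_barcode_distance must be >= 1")

    @classmethod
    def from_json(cls, path) -> "DesignConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class Alteration:
    """What was done to a wild-type tile to produce this variant."""

    kind: str = "wildtype"  # wildtype | motif_mutation | motif_insertion |
    #                         synthetic_insertion | barcode_control | barcode_only
    motif: str | None = None
    positions: tuple[int, ...] = ()
    copies: int = 0
    hairpin: bool = False

    KINDS = (
        "wildtype",
        "motif_mutation",
        "motif_insertion",
        "synthetic_insertion",
        "barcode_control",
        "barcode_only",
    )

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(self.positions))
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown alteration kind {self.kind!r}")


@dataclass(frozen=True)
class OligoVariant:
    variant_id: str
    barcode: str
    variable_region: str
    gene_id: str | None = None
    tile_start: int | None = None
    alteration: Alteration = field(default_factory=Alteration)


# ---------------------------------------------------------------------------
# tiling


def tile_utr(utr: GeneUtr, config: DesignConfig) -> list[tuple[int, str]]:
    """Tile a 3'UTR with ``tile_length`` windows every ``step`` nt.

    Windows are 0-based half-open ``[start, start + tile_length)``; any window
    containing a polyadenylation signal is dropped.  Returns ``(start, seq)``
    pairs in ascending start order; empty when the UTR is shorter than a tile.
    """
    L, tl = len(utr.sequence), config.tile_length
    out = []
    for start in range(0, L - tl + 1, config.step):
        tile = utr.sequence[start : start + tl]
        if any(p in tile for p in config.pas_motifs):
            continue
        out.append((start, tile))
    return out


# ---------------------------------------------------------------------------
# barcodes


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_hamming(barcodes: list[str]) -> int:
    """Brute-force all-pairs minimum Hamming distance (vectorized)."""
    if len(barcodes) < 2:
        raise ValueError("need >= 2 barcodes")
    arr = np.array([list(b) for b in barcodes], dtype="U1").view(np.uint32)
    arr = arr.reshape(len(barcodes), -1)
    best = arr.shape[1]
    for i in range(len(barcodes) - 1):
        d = (arr[i + 1 :] != arr[i]).sum(axis=1).min()
        best = min(best, int(d))
        if best == 0:
            break
    return best


def design_barcodes(
    n: int,
    config: DesignConfig | None = None,
    rng: np.random.Generator | None = None,
    max_attempts_per_barcode: int = 10_000,
) -> list[str]:
    """Draw ``n`` barcodes whose pairwise Hamming distance is at least
    ``min_barcode_distance``.

    Greedy rejection sampling: candidates are drawn uniformly and accepted if
    they avoid forbidden/PAS subsequences and keep their distance from every
    accepted barcode.  Deterministic given the config seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or DesignConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bl, dmin = config.barcode_length, config.min_barcode_distance
    avoid = tuple(config.forbidden_sites) + tuple(config.pas_motifs)

    accepted: list[str] = []
    acc_mat = np.empty((n, bl), dtype=np.uint8)
    attempts = 0
    budget = n * max_attempts_per_barcode
    while len(accepted) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"barcode capacity exceeded: {len(accepted)}/{n} after {attempts} draws"
            )
        attempts += 1
        codes = rng.integers(0, 4, size=bl, dtype=np.uint8)
        bc = "".join(BASES[c] for c in codes)
        if any(s in bc for s in avoid):
            continue
        k = len(accepted)
        if k and int((acc_mat[:k] != codes).sum(axis=1).min()) < dmin:
            continue
        acc_mat[k] = codes
        accepted.append(bc)
    return accepted


# ---------------------------------------------------------------------------
# sequence alterations


def _find_all(seq: str, motif: str) -> list[int]:
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def mutate_motif(
    tile_sequence: str,
    motif: str,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> str:
    """Replace every occurrence of ``motif`` with random sequence.

    Length-preserving; replacement bases are re-drawn if any motif occurrence
    survives or is re-created at a junction.  Raises if the motif is absent.
    """
    _check_dna(motif, "motif")
    hits = _find_all(tile_sequence, motif)
    if not hits:
        raise ValueError(f"motif not found: {motif}")
    # non-overlapping cover of every hit position
    covered: set[int] = set()
    for h in hits:
        covered.update(range(h, h + len(motif)))
    positions = sorted(covered)
    seq = list(tile_sequence)
    for _ in range(max_attempts):
        for p in positions:
            seq[p] = BASES[rng.integers(0, 4)]
        cand = "".join(seq)
        if motif not in cand:
            return cand
    raise RuntimeError(f"could not erase motif {motif} in {max_attempts} attempts")


def insert_motif(
    tile_sequence: str,
    motif: str,
    positions: list[int],
    hairpin: bool = False,
) -> str:
    """Substitute motif payloads into a tile at fixed offsets.

    The payload replaces the native bases at ``[p, p + len(payload))`` so the
    tile length is unchanged.  With ``hairpin=True`` the payload is
    ``HAIRPIN_ARM + motif + revcomp(HAIRPIN_ARM)``, folding the motif into the
    loop of a 9-bp stem.
    """
    if not positions:
        return tile_sequence
    _check_dna(motif, "motif")
    payload = HAIRPIN_ARM + motif + reverse_complement(HAIRPIN_ARM) if hairpin else motif
    intervals = sorted((p, p + len(payload)) for p in positions)
    prev_end = -1
    for s, e in intervals:
        if s < 0 or e > len(tile_sequence):
            raise ValueError(f"payload [{s},{e}) runs past tile end {len(tile_sequence)}")
        if s < prev_end:
            raise ValueError(f"overlapping payloads at {s}")
        prev_end = e
    seq = list(tile_sequence)
    for s, e in intervals:
        seq[s:e] = payload
    return "".join(seq)


def assemble_oligo(variant: OligoVariant, config: DesignConfig) -> str:
    """fwd_primer + barcode + variable_region + rev_primer, constraint-checked."""
    if len(variant.barcode) != config.barcode_length:
        raise ValueError(f"{variant.variant_id}: barcode length != {config.barcode_length}")
    if len(variant.variable_region) != config.tile_length:
        raise ValueError(
            f"{variant.variant_id}: variable region length != {config.tile_length}"
        )
    oligo = config.fwd_primer + variant.barcode + variant.variable_region + config.rev_primer
    assert len(oligo) == config.oligo_length
    for site in config.forbidden_sites:
        off = oligo.find(site)
        if off != -1:
            raise ValueError(
                f"{variant.variant_id}: forbidden site {site} at offset {off}"
            )
    return oligo


# ---------------------------------------------------------------------------
# full design assembly


@dataclass(frozen=True)
class AlterationSpec:
    """One row of the alteration plan applied on top of the wild-type tiling.

    ``gene_ids``/``tile_starts`` restrict which tiles are altered (None = all
    eligible); ``n_barcodes`` > 1 creates a multi-barcode group (same variable
    region, different barcodes).
    """

    kind: str = "wildtype"
    motif: str | None = None
    positions: tuple[int, ...] = ()
    copies: int = 0
    hairpin: bool = False
    gene_ids: tuple[str, ...] | None = None
    tile_starts: tuple[int, ...] | None = None
    n_barcodes: int = 1

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(self.positions))
        if self.gene_ids is not None:
            object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if self.tile_starts is not None:
            object.__setattr__(self, "tile_starts", tuple(self.tile_starts))

    @staticmethod
    def plan_from_json(path) -> list["AlterationSpec"]:
        with open(path) as fh:
            return [AlterationSpec(**row) for row in json.load(fh)]


def build_design(
    genes: list[GeneUtr],
    alteration_plan: list[AlterationSpec],
    config: DesignConfig,
) -> list[OligoVariant]:
    """Expand genes x alterations x barcode replicates into a design table.

    Wild-type tiles are produced by ``tile_utr``; each plan row derives
    altered variants from the targeted wild-type tiles.  Barcodes are drawn
    once for the whole design so the distance guarantee holds globally.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []  # pending variants without barcodes
    for utr in genes:
        tiles = tile_utr(utr, config)
        for spec in alteration_plan:
            if spec.gene_ids is not None and utr.gene_id not in spec.gene_ids:
                continue
            for start, tile in tiles:
                if spec.tile_starts is not None and start not in spec.tile_starts:
                    continue
                if spec.kind == "wildtype":
                    var_seq, alt = tile, Alteration()
                elif spec.kind == "barcode_control":
                    var_seq = tile
                    alt = Alteration(kind="barcode_control")
                elif spec.kind == "motif_mutation":
                    if spec.motif not in tile:
                        continue
                    var_seq = mutate_motif(tile, spec.motif, rng)
                    alt = Alteration(kind="motif_mutation", motif=spec.motif)
                elif spec.kind in ("motif_insertion", "synthetic_insertion"):
                    copies = spec.copies or len(spec.positions)
                    pos = spec.positions[:copies]
                    var_seq = insert_motif(tile, spec.motif, list(pos), spec.hairpin)
                    alt = Alteration(
                        kind=spec.kind,
                        motif=spec.motif,
                        positions=pos,
                        copies=len(pos),
                        hairpin=spec.hairpin,
                    )
                else:
                    raise ValueError(f"unsupported plan kind {spec.kind!r}")
                for rep in range(max(1, spec.n_barcodes)):
                    rows.append(
                        dict(
                            gene_id=utr.gene_id,
                            tile_start=start,
                            variable_region=var_seq,
                            alteration=alt,
                            bc_rep=rep,
                        )
                    )
    if not rows:
        return []
    barcodes = design_barcodes(len(rows), config, rng=rng)
    variants = []
    for i, (row, bc) in enumerate(zip(rows, barcodes)):
        alt = row["alteration"]
        tag = alt.kind if alt.kind != "wildtype" else "wt"
        vid = f"{row['gene_id']}:{row['tile_start']}:{tag}:{i}"
        v = OligoVariant(
            variant_id=vid,
            barcode=bc,
            variable_region=row["variable_region"],
            gene_id=row["gene_id"],
            tile_start=row["tile_start"],
            alteration=alt,
        )
        assemble_oligo(v, config)  # constraint check
        variants.append(v)
    return variants


# ---------------------------------------------------------------------------
# I/O

DESIGN_COLUMNS = [
    "variant_id",
    "barcode",
    "gene_id",
    "tile_start",
    "alteration_kind",
    "motif",
    "positions",
    "copies",
    "hairpin",
    "variable_region",
    "full_oligo",
]


def design_to_frame(variants: list[OligoVariant], config: DesignConfig):
    import pandas as pd

    rec = []
    for v in variants:
        a = v.alteration
        rec.append(
            dict(
                variant_id=v.variant_id,
                barcode=v.barcode,
                gene_id=v.gene_id,
                tile_start=v.tile_start,
                alteration_kind=a.kind,
                motif=a.motif or "",
                positions=",".join(map(str, a.positions)),
                copies=a.copies,
                hairpin=a.hairpin,
                variable_region=v.variable_region,
                full_oligo=assemble_oligo(v, config),
            )
        )
    import pandas as pd  # noqa: F811

    return pd.DataFrame(rec, columns=DESIGN_COLUMNS)


def write_design(variants, config, tsv_path, fasta_path=None) -> None:
    df = design_to_frame(variants, config)
    df.to_csv(tsv_path, sep="\t", index=False)
    if fasta_path:
        with open(fasta_path, "w") as fh:
            for _, r in df.iterrows():
                fh.write(f">{r.variant_id}\n{r.full_oligo}\n")


def read_design(tsv_path) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False, dtype={"motif": str})
    return df


def variants_from_frame(df) -> list[OligoVariant]:
    out = []
    for _, r in df.iterrows():
        pos = tuple(int(x) for x in str(r.positions).split(",") if x != "")
        hp = r.hairpin in (True, "True", "true", 1, "1")
        out.append(
            OligoVariant(
                variant_id=r.variant_id,
                barcode=r.barcode,
                variable_region=r.variable_region,
                gene_id=r.gene_id or None,
                tile_start=None if r.tile_start == "" else int(r.tile_start),
                alteration=Alteration(
                    kind=r.alteration_kind,
                    motif=r.motif or None,
                    positions=pos,
                    copies=int(r.copies),
                    hairpin=hp,
                ),
            )
        )
    return out


def read_utrs_fasta(path, group_label: str = "") -> list[GeneUtr]:
    return [
        GeneUtr(rec.id, str(rec.seq).upper(), group_label)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_utrs_fasta(utrs: list[GeneUtr], path) -> None:
    with open(path, "w") as fh:
        for u in utrs:
            fh.write(f">{u.gene_id}\n{u.sequence}\n")
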