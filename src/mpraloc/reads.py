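"""Paired FASTQ -> deduplicated UMI count matrix.

Read 2 carries the 12-nt variant barcode at its 5' end and is used to assign
each read pair to a library variant; reads that cannot be assigned (or that
match two design barcodes equally well) are discarded and tallied.  Read 1
carries a 15-nt UMI at its 5' end; the per-(variant, sample) count is the
number of distinct UMIs, which collapses PCR duplicates.
"""

from __future__ import annotations

import gzip
import json
from itertools import product

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import UmiCountMatrix


def _open_maybe_gz(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


class BarcodeIndex:
    """Exact or near-exact (<= max_mismatch) barcode lookup.

    For mismatch tolerance 1 the index enumerates all single-substitution
    neighbours of each design barcode; a neighbour claimed by two barcodes is
    marked ambiguous.  Exact matches always win.
    """

    def __init__(self, barcodes: list[str], max_mismatch: int = 1):
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("design barcodes are not unique")
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        self.length = len(barcodes[0])
        if any(len(b) != self.length for b in barcodes):
            raise ValueError("barcodes differ in length")
        self.max_mismatch = max_mismatch
        self.exact = {b: i for i, b in enumerate(barcodes)}
        self.near: dict[str, int] = {}
        self.AMBIGUOUS = -2
        if max_mismatch == 1:
            for i, b in enumerate(barcodes):
                for pos, alt in product(range(self.length), "ACGT"):
                    if alt == b[pos]:
                        continue
                    nb = b[:pos] + alt + b[pos + 1 :]
                    if nb in self.exact:
                        continue
                    if nb in self.near and self.near[nb] != i:
                        self.near[nb] = self.AMBIGUOUS
                    else:
                        self.near[nb] = i

    def lookup(self, seq: str) -> int:
        """Variant index, -1 if unassignable, -2 if ambiguous."""
        hit = self.exact.get(seq)
        if hit is not None:
            return hit
        if self.max_mismatch == 1:
            return self.near.get(seq, -1)
        return -1


def count_sample(
    fastq_r1,
    fastq_r2,
    index: BarcodeIndex,
    n_variants: int,
    umi_length: int = 15,
) -> tuple[np.ndarray, dict]:
    """Distinct-UMI counts per variant for one sample's read pair files."""
    umis: list[set[str]] = [set() for _ in range(n_variants)]
    stats = {"total": 0, "assigned": 0, "discarded": 0, "ambiguous": 0}
    with _open_maybe_gz(fastq_r1) as h1, _open_maybe_gz(fastq_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError("R1/R2 read count mismatch") from None
            stats["total"] += 1
            hit = index.lookup(rec2[1][: index.length])
            if hit == index.AMBIGUOUS:
                stats["ambiguous"] += 1
                stats["discarded"] += 1
                continue
            if hit < 0:
                stats["discarded"] += 1
                continue
            umis[hit].add(rec1[1][:umi_length])
            stats["assigned"] += 1
        if next(it2, None) is not None:
            raise ValueError("R1/R2 read count mismatch")
    return np.array([len(s) for s in umis], dtype=np.int64), stats


def assign_reads(
    fastq_pairs: dict,
    design: pd.DataFrame,
    samples: pd.DataFrame,
    umi_length: int = 15,
    max_mismatch: int = 1,
) -> tuple[UmiCountMatrix, dict]:
    """Build the UMI count matrix from one FASTQ pair per sample.

    ``fastq_pairs`` maps sample_id -> (r1_path, r2_path); ``design`` is the
    design table (variant_id, barcode); ``samples`` the sample sheet.
    Returns the matrix plus per-sample assignment statistics.
    """
    barcodes = list(design.barcode)
    index = BarcodeIndex(barcodes, max_mismatch=max_mismatch)
    counts = {}
    stats = {}
    for sid in samples.sample_id:
        r1, r2 = fastq_pairs[sid]
        counts[sid], stats[sid] = count_sample(r1, r2, index, len(barcodes), umi_length)
    cdf = pd.DataFrame(counts, index=pd.Index(design.variant_id, name="variant_id"))
    cdf = cdf[list(samples.sample_id)]
    return UmiCountMatrix(cdf, samples), stats


def write_stats(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=1)
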