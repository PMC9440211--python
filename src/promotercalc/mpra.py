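"""Barcoded measurement processing: from raw reads to transcription rates.

Each promoter variant carries a unique 20-nt barcode.  DNA-Seq counts how
many template molecules carry each variant (barcode must match exactly and
the linked promoter must match its reference exactly); RNA-Seq counts
transcript-derived barcodes (one substitution/indel tolerated).  The
relative transcription rate of variant *i* in replicate *j* is the
depth-normalized count ratio

    r_ij = (RNA_ij / DNA_ij) * (sum_i DNA_ij / sum_i RNA_ij),

whose DNA-weighted mean over the included variants of a replicate is 1 by
construction.  TSS-mapping reads locate each transcript's first base by
anchoring on a constant flanking sequence and requiring a unique, perfect
match of the adjacent transcript sequence in the variant's reference.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .training import PromoterDataset

__all__ = [
    "BarcodeSet",
    "CountTable",
    "TSSReadMap",
    "hamming",
    "design_barcodes",
    "count_barcodes",
    "relative_tx_rates",
    "map_tss_reads",
    "filter_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeSet:
    """Fixed-length DNA barcodes with a guaranteed minimum pairwise distance."""

    barcodes: tuple[str, ...]
    length: int
    min_hamming: int
    blocklist: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(len(b) != self.length for b in self.barcodes):
            raise ValueError("all barcodes must share the declared length")

    def __len__(self) -> int:
        return len(self.barcodes)

    def min_pairwise_hamming(self) -> int:
        """Exhaustive minimum pairwise Hamming distance over the set."""
        arr = np.frombuffer("".join(self.barcodes).encode(), dtype=np.uint8).reshape(
            len(self.barcodes), self.length
        )
        best = self.length
        for i in range(len(arr) - 1):
            d = (arr[i + 1 :] != arr[i]).sum(axis=1).min()
            best = min(best, int(d))
            if best == 0:
                break
        return best


def design_barcodes(
    n: int,
    length: int = 20,
    min_hamming: int = 2,
    blocklist: Sequence[str] = (),
    seed: int = 0,
    attempts_per_barcode: int = 200,
) -> BarcodeSet:
    """Greedy-with-rejection barcode design.

    Draws random sequences and accepts each only if its Hamming distance to
    every accepted barcode is at least ``min_hamming`` and it contains no
    blocklisted k-mer.  Seed-deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    # crude packing feasibility: distance >= 2 forbids duplicates and near-twins
    if n > 4 ** (length - 1):
        raise ValueError(f"{n} barcodes of length {length} at distance {min_hamming} infeasible")
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    budget = n * attempts_per_barcode
    blocked = tuple(blocklist)
    while count < n:
        if budget <= 0:
            raise RuntimeError(f"barcode design exhausted attempts at {count}/{n}")
        budget -= 1
        cand = _BASES[rng.integers(0, 4, size=length)]
        seq = cand.tobytes().decode()
        if any(k in seq for k in blocked):
            continue
        if count and int((accepted[:count] != cand).sum(axis=1).min()) < min_hamming:
            continue
        accepted[count] = cand
        count += 1
    barcodes = tuple(accepted[i].tobytes().decode() for i in range(n))
    return BarcodeSet(barcodes=barcodes, length=length, min_hamming=min_hamming, blocklist=blocked)


@dataclass
class CountTable:
    """Per-variant, per-replicate RNA and DNA barcode counts.

    Both frames are indexed by variant id with one column per replicate;
    counts are non-negative integers.
    """

    rna: pd.DataFrame
    dna: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.rna.index.equals(self.dna.index):
            raise ValueError("RNA and DNA tables must share the variant index")
        for frame in (self.rna, self.dna):
            if (frame.to_numpy() < 0).any():
                raise ValueError("counts must be non-negative")

    def totals(self) -> pd.DataFrame:
        return pd.DataFrame({"rna": self.rna.sum(), "dna": self.dna.sum()})


def count_barcodes(
    reads: Iterable[str],
    barcode_set: BarcodeSet,
    mode: str,
    promoter_refs: Mapping[str, str] | None = None,
    barcode_start: int = 0,
) -> tuple[pd.Series, dict[str, int]]:
    """Assign reads to barcodes; returns (counts per barcode, audit).

    RNA mode: a read is counted for the unique barcode within edit distance
    (Levenshtein) <= 1 of its barcode field; ambiguous or unmatched reads
    are discarded.  DNA mode: the barcode must match exactly and the
    remainder of the read must match the barcode's promoter reference
    exactly.  Every read is classified exactly once.
    """
    if mode not in ("rna", "dna"):
        raise ValueError("mode must be 'rna' or 'dna'")
    if mode == "dna" and promoter_refs is None:
        raise ValueError("DNA mode requires promoter references")
    exact = {b: b for b in barcode_set.barcodes}
    length = barcode_set.length
    counts: Counter[str] = Counter()
    audit = Counter(counted=0, unmatched=0, ambiguous=0, promoter_mismatch=0, too_short=0)
    for read in reads:
        if len(read) < barcode_start + length:
            audit["too_short"] += 1
            continue
        field_ = read[barcode_start : barcode_start + length]
        bc = exact.get(field_)
        if mode == "dna":
            if bc is None:
                audit["unmatched"] += 1
                continue
            ref = promoter_refs.get(bc, "")
            body = read[barcode_start + length :]
            if body[: len(ref)] != ref:
                audit["promoter_mismatch"] += 1
                continue
            counts[bc] += 1
            audit["counted"] += 1
            continue
        # RNA mode: tolerate one edit
        if bc is None:
            hits = [
                b
                for b in barcode_set.barcodes
                if edlib.align(field_, b, task="distance", k=1)["editDistance"] != -1
            ]
            if len(hits) == 1:
                bc = hits[0]
            elif len(hits) > 1:
                audit["ambiguous"] += 1
                continue
            else:
                audit["unmatched"] += 1
                continue
        counts[bc] += 1
        audit["counted"] += 1
    series = pd.Series(
        {b: counts.get(b, 0) for b in barcode_set.barcodes}, name=mode, dtype=int
    )
    return series, dict(audit)


def relative_tx_rates(table: CountTable) -> pd.DataFrame:
    """Depth-normalized count-ratio rates with replicate mean/SD/CV.

    Variants with a zero DNA count in a replicate are excluded from that
    replicate (NaN) and from its normalization totals.  Returns a frame
    with one ``r_<rep>`` column per replicate plus ``tx_mean``, ``tx_sd``
    and ``tx_cv`` over the replicates.
    """
    rna = table.rna.to_numpy(dtype=float)
    dna = table.dna.to_numpy(dtype=float)
    r = np.full_like(rna, np.nan)
    for j in range(rna.shape[1]):
        included = dna[:, j] > 0
        dna_total = dna[included, j].sum()
        rna_total = rna[included, j].sum()
        if rna_total == 0:
            warnings.warn(f"replicate {j} has zero RNA counts among included variants")
            continue
        r[included, j] = rna[included, j] / dna[included, j] * dna_total / rna_total
    out = pd.DataFrame(
        r,
        index=table.rna.index,
        columns=[f"r_{c}" for c in table.rna.columns],
    )
    out["tx_mean"] = np.nanmean(r, axis=1)
    out["tx_sd"] = np.nanstd(r, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["tx_cv"] = out["tx_sd"] / out["tx_mean"]
    return out


@dataclass
class TSSReadMap:
    """Per-variant TSS read histograms with predominance statistics."""

    counts: dict[str, dict[int, int]]
    audit: dict[str, int] = field(default_factory=dict)

    def predominant(self, variant: str) -> tuple[int | None, float]:
        """(predominant TSS, ratio of top count to runner-up count).

        The ratio is ``inf`` when there is a single observed start.
        """
        hist = self.counts.get(variant, {})
        if not hist:
            return None, 0.0
        ranked = sorted(hist.items(), key=lambda kv: (-kv[1], kv[0]))
        top_pos, top_n = ranked[0]
        if len(ranked) == 1:
            return top_pos, float("inf")
        return top_pos, top_n / ranked[1][1]


def _unique_exact_start(fragment: str, reference: str) -> int | None:
    """Start index if ``fragment`` occurs exactly once in ``reference``."""
    first = reference.find(fragment)
    if first == -1:
        return None
    if reference.find(fragment, first + 1) != -1:
        return None
    return first


def map_tss_reads(
    reads: Iterable[str],
    anchor: str,
    barcode_to_variant: Mapping[str, str],
    references: Mapping[str, str],
    barcode_start: int = 0,
    barcode_length: int = 20,
    fragment_length: int = 20,
) -> TSSReadMap:
    """Map transcript 5' ends onto their reference promoters.

    Each read carries a barcode, the constant flank ``anchor`` and the
    transcript-adjacent sequence.  A TSS is recorded only when the
    extracted fragment perfectly matches the reference at exactly one start
    location; anything else is discarded with a reason code.
    """
    counts: dict[str, dict[int, int]] = {}
    audit = Counter(
        counted=0, no_barcode=0, no_anchor=0, mismatch_or_multi=0, too_short=0
    )
    for read in reads:
        if len(read) < barcode_start + barcode_length + len(anchor):
            audit["too_short"] += 1
            continue
        bc = read[barcode_start : barcode_start + barcode_length]
        variant = barcode_to_variant.get(bc)
        if variant is None:
            audit["no_barcode"] += 1
            continue
        pos = read.find(anchor, barcode_start + barcode_length)
        if pos == -1:
            audit["no_anchor"] += 1
            continue
        fragment = read[pos + len(anchor) : pos + len(anchor) + fragment_length]
        start = _unique_exact_start(fragment, references[variant]) if fragment else None
        if start is None:
            audit["mismatch_or_multi"] += 1
            continue
        counts.setdefault(variant, {})
        counts[variant][start] = counts[variant].get(start, 0) + 1
        audit["counted"] += 1
    return TSSReadMap(counts=counts, audit=dict(audit))


def filter_dataset(
    dataset: PromoterDataset,
    mode: str,
    table: CountTable | None = None,
    tss_map: TSSReadMap | None = None,
    min_counts: int = 50,
    counts_per_replicate: bool = True,
    predominance_ratio: float = 2.0,
    tss_window: int = 5,
    cv_max: float = 0.40,
) -> tuple[PromoterDataset, pd.DataFrame]:
    """Apply the training-set or high-precision filters; returns audit too.

    ``single_tss`` mode intersects three criteria: (i) at least
    ``min_counts`` RNA and DNA counts (per replicate by default, summed
    across replicates when ``counts_per_replicate=False``); (ii) one
    predominant TSS with at least ``predominance_ratio`` times the counts
    of the runner-up; (iii) the predominant TSS within ``tss_window`` bp of
    the anticipated TSS (a 10-bp-wide symmetric window by default; pass 10
    for the wider reading).  ``high_precision`` mode keeps variants with
    replicate CV strictly below ``cv_max``.
    """
    rec = dataset.records
    ids = rec["id"].astype(str).tolist()
    audit = pd.DataFrame(index=ids)
    if mode == "high_precision":
        if "tx_cv" not in rec.columns:
            raise ValueError("high_precision mode requires a tx_cv column")
        audit["pass_cv"] = (rec["tx_cv"] < cv_max).to_numpy()
        audit["pass"] = audit["pass_cv"]
    elif mode == "single_tss":
        if table is None or tss_map is None:
            raise ValueError("single_tss mode requires a count table and a TSS read map")
        rna = table.rna.reindex(ids).fillna(0)
        dna = table.dna.reindex(ids).fillna(0)
        if counts_per_replicate:
            ok_counts = (rna.min(axis=1) >= min_counts) & (dna.min(axis=1) >= min_counts)
        else:
            ok_counts = (rna.sum(axis=1) >= min_counts) & (dna.sum(axis=1) >= min_counts)
        audit["pass_counts"] = ok_counts.to_numpy()
        pred_ok, window_ok = [], []
        anticipated = dict(zip(ids, rec["tss"].astype(int)))
        for vid in ids:
            pos, ratio = tss_map.predominant(vid)
            pred_ok.append(pos is not None and ratio >= predominance_ratio)
            window_ok.append(pos is not None and abs(pos - anticipated[vid]) <= tss_window)
        audit["pass_predominance"] = pred_ok
        audit["pass_window"] = window_ok
        audit["pass"] = audit.all(axis=1)
    else:
        raise ValueError("mode must be 'single_tss' or 'high_precision'")
    kept = dataset.subset(audit["pass"].to_numpy())
    return kept, audit
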