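"""Synthetic ground truths, promoter datasets and raw-ish reads.

Everything downstream of the wet lab can be exercised without external
data: a ground-truth energy model is drawn from block-wise Gaussian
distributions (optionally forcing the canonical motifs to be strictly
minimal in their blocks), promoter variants are assembled from the
configuration grammar the measurement library uses (consensus-anchored
hexamers, spacer 15-20 bp, discriminator 5-10 nt, random UP and ITR),
replicate rates follow ``ln TX = -dG_true + N(0, sigma)``, and barcoded
RNA/DNA/TSS reads are sampled multinomially so per-replicate totals are
fixed -- matching the depth-normalization structure of the rate estimator.

The generator emulates the statistical structure of barcoded in vitro
measurements, not sequencing realism: base-call errors are uniform
substitutions and there are no quality scores beyond a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .energy_model import (
    FEATURE_NAMES,
    NUMERIC_FEATURES,
    CompiledModel,
    EnergyModelParams,
    default_normalizers,
    parse_configuration,
)
from .mpra import BarcodeSet
from .shape import ShapeTables, load_default_tables
from .training import CATEGORICAL_BLOCKS, PromoterDataset

__all__ = [
    "GroundTruthConfig",
    "SimulatedReads",
    "simulate_ground_truth",
    "simulate_dataset",
    "simulate_reads",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CANONICAL_FEATURES = (
    "hex35_1_TTG",
    "hex35_2_ACA",
    "hex10_1_TAT",
    "hex10_2_AAT",
    "ext10_TG",
    "spacer_len_17",
)


@dataclass(frozen=True)
class GroundTruthConfig:
    """Distributional knobs for sampled ground-truth energies (RT units)."""

    sigma_hexamer: float = 0.6
    sigma_disc: float = 0.3
    sigma_ext10: float = 0.3
    sigma_spacer: float = 0.3
    sigma_numeric: float = 1.0
    canonical: bool = True
    canonical_margin: float = 0.5

    def block_sigma(self, block: str) -> float:
        if block.startswith(("hex35", "hex10")):
            return self.sigma_hexamer
        if block == "disc":
            return self.sigma_disc
        if block == "ext10":
            return self.sigma_ext10
        return self.sigma_spacer


def simulate_ground_truth(
    config: GroundTruthConfig | None = None,
    seed: int = 0,
    tables: ShapeTables | None = None,
) -> EnergyModelParams:
    """Draw a seed-deterministic ground-truth parameter set.

    Categorical energies are Gaussian within each block and centered to
    block mean zero; numeric-feature energies are Gaussian.  With
    ``canonical=True`` the consensus features (TTGACA / TATAAT 3-mers, TG,
    17-bp spacer) are pushed ``canonical_margin`` RT below their block
    minimum, making them strictly minimal.
    """
    config = config or GroundTruthConfig()
    tables = tables or load_default_tables()
    rng = np.random.default_rng(seed)
    coeffs = {n: 0.0 for n in FEATURE_NAMES}
    for block, names in CATEGORICAL_BLOCKS.items():
        draws = rng.normal(0.0, config.block_sigma(block), size=len(names))
        draws -= draws.mean()
        for n, v in zip(names, draws):
            coeffs[n] = float(v)
    for n in NUMERIC_FEATURES:
        coeffs[n] = float(rng.normal(0.0, config.sigma_numeric))
    if config.canonical:
        for target in CANONICAL_FEATURES:
            block = next(
                names for names in CATEGORICAL_BLOCKS.values() if target in names
            )
            floor = min(coeffs[n] for n in block)
            coeffs[target] = floor - config.canonical_margin
    return EnergyModelParams(
        coefficients=coeffs,
        normalizers=default_normalizers(tables),
        tables_checksum=tables.checksum(),
    )


def _rand(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _random_promoter(rng: np.random.Generator) -> tuple[str, int, int, int]:
    """One library-style promoter: at least one consensus hexamer anchor."""
    spacer_len = int(rng.integers(15, 21))
    disc_len = int(rng.integers(5, 11))
    which = rng.random()
    if which < 0.45:
        hex35, hex10 = "TTGACA", _rand(rng, 6)
    elif which < 0.9:
        hex35, hex10 = _rand(rng, 6), "TATAAT"
    else:
        hex35, hex10 = _rand(rng, 6), _rand(rng, 6)
    up = _rand(rng, 20)
    spacer = _rand(rng, spacer_len)
    disc = _rand(rng, disc_len)
    itr = _rand(rng, 20)
    seq = up + hex35 + spacer + hex10 + disc + itr
    tss = 32 + spacer_len + disc_len
    return seq, tss, spacer_len, disc_len


def simulate_dataset(
    truth: EnergyModelParams,
    n: int,
    seed: int = 0,
    noise_sigma: float = 0.3,
    n_reps: int = 3,
    tables: ShapeTables | None = None,
    test_fraction: float = 0.1,
) -> PromoterDataset:
    """Sample a measured promoter dataset from a ground-truth model.

    Each record is a randomly assembled promoter whose true binding
    configuration is annotated (``spacer_length``/``disc_length``);
    replicate rates are ``exp(-dG_true + N(0, noise_sigma))`` so the
    log-rates carry additive Gaussian measurement noise.  A seed-determined
    train/test split is attached.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    tables = tables or load_default_tables()
    compiled = CompiledModel(truth, tables)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        seq, tss, spacer_len, disc_len = _random_promoter(rng)
        config = parse_configuration(seq, tss, spacer_length=spacer_len, disc_length=disc_len)
        dg = compiled.breakdown(config).dg_total
        reps = np.exp(-dg + rng.normal(0.0, noise_sigma, size=n_reps))
        row = {
            "id": f"syn{i:05d}",
            "sequence": seq,
            "tss": tss,
            "spacer_length": spacer_len,
            "disc_length": disc_len,
            "dg_true": dg,
        }
        for j, r in enumerate(reps, start=1):
            row[f"tx_rep{j}"] = float(r)
        row["tx_mean"] = float(reps.mean())
        row["tx_sd"] = float(reps.std(ddof=1)) if n_reps > 1 else 0.0
        row["tx_cv"] = row["tx_sd"] / row["tx_mean"]
        row["split"] = "test" if rng.random() < test_fraction else "train"
        rows.append(row)
    return PromoterDataset(pd.DataFrame(rows))


@dataclass
class SimulatedReads:
    """Raw-ish reads for one simulated experiment.

    ``rna``/``dna`` hold one read list per replicate; ``tss`` is a single
    TSS-mapping read list.  ``barcode_of`` links variant ids to barcodes
    and ``anchor`` is the constant flank used in TSS reads.
    """

    rna: list[list[str]]
    dna: list[list[str]]
    tss: list[str]
    barcode_of: dict[str, str]
    anchor: str

    def barcode_to_variant(self) -> dict[str, str]:
        return {b: v for v, b in self.barcode_of.items()}


def _mutate(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0:
        return reads
    out = []
    for read in reads:
        arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(arr)) < rate)[0]
        for pos in hits:
            arr[pos] = _BASES[rng.integers(0, 4)]
        out.append(arr.tobytes().decode())
    return out


def simulate_reads(
    dataset: PromoterDataset,
    barcode_set: BarcodeSet,
    depth: int = 500,
    seed: int = 0,
    error_rate: float = 0.0,
    tss_jitter: float = 0.0,
    copy_sigma: float = 0.2,
    depth_tss: int = 50,
    anchor: str = "ACCTGACGGT",
) -> SimulatedReads:
    """Sample barcoded RNA-Seq, DNA-Seq and TSS-mapping reads.

    DNA reads are multinomial in the (lognormal, ``copy_sigma``) plasmid
    copy numbers; RNA reads are multinomial with probability proportional
    to ``TX_ij x copy_i``; TSS reads start at the recorded TSS with
    optional +/-1 jitter.  Substitution errors are applied uniformly at
    ``error_rate`` per base.  Fixed totals per replicate (``depth`` reads
    per variant on average) mirror the normalization structure of the rate
    estimator.
    """
    rec = dataset.records
    n = len(rec)
    if len(barcode_set) < n:
        raise ValueError("need at least one barcode per variant")
    if depth < 1:
        import warnings

        warnings.warn("depth below one read per variant; counts will be sparse")
    rng = np.random.default_rng(seed)
    barcodes = list(barcode_set.barcodes[:n])
    barcode_of = dict(zip(rec["id"].astype(str), barcodes))
    rep_cols = [c for c in rec.columns if c.startswith("tx_rep")]
    copies = np.exp(rng.normal(0.0, copy_sigma, size=n)) if copy_sigma > 0 else np.ones(n)
    total = depth * n

    dna_reads: list[list[str]] = []
    rna_reads: list[list[str]] = []
    for col in rep_cols:
        tx = rec[col].to_numpy(dtype=float)
        dna_counts = rng.multinomial(total, copies / copies.sum())
        rna_counts = rng.multinomial(total, (tx * copies) / (tx * copies).sum())
        dna = [
            barcodes[i] + rec["sequence"].iloc[i]
            for i in range(n)
            for _ in range(dna_counts[i])
        ]
        rna = [barcodes[i] for i in range(n) for _ in range(rna_counts[i])]
        dna_reads.append(_mutate(dna, error_rate, rng))
        rna_reads.append(_mutate(rna, error_rate, rng))

    tss_reads: list[str] = []
    for i in range(n):
        seq, tss = rec["sequence"].iloc[i], int(rec["tss"].iloc[i])
        for _ in range(depth_tss):
            start = tss
            if tss_jitter > 0 and rng.random() < tss_jitter:
                start = max(0, tss + (1 if rng.random() < 0.5 else -1))
            tss_reads.append(barcodes[i] + anchor + seq[start : start + 20])
    tss_reads = _mutate(tss_reads, error_rate, rng)

    return SimulatedReads(
        rna=rna_reads, dna=dna_reads, tss=tss_reads, barcode_of=barcode_of, anchor=anchor
    )


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    """Write reads as uncompressed FASTQ with constant quality."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{read}\n+\n{'I' * len(read)}\n")
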