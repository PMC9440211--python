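"""Whole-construct analysis: cryptic promoter calling and context effects.

Scanning an engineered construct yields a transcriptional profile on both
strands; positions whose predicted initiation rate is at least threefold
above the strand average are called as TSSs.  Calls can be compared to
measured start-site lists with a precision-style accuracy (fraction of
predicted TSSs with a measured peak within a window), and a promoter's
sensitivity to its genetic context is quantified by Monte Carlo sampling
of random flanking sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .energy_model import EnergyModelParams
from .scan import TranscriptionProfile, scan_profile
from .shape import ShapeTables, load_default_tables

__all__ = [
    "TSSCall",
    "ContextSummary",
    "call_tss",
    "compare_tss",
    "context_monte_carlo",
    "write_bed",
]


@dataclass(frozen=True)
class TSSCall:
    """One called transcription start site."""

    position: int
    strand: str
    tx_rate: float
    fold_over_mean: float
    annotation: str = "cryptic"


def call_tss(
    profile: TranscriptionProfile,
    fold_threshold: float = 3.0,
    merge_radius: int = 5,
) -> list[TSSCall]:
    """Call TSSs where the rate is >= ``fold_threshold`` x the strand mean.

    The threshold is inclusive.  Adjacent qualifying positions within
    ``merge_radius`` nt collapse to their local maximum (real profiles have
    plateaus); pass ``merge_radius=0`` to disable merging.
    """
    if not profile.forward and not profile.reverse:
        raise ValueError("empty profile")
    calls: list[TSSCall] = []
    for strand in ("forward", "reverse"):
        entries = profile.strand_calls(strand)
        if not entries:
            continue
        mean = sum(c.tx_rate for c in entries) / len(entries)
        qualifying = [c for c in entries if c.tx_rate >= fold_threshold * mean]
        qualifying.sort(key=lambda c: c.position)
        clusters: list[list] = []
        for c in qualifying:
            if (
                merge_radius
                and clusters
                and c.position - clusters[-1][-1].position <= merge_radius
            ):
                clusters[-1].append(c)
            else:
                clusters.append([c])
        for cluster in clusters:
            peak = max(cluster, key=lambda c: (c.tx_rate, -c.position))
            calls.append(
                TSSCall(
                    position=peak.position,
                    strand=strand,
                    tx_rate=peak.tx_rate,
                    fold_over_mean=peak.tx_rate / mean,
                )
            )
    return calls


def compare_tss(
    predicted: Sequence[TSSCall] | Sequence[int],
    measured: Sequence[int],
    window: int = 10,
) -> dict:
    """Precision-style accuracy of predicted against measured TSSs.

    Accuracy = (number of predicted TSSs with a measured peak within
    ``window`` bp) / (number of predicted TSSs).  Undefined (flagged) when
    nothing was predicted.
    """
    positions = [p.position if isinstance(p, TSSCall) else int(p) for p in predicted]
    matched = []
    for p in positions:
        near = [m for m in measured if abs(m - p) <= window]
        if near:
            matched.append((p, min(near, key=lambda m: abs(m - p))))
    if not positions:
        return {"accuracy": None, "defined": False, "n_predicted": 0, "matched": []}
    return {
        "accuracy": len(matched) / len(positions),
        "defined": True,
        "n_predicted": len(positions),
        "matched": matched,
    }


@dataclass
class ContextSummary:
    """Distribution of a promoter's predicted rate over random contexts."""

    mean: float
    sd: float
    cv: float
    quartiles: tuple[float, float, float]
    outliers: list[float]
    n: int
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(self.__dict__, indent=1, default=float)
        if path is not None:
            Path(path).write_text(doc)
        return doc


def context_monte_carlo(
    core_promoter: str,
    params: EnergyModelParams,
    tables: ShapeTables | None = None,
    n: int = 10000,
    flank_len: int = 30,
    seed: int = 0,
    both_strands: bool = False,
) -> ContextSummary:
    """Quantify genetic-context sensitivity of a core promoter.

    Draws ``n`` random flank pairs (``flank_len`` bp each, uniform base
    composition), embeds the core promoter between them, scans each
    construct and records the maximum predicted rate within it.  Outliers
    are values beyond 1.5 IQR of the quartiles.
    """
    tables = tables or load_default_tables()
    rng = np.random.default_rng(seed)
    min_len = 62 + 20  # smallest scannable construct
    if len(core_promoter) + 2 * flank_len < min_len:
        raise ValueError(
            f"core of {len(core_promoter)} nt with {flank_len} nt flanks is below the "
            f"minimal scannable length of {min_len} nt"
        )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    rates = np.empty(n)
    for i in range(n):
        left = bases[rng.integers(0, 4, size=flank_len)].tobytes().decode()
        right = bases[rng.integers(0, 4, size=flank_len)].tobytes().decode()
        profile = scan_profile(
            left + core_promoter + right, params, tables=tables, both_strands=both_strands
        )
        calls = profile.forward + profile.reverse
        rates[i] = max(c.tx_rate for c in calls)
    q1, q2, q3 = (float(q) for q in np.percentile(rates, [25, 50, 75]))
    iqr = q3 - q1
    out = rates[(rates < q1 - 1.5 * iqr) | (rates > q3 + 1.5 * iqr)]
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1)) if n > 1 else 0.0
    return ContextSummary(
        mean=mean,
        sd=sd,
        cv=sd / mean if mean else 0.0,
        quartiles=(q1, q2, q3),
        outliers=[float(v) for v in out],
        n=n,
        seed=seed,
    )


def write_bed(calls: Sequence[TSSCall], path: str | Path, sequence_id: str = "seq") -> None:
    """Export calls as strand-aware BED6."""
    with open(path, "w") as fh:
        for i, c in enumerate(sorted(calls, key=lambda c: c.position)):
            strand = "+" if c.strand == "forward" else "-"
            fh.write(
                f"{sequence_id}\t{c.position}\t{c.position + 1}\tTSS{i}\t"
                f"{min(int(round(c.fold_over_mean * 100)), 1000)}\t{strand}\n"
            )
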