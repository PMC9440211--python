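"""Transcriptional profiling of arbitrary DNA.

At every candidate TSS the scanner enumerates the 36 ways RNAP/sigma70 can
tile the surrounding sequence (spacer 15-20 bp x discriminator 5-10 nt),
scores each with the free-energy model, and keeps the configuration with
the most negative total energy.  Repeating this at every position on both
strands yields a transcriptional profile: predicted initiation rate versus
nucleotide position.

Ties between equal-energy configurations are broken deterministically
(|spacer - 17| ascending, then smaller disc, then smaller spacer) so
profiles are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .energy_model import (
    DISC_RANGE,
    SPACER_RANGE,
    CompiledModel,
    EnergyBreakdown,
    EnergyModelParams,
    InsufficientContextError,
    PromoterConfiguration,
    parse_configuration,
    reverse_complement,
)
from .shape import ShapeTables, load_default_tables

__all__ = [
    "SiteCall",
    "TranscriptionProfile",
    "best_configuration",
    "scan_profile",
    "MAX_UPSTREAM",
    "DOWNSTREAM",
]

#: context required upstream of a TSS so that all 36 configurations fit
MAX_UPSTREAM = 32 + max(SPACER_RANGE) + max(DISC_RANGE)
#: context required downstream of a TSS (the ITR window)
DOWNSTREAM = 20

#: enumeration order also encodes the tie-break: |spacer-17| asc, disc asc, spacer asc
_CONFIG_ORDER = sorted(
    ((s, d) for s in SPACER_RANGE for d in DISC_RANGE),
    key=lambda sd: (abs(sd[0] - 17), sd[1], sd[0]),
)


@dataclass(frozen=True)
class SiteCall:
    """Best binding configuration and predicted rate at one TSS position."""

    position: int  # forward-parent coordinate of the TSS
    strand: str
    dg_total: float
    tx_rate: float
    config: PromoterConfiguration
    breakdown: EnergyBreakdown


@dataclass
class TranscriptionProfile:
    """Per-position, per-strand predicted transcription initiation rates.

    Both strand vectors are indexed on the forward coordinate system;
    entries are sorted by position.
    """

    sequence_id: str
    length: int
    circular: bool
    model_fingerprint: str | None
    forward: list[SiteCall]
    reverse: list[SiteCall]

    def strand_calls(self, strand: str) -> list[SiteCall]:
        return self.forward if strand == "forward" else self.reverse

    def to_rows(self) -> Iterator[dict]:
        for call in self.forward + self.reverse:
            c = call.config
            yield {
                "seq_id": self.sequence_id,
                "strand": call.strand,
                "position_0based": call.position,
                "dg_total": call.dg_total,
                "tx_rate": call.tx_rate,
                "spacer_len": c.spacer_length,
                "disc_len": c.disc_length,
                "hex35": c.hex35,
                "hex10": c.hex10,
                "disc": c.disc,
                "itr": c.itr,
            }

    def write_tsv(self, path: str | Path) -> None:
        import csv

        rows = list(self.to_rows())
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else [], delimiter="\t")
            writer.writeheader()
            writer.writerows(rows)

    def write_bedgraph(self, directory: str | Path) -> None:
        """One bedGraph track per strand, value = predicted TX rate."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for strand, calls in (("forward", self.forward), ("reverse", self.reverse)):
            with open(directory / f"{self.sequence_id}.{strand}.bedgraph", "w") as fh:
                fh.write(
                    f'track type=bedGraph name="{self.sequence_id} {strand} TX"\n'
                )
                for call in calls:
                    fh.write(
                        f"{self.sequence_id}\t{call.position}\t{call.position + 1}\t{call.tx_rate:.6g}\n"
                    )


def best_configuration(
    sequence: str,
    tss_index: int,
    strand: str,
    model: CompiledModel,
    circular: bool = False,
) -> tuple[PromoterConfiguration, EnergyBreakdown]:
    """Minimum-energy binding configuration at one TSS.

    Enumerates all 36 spacer x disc tilings and returns the argmin of
    ``dg_total``.  Raises :class:`InsufficientContextError` if the position
    cannot hold every tiling on a linear sequence (so that the argmin is
    always over the full 36-way enumeration).
    """
    best: tuple[PromoterConfiguration, EnergyBreakdown] | None = None
    for spacer_len, disc_len in _CONFIG_ORDER:
        config = parse_configuration(
            sequence,
            tss_index,
            strand=strand,
            spacer_length=spacer_len,
            disc_length=disc_len,
            circular=circular,
        )
        bd = model.breakdown(config)
        if best is None or bd.dg_total < best[1].dg_total:
            best = (config, bd)
    assert best is not None
    return best


def _evaluable_positions(length: int, circular: bool, strand: str) -> range:
    if circular:
        return range(length)
    if strand == "forward":
        lo, hi = MAX_UPSTREAM, length - DOWNSTREAM
    else:  # mirrored bounds on the forward coordinate system
        lo, hi = DOWNSTREAM - 1, length - MAX_UPSTREAM - 1
    return range(lo, max(hi + 1, lo))


def scan_profile(
    sequence: str,
    params: EnergyModelParams,
    tables: ShapeTables | None = None,
    circular: bool = False,
    both_strands: bool = True,
    sequence_id: str = "seq",
) -> TranscriptionProfile:
    """Predict the transcriptional profile of a sequence.

    For linear sequences only positions with full context for all 36
    configurations are evaluated; circular sequences are evaluated at every
    position on each strand (wrapping across the origin).  The reverse
    strand is scored by running the identical forward calculation on the
    reverse complement and re-mapping coordinates, so strand symmetry is
    exact.
    """
    if not sequence:
        raise ValueError("empty sequence")
    tables = tables or load_default_tables()
    model = CompiledModel(params, tables)
    length = len(sequence)

    forward: list[SiteCall] = []
    for pos in _evaluable_positions(length, circular, "forward"):
        config, bd = best_configuration(sequence, pos, "forward", model, circular)
        forward.append(
            SiteCall(pos, "forward", bd.dg_total, model.tx(bd.dg_total), config, bd)
        )

    reverse: list[SiteCall] = []
    if both_strands:
        rc = reverse_complement(sequence)
        for pos in _evaluable_positions(length, circular, "reverse"):
            rc_pos = length - 1 - pos
            config, bd = best_configuration(rc, rc_pos, "forward", model, circular)
            reverse.append(
                SiteCall(pos, "reverse", bd.dg_total, model.tx(bd.dg_total), config, bd)
            )

    return TranscriptionProfile(
        sequence_id=sequence_id,
        length=length,
        circular=circular,
        model_fingerprint=params.tables_checksum,
        forward=forward,
        reverse=reverse,
    )


def scan_records(
    records: Iterable,
    params: EnergyModelParams,
    tables: ShapeTables | None = None,
    circular: bool = False,
) -> Iterator[TranscriptionProfile]:
    """Scan Biopython SeqRecords (FASTA/GenBank); honors record topology."""
    for rec in records:
        topo = rec.annotations.get("topology", "") if hasattr(rec, "annotations") else ""
        yield scan_profile(
            str(rec.seq).upper(),
            params,
            tables=tables,
            circular=circular or topo == "circular",
            sequence_id=rec.id,
        )
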