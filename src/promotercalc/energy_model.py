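"""Free-energy decomposition of RNAP/sigma70-promoter binding.

The model treats transcription initiation as a two-state system: RNAP/sigma70
free in solution versus bound at a promoter with a stable transcription
bubble.  The total binding free energy decomposes additively over seven
sequence regions,

    dG_total = dG_UP + dG_-35 + dG_spacer + dG_-10ext + dG_-10 + dG_disc + dG_ITR,

and relates to the transcription initiation rate through a reference
promoter,

    TX / TX_ref = exp(-beta * (dG_total - dG_total_ref)).

Each region's energy is a linear function of a 346-entry feature vector:
one-hot 3-mers for the two halves of each hexamer (4 x 64), one-hot 3-mers
for the first three discriminator nucleotides (64), one-hot 2-mers for the
two nucleotides abutting the -10 hexamer (16), one-hot spacer-length bits
for 15-20 bp (6), and four normalized numeric features (spacer rigidity,
minor groove width of the distal and proximal UP half-sites, and R-loop
stability of the initial transcribed region).

Energies are in RT units with ``beta`` fixed at 1: the coefficients are
fitted to log-rates, so any other choice of scale would simply be absorbed
into them.
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .shape import ShapeTables, minor_groove_width, r_loop_delta_g, spacer_rigidity

__all__ = [
    "FEATURE_NAMES",
    "NUMERIC_FEATURES",
    "TERM_BLOCKS",
    "SPACER_RANGE",
    "DISC_RANGE",
    "PromoterConfiguration",
    "FeatureVector",
    "EnergyBreakdown",
    "EnergyModelParams",
    "OccupancySystem",
    "CompiledModel",
    "parse_configuration",
    "encode_features",
    "delta_g_total",
    "tx_from_energy",
    "occupancy",
    "reverse_complement",
    "default_normalizers",
    "InsufficientContextError",
]

SPACER_RANGE = range(15, 21)
DISC_RANGE = range(5, 11)

_BASES = "ACGT"
_VALID = set(_BASES)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

KMERS3 = tuple("".join(p) for p in itertools.product(_BASES, repeat=3))
KMERS2 = tuple("".join(p) for p in itertools.product(_BASES, repeat=2))

NUMERIC_FEATURES = ("spacer_rigidity", "up_distal_mgw", "up_proximal_mgw", "itr_rloop")

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"hex35_1_{k}" for k in KMERS3)
    + tuple(f"hex35_2_{k}" for k in KMERS3)
    + tuple(f"hex10_1_{k}" for k in KMERS3)
    + tuple(f"hex10_2_{k}" for k in KMERS3)
    + tuple(f"disc_{k}" for k in KMERS3)
    + tuple(f"ext10_{k}" for k in KMERS2)
    + tuple(f"spacer_len_{n}" for n in SPACER_RANGE)
    + NUMERIC_FEATURES
)
assert len(FEATURE_NAMES) == 346

_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: feature prefixes contributing to each free-energy term
TERM_BLOCKS: dict[str, tuple[str, ...]] = {
    "dg_35": ("hex35_1_", "hex35_2_"),
    "dg_10": ("hex10_1_", "hex10_2_"),
    "dg_disc": ("disc_",),
    "dg_10ext": ("ext10_",),
    "dg_spacer": ("spacer_len_", "spacer_rigidity"),
    "dg_up": ("up_distal_mgw", "up_proximal_mgw"),
    "dg_itr": ("itr_rloop",),
}

TERM_INDICES: dict[str, np.ndarray] = {
    term: np.array(
        [i for i, n in enumerate(FEATURE_NAMES) if any(n.startswith(p) for p in prefixes)],
        dtype=np.intp,
    )
    for term, prefixes in TERM_BLOCKS.items()
}

Strand = Literal["forward", "reverse"]


class InsufficientContextError(ValueError):
    """Raised when a linear sequence lacks the context to tile a configuration."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class PromoterConfiguration:
    """One RNAP/sigma70 binding geometry at a fixed transcription start site.

    Motif slices tile contiguously on the working strand:
    ``up_distal | up_proximal | hex35 | spacer | hex10 | disc`` end exactly
    at the TSS and ``itr`` starts there.  ``ext10`` is the 3'-most 4 nt of
    the spacer.  ``coords`` holds the 0-based half-open slice of each motif
    on the working strand (the forward parent, or the reverse complement if
    ``strand == "reverse"``).
    """

    sequence_window: str
    tss_index: int
    strand: Strand
    spacer_length: int
    disc_length: int
    up_distal: str
    up_proximal: str
    hex35: str
    spacer: str
    ext10: str
    hex10: str
    disc: str
    itr: str
    coords: Mapping[str, tuple[int, int]] = field(default_factory=dict, compare=False)

    @property
    def upstream_context(self) -> int:
        """Total nucleotides consumed upstream of the TSS."""
        return 32 + self.spacer_length + self.disc_length


def parse_configuration(
    sequence: str,
    tss_index: int,
    strand: Strand = "forward",
    spacer_length: int = 17,
    disc_length: int = 6,
    circular: bool = False,
) -> PromoterConfiguration:
    """Tile the motif slices of one binding configuration around a TSS.

    Parameters
    ----------
    sequence
        Parent DNA, forward strand, uppercase A/C/G/T.
    tss_index
        0-based position of the first transcribed base.  For
        ``strand="reverse"`` this is still a forward-parent coordinate; the
        configuration is built on the reverse complement with the TSS
        re-expressed on that strand.
    circular
        Treat the sequence as a circle, wrapping context across the origin.
    """
    if not sequence:
        raise ValueError("empty sequence")
    _check_dna(sequence)
    if spacer_length not in SPACER_RANGE:
        raise ValueError(f"spacer length must be in [15, 20], got {spacer_length}")
    if disc_length not in DISC_RANGE:
        raise ValueError(f"disc length must be in [5, 10], got {disc_length}")
    length = len(sequence)
    if not 0 <= tss_index < length:
        raise ValueError(f"tss_index {tss_index} outside sequence of length {length}")

    if strand == "reverse":
        work_seq = reverse_complement(sequence)
        work_tss = length - 1 - tss_index
    elif strand == "forward":
        work_seq = sequence
        work_tss = tss_index
    else:
        raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")

    upstream = 32 + spacer_length + disc_length
    if circular:
        if length < upstream + 20:
            raise InsufficientContextError(
                f"circular sequence of {length} nt cannot hold a {upstream + 20} nt window"
            )
        # unwrap a window around the TSS so plain slicing applies
        start = (work_tss - upstream) % length
        window = (work_seq + work_seq)[start : start + upstream + 20]
        offset = 0
    else:
        if work_tss < upstream or work_tss + 20 > length:
            raise InsufficientContextError(
                f"TSS at {tss_index} needs {upstream} nt upstream and 20 nt downstream "
                f"on the {strand} strand"
            )
        window = work_seq[work_tss - upstream : work_tss + 20]
        offset = work_tss - upstream

    cuts = {
        "up_distal": (0, 10),
        "up_proximal": (10, 20),
        "hex35": (20, 26),
        "spacer": (26, 26 + spacer_length),
        "hex10": (26 + spacer_length, 32 + spacer_length),
        "disc": (32 + spacer_length, upstream),
        "itr": (upstream, upstream + 20),
    }
    parts = {name: window[a:b] for name, (a, b) in cuts.items()}
    coords = {name: (a + offset, b + offset) for name, (a, b) in cuts.items()}
    return PromoterConfiguration(
        sequence_window=window,
        tss_index=tss_index,
        strand=strand,
        spacer_length=spacer_length,
        disc_length=disc_length,
        up_distal=parts["up_distal"],
        up_proximal=parts["up_proximal"],
        hex35=parts["hex35"],
        spacer=parts["spacer"],
        ext10=parts["spacer"][-4:],
        hex10=parts["hex10"],
        disc=parts["disc"],
        itr=parts["itr"],
        coords=coords,
    )


class FeatureVector:
    """Ordered 346-entry mapping of feature name to numeric value.

    Categorical entries are 0/1 bits; the four numeric entries are values
    divided by their stored normalizers.  ``values`` exposes the dense
    float64 array in canonical :data:`FEATURE_NAMES` order.
    """

    __slots__ = ("values",)
    names = FEATURE_NAMES

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"feature vector must have {len(FEATURE_NAMES)} entries")
        self.values = values

    def __getitem__(self, name: str) -> float:
        return float(self.values[_INDEX[name]])

    def __len__(self) -> int:
        return len(FEATURE_NAMES)

    def items(self):
        return zip(FEATURE_NAMES, self.values)

    def active(self) -> list[str]:
        """Names of the nonzero entries."""
        return [n for n, v in self.items() if v != 0.0]


def encode_features(
    config: PromoterConfiguration,
    tables: ShapeTables,
    normalizers: Mapping[str, float],
) -> FeatureVector:
    """Encode one binding configuration as the canonical 346-entry vector.

    Exactly seven categorical bits are set per configuration: two 3-mers in
    each hexamer, the discriminator 3-mer, the -10-proximal 2-mer of the
    extended -10, and the spacer-length bit.
    """
    missing = [n for n in NUMERIC_FEATURES if n not in normalizers]
    if missing:
        raise ValueError(f"normalizers missing numeric features: {missing}")
    v = np.zeros(len(FEATURE_NAMES))
    for name in (
        f"hex35_1_{config.hex35[:3]}",
        f"hex35_2_{config.hex35[3:]}",
        f"hex10_1_{config.hex10[:3]}",
        f"hex10_2_{config.hex10[3:]}",
        f"disc_{config.disc[:3]}",
        f"ext10_{config.ext10[2:]}",
        f"spacer_len_{config.spacer_length}",
    ):
        v[_INDEX[name]] = 1.0
    v[_INDEX["spacer_rigidity"]] = (
        spacer_rigidity(config.spacer, tables) / normalizers["spacer_rigidity"]
    )
    v[_INDEX["up_distal_mgw"]] = (
        minor_groove_width(config.up_distal, tables) / normalizers["up_distal_mgw"]
    )
    v[_INDEX["up_proximal_mgw"]] = (
        minor_groove_width(config.up_proximal, tables) / normalizers["up_proximal_mgw"]
    )
    v[_INDEX["itr_rloop"]] = r_loop_delta_g(config.itr, tables) / normalizers["itr_rloop"]
    return FeatureVector(v)


def default_normalizers(tables: ShapeTables) -> dict[str, float]:
    """Maximum-possible-value normalizers derived from a table set."""
    mgw_max = max(tables.mgw_pentamer.values())
    rig_max = max(tables.rigidity_dinucleotide.values())
    rloop_max = 14 * max(
        abs(tables.nn_dna_dna[s] - tables.nn_rna_dna[s]) for s in tables.nn_dna_dna
    )
    return {
        "spacer_rigidity": rig_max,
        "up_distal_mgw": mgw_max,
        "up_proximal_mgw": mgw_max,
        "itr_rloop": rloop_max,
    }


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-region free energies (RT); ``dg_total`` is their sum."""

    dg_up: float
    dg_35: float
    dg_spacer: float
    dg_10ext: float
    dg_10: float
    dg_disc: float
    dg_itr: float
    dg_total: float

    def terms(self) -> dict[str, float]:
        return {
            "dg_up": self.dg_up,
            "dg_35": self.dg_35,
            "dg_spacer": self.dg_spacer,
            "dg_10ext": self.dg_10ext,
            "dg_10": self.dg_10,
            "dg_disc": self.dg_disc,
            "dg_itr": self.dg_itr,
        }


@dataclass
class EnergyModelParams:
    """The 346 interaction energies plus calibration constants.

    ``coefficients`` maps every canonical feature name to its energy
    contribution in RT.  ``normalizers`` holds the positive maxima the four
    numeric features are divided by; they are stored with the model (not
    recomputed at predict time) so predictions are reproducible across
    datasets.  ``tables_checksum`` pins the shape tables the model was
    trained with.
    """

    coefficients: dict[str, float]
    normalizers: dict[str, float]
    beta: float = 1.0
    dg_total_ref: float = 0.0
    tx_ref: float = 1.0
    feature_space_version: str = "pruned-346-v1"
    tables_checksum: str | None = None

    def __post_init__(self) -> None:
        extra = set(self.coefficients) - set(FEATURE_NAMES)
        missing = set(FEATURE_NAMES) - set(self.coefficients)
        if extra or missing:
            raise ValueError(
                f"coefficient names must match the 346 canonical features "
                f"(missing {len(missing)}, unknown {len(extra)})"
            )
        for name in NUMERIC_FEATURES:
            if self.normalizers.get(name, 0.0) <= 0:
                raise ValueError(f"normalizer for {name} must be strictly positive")
        if self.tx_ref <= 0:
            raise ValueError("tx_ref must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in FEATURE_NAMES])

    @classmethod
    def zeros(cls, tables: ShapeTables | None = None, **kwargs) -> "EnergyModelParams":
        from .shape import load_default_tables

        tables = tables or load_default_tables()
        return cls(
            coefficients={n: 0.0 for n in FEATURE_NAMES},
            normalizers=default_normalizers(tables),
            tables_checksum=tables.checksum(),
            **kwargs,
        )

    def replace_coefficients(self, updates: Mapping[str, float]) -> "EnergyModelParams":
        coeffs = dict(self.coefficients)
        coeffs.update(updates)
        return EnergyModelParams(
            coefficients=coeffs,
            normalizers=dict(self.normalizers),
            beta=self.beta,
            dg_total_ref=self.dg_total_ref,
            tx_ref=self.tx_ref,
            feature_space_version=self.feature_space_version,
            tables_checksum=self.tables_checksum,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "feature_space_version": self.feature_space_version,
                "coefficients": self.coefficients,
                "normalizers": self.normalizers,
                "beta": self.beta,
                "dg_total_ref": self.dg_total_ref,
                "tx_ref": self.tx_ref,
                "tables_checksum": self.tables_checksum,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "EnergyModelParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            coefficients=doc["coefficients"],
            normalizers=doc["normalizers"],
            beta=doc.get("beta", 1.0),
            dg_total_ref=doc.get("dg_total_ref", 0.0),
            tx_ref=doc.get("tx_ref", 1.0),
            feature_space_version=doc.get("feature_space_version", "pruned-346-v1"),
            tables_checksum=doc.get("tables_checksum"),
        )

    def to_csv(self, path: str | Path) -> None:
        """Export the interaction-energy table as (feature, coefficient) CSV."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["feature", "coefficient_RT"])
            for name in FEATURE_NAMES:
                writer.writerow([name, repr(self.coefficients[name])])


def delta_g_total(fv: FeatureVector, params: EnergyModelParams) -> EnergyBreakdown:
    """Decompose a feature vector's energy into the seven region terms."""
    w = params.weights
    v = fv.values
    terms = {term: float(w[idx] @ v[idx]) for term, idx in TERM_INDICES.items()}
    return EnergyBreakdown(**{k: terms[k] for k in terms}, dg_total=sum(terms.values()))


def tx_from_energy(dg_total: float, params: EnergyModelParams) -> float:
    """Transcription initiation rate for a total binding energy (RT).

    ``TX = TX_ref * exp(-beta * (dG_total - dG_total_ref))``; strictly
    decreasing in ``dg_total`` and equal to ``tx_ref`` at the reference
    energy.
    """
    return params.tx_ref * math.exp(-params.beta * (dg_total - params.dg_total_ref))


@dataclass(frozen=True)
class OccupancySystem:
    """Competing RNAP/sigma70 binding sites in one closed system.

    ``sites`` holds ``(copy_number, dg_total)`` pairs; ``r_total`` is the
    total available holoenzyme count.
    """

    sites: tuple[tuple[float, float], ...]
    r_total: float

    def __post_init__(self) -> None:
        if any(p <= 0 for p, _ in self.sites):
            raise ValueError("site copy numbers must be positive")
        if self.r_total < 0:
            raise ValueError("r_total must be non-negative")


def occupancy(system: OccupancySystem, beta: float = 1.0) -> tuple[list[float], float]:
    """Equilibrium bound counts per site and the free holoenzyme count.

    ``C_i = R_total * P_i * exp(-beta * dG_i) / Z`` with the partition
    function ``Z = 1 + sum_j P_j exp(-beta * dG_j)``; the free count is
    ``R = R_total / Z`` so that ``sum C_i + R = R_total`` exactly.
    """
    boltz = [p * math.exp(-beta * dg) for p, dg in system.sites]
    z = 1.0 + sum(boltz)
    bound = [system.r_total * b / z for b in boltz]
    return bound, system.r_total / z


class CompiledModel:
    """Dictionary-lookup fast path for scoring many configurations.

    Produces the same :class:`EnergyBreakdown` as
    ``delta_g_total(encode_features(...), params)`` without materializing
    the 346-entry vector; used by the scanner, the designers and the
    synthetic-data generator.
    """

    __slots__ = ("params", "tables", "_w", "_norm")

    def __init__(self, params: EnergyModelParams, tables: ShapeTables):
        if params.tables_checksum and params.tables_checksum != tables.checksum():
            raise ValueError(
                "shape tables do not match the tables these parameters were trained with"
            )
        self.params = params
        self.tables = tables
        self._w = params.coefficients
        self._norm = params.normalizers

    def breakdown(self, config: PromoterConfiguration) -> EnergyBreakdown:
        w, t, norm = self._w, self.tables, self._norm
        dg_35 = w["hex35_1_" + config.hex35[:3]] + w["hex35_2_" + config.hex35[3:]]
        dg_10 = w["hex10_1_" + config.hex10[:3]] + w["hex10_2_" + config.hex10[3:]]
        dg_disc = w["disc_" + config.disc[:3]]
        dg_10ext = w["ext10_" + config.ext10[2:]]
        dg_spacer = (
            w[f"spacer_len_{config.spacer_length}"]
            + w["spacer_rigidity"]
            * spacer_rigidity(config.spacer, t)
            / norm["spacer_rigidity"]
        )
        dg_up = (
            w["up_distal_mgw"] * minor_groove_width(config.up_distal, t) / norm["up_distal_mgw"]
            + w["up_proximal_mgw"]
            * minor_groove_width(config.up_proximal, t)
            / norm["up_proximal_mgw"]
        )
        dg_itr = w["itr_rloop"] * r_loop_delta_g(config.itr, t) / norm["itr_rloop"]
        total = dg_up + dg_35 + dg_spacer + dg_10ext + dg_10 + dg_disc + dg_itr
        return EnergyBreakdown(
            dg_up=dg_up,
            dg_35=dg_35,
            dg_spacer=dg_spacer,
            dg_10ext=dg_10ext,
            dg_10=dg_10,
            dg_disc=dg_disc,
            dg_itr=dg_itr,
            dg_total=total,
        )

    def tx(self, dg_total: float) -> float:
        return tx_from_energy(dg_total, self.params)
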