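"""Sequence-derived biophysical quantities feeding the numeric model features.

Three calculators contribute one numeric feature each (the minor-groove-width
calculator contributes two, one per UP half-site):

* minor groove width of a 10-bp UP half-site, averaged over its six
  overlapping pentamers (Angstrom);
* spacer rigidity, the mean dinucleotide-step stiffness over the spacer
  (arbitrary persistence-length units);
* R-loop stability of the first 15 transcribed nucleotides, the DNA:DNA
  duplex free energy minus the RNA:DNA hybrid free energy summed over the
  14 nearest-neighbor steps (kcal/mol).

All three are pure functions of ``(sequence, tables)``.  The shipped default
tables live in :mod:`promotercalc.data`; trained coefficients are only
meaningful together with the tables in force at training time, so
:class:`~promotercalc.energy_model.EnergyModelParams` records a checksum of
the tables it was fitted with.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "ShapeTables",
    "load_default_tables",
    "minor_groove_width",
    "spacer_rigidity",
    "r_loop_delta_g",
]

_VALID = set("ACGT")


def _read_table(path_or_text: str) -> dict[str, float]:
    table: dict[str, float] = {}
    for line in path_or_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        try:
            table[key] = float(value)
        except ValueError:
            continue  # header row
    return table


@dataclass(frozen=True)
class ShapeTables:
    """Lookup tables for the shape/thermodynamic calculators.

    Attributes
    ----------
    mgw_pentamer
        5-mer -> minor groove width (Angstrom); 1024 entries.
    rigidity_dinucleotide
        2-mer step -> stiffness contribution (arbitrary units); 16 entries.
    nn_dna_dna
        2-mer step -> DNA:DNA duplex dG37 (kcal/mol); 16 entries.
    nn_rna_dna
        2-mer step (DNA alphabet; transcript step = T->U) -> RNA:DNA hybrid
        dG37 (kcal/mol); 16 entries.
    """

    mgw_pentamer: dict[str, float]
    rigidity_dinucleotide: dict[str, float]
    nn_dna_dna: dict[str, float]
    nn_rna_dna: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.mgw_pentamer) != 4**5:
            raise ValueError(
                f"minor-groove table must cover all 1024 pentamers, got {len(self.mgw_pentamer)}"
            )
        for name, tab in [
            ("rigidity_dinucleotide", self.rigidity_dinucleotide),
            ("nn_dna_dna", self.nn_dna_dna),
            ("nn_rna_dna", self.nn_rna_dna),
        ]:
            if len(tab) != 16:
                raise ValueError(f"{name} must cover all 16 dinucleotide steps, got {len(tab)}")

    def checksum(self) -> str:
        """Stable digest of all table contents (recorded in trained params)."""
        h = hashlib.sha256()
        for tab in (
            self.mgw_pentamer,
            self.rigidity_dinucleotide,
            self.nn_dna_dna,
            self.nn_rna_dna,
        ):
            for key in sorted(tab):
                h.update(f"{key}={tab[key]:.6g};".encode())
        return h.hexdigest()[:16]

    @classmethod
    def from_files(cls, mgw: Path, rigidity: Path, nn_dna: Path, nn_rna: Path) -> "ShapeTables":
        return cls(
            mgw_pentamer=_read_table(Path(mgw).read_text()),
            rigidity_dinucleotide=_read_table(Path(rigidity).read_text()),
            nn_dna_dna=_read_table(Path(nn_dna).read_text()),
            nn_rna_dna=_read_table(Path(nn_rna).read_text()),
        )


def load_default_tables() -> ShapeTables:
    """Load the tables shipped with the package."""
    data = resources.files("promotercalc") / "data"
    read = lambda name: _read_table((data / name).read_text())  # noqa: E731
    return ShapeTables(
        mgw_pentamer=read("mgw_pentamer_synthetic.tsv"),
        rigidity_dinucleotide=read("rigidity_dinucleotide_synthetic.tsv"),
        nn_dna_dna=read("nn_dna_dna.tsv"),
        nn_rna_dna=read("nn_rna_dna.tsv"),
    )


def _check_dna(seq: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


def minor_groove_width(site: str, tables: ShapeTables) -> float:
    """Mean minor groove width (Angstrom) of a 10-nt site.

    The site contributes six overlapping pentamers; the returned value is
    their unweighted arithmetic mean.
    """
    if len(site) != 10:
        raise ValueError(f"UP half-site must be exactly 10 nt, got {len(site)}")
    _check_dna(site)
    tab = tables.mgw_pentamer
    return sum(tab[site[i : i + 5]] for i in range(6)) / 6.0


def spacer_rigidity(spacer: str, tables: ShapeTables) -> float:
    """Mean dinucleotide-step stiffness over a 15-20 nt spacer."""
    if not 15 <= len(spacer) <= 20:
        raise ValueError(f"spacer length must be 15-20 nt, got {len(spacer)}")
    _check_dna(spacer)
    tab = tables.rigidity_dinucleotide
    steps = len(spacer) - 1
    return sum(tab[spacer[i : i + 2]] for i in range(steps)) / steps


def r_loop_delta_g(itr: str, tables: ShapeTables) -> float:
    """R-loop stability over the first 15 transcribed nucleotides.

    Returns the DNA:DNA duplex free energy minus the RNA:DNA hybrid free
    energy, summed over the 14 nearest-neighbor steps of ``itr[:15]``
    (kcal/mol).  More negative values mean the hybrid is more stable than
    the duplex it displaces.
    """
    if len(itr) < 15:
        raise ValueError(f"ITR must provide at least 15 nt, got {len(itr)}")
    window = itr[:15]
    _check_dna(window)
    dna, rna = tables.nn_dna_dna, tables.nn_rna_dna
    return sum(dna[window[i : i + 2]] - rna[window[i : i + 2]] for i in range(14))
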