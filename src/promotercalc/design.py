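"""Sequence generation: design libraries, promoters and silent regions.

Four designers share the free-energy model as their objective:

* :func:`generate_background` -- random DNA matched to a GC target with no
  restriction sites and no strong cryptic hexamer motifs;
* :func:`generate_library` -- the seven-subset measurement library
  (exhaustive hexamer and extended -10 enumerations; rule-driven sampled
  UP/spacer/discriminator/ITR subsets) totalling 14,206 unique variants;
* :func:`design_promoter` -- simulated annealing toward user-defined
  transcription rates at chosen start sites while penalizing off-target
  initiation;
* :func:`minimize_tx_design` -- "no-promoter" spacer DNA and synonymous
  coding-sequence redesign that minimize the maximum predicted rate on
  both strands.

All designers are seed-deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .energy_model import CompiledModel, EnergyModelParams, reverse_complement
from .scan import best_configuration, scan_profile
from .shape import ShapeTables, load_default_tables
from .training import Pwm, default_pwms

__all__ = [
    "CONSENSUS_35",
    "CONSENSUS_10",
    "LibrarySpec",
    "DesignObjective",
    "DesignResult",
    "generate_background",
    "generate_library",
    "design_promoter",
    "minimize_tx_design",
]

CONSENSUS_35 = "TTGACA"
CONSENSUS_10 = "TATAAT"
ANTI_35 = "AACTGT"  # Watson complement of the consensus
ANTI_10 = "ATATTA"
MUT_35 = "TTGACC"
MUT_10 = "TATAAG"

_BASES = "ACGT"


def _rand_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(list(_BASES), size=length, p=[p_at, p_gc, p_gc, p_at]))


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _max_hexamer_score(seq: str, pwms: Mapping[str, Pwm]) -> float:
    if len(seq) < 6:
        return -math.inf
    return max(
        pwm.score(seq[i : i + 6])
        for pwm in pwms.values()
        for i in range(len(seq) - 5)
    )


def generate_background(
    length: int,
    gc_target: float = 0.508,
    forbidden_sites: Sequence[str] = (),
    motif_score_ceiling: float = 4.5,
    seed: int = 0,
    max_attempts: int = 2000,
) -> str:
    """Random background DNA with controlled GC and no cryptic promoters.

    Rejection-samples sequences until the GC fraction is within +/-0.05 of
    the target (the E. coli genome's 0.508 by default), no forbidden site
    occurs, and no 6-mer window scores above ``motif_score_ceiling`` under
    the consensus -10/-35 PWMs (the default ceiling rejects windows with
    five or more consensus matches).
    """
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    pwms = default_pwms()
    for _ in range(max_attempts):
        seq = _rand_seq(rng, length, gc_target)
        if abs(_gc_fraction(seq) - gc_target) > 0.05:
            continue
        if any(site in seq for site in forbidden_sites):
            continue
        if _max_hexamer_score(seq, pwms) > motif_score_ceiling:
            continue
        return seq
    raise RuntimeError(f"no background satisfying constraints within {max_attempts} attempts")


@dataclass(frozen=True)
class LibrarySpec:
    """Subset sizes and seed for the designed measurement library."""

    subset_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "up": 2420,
            "hex35": 4096,
            "spacer": 229,
            "ext10": 2048,
            "hex10": 4096,
            "disc": 735,
            "itr": 582,
        }
    )
    seed: int = 0

    @property
    def total(self) -> int:
        return sum(self.subset_sizes.values())


@dataclass
class _Backbone:
    """Baseline promoter parts for one subset's design background."""

    up: str
    hex35: str
    spacer: str
    hex10: str
    disc: str
    itr: str

    def assemble(self) -> tuple[str, int, int, int]:
        seq = self.up + self.hex35 + self.spacer + self.hex10 + self.disc + self.itr
        tss = len(self.up) + 6 + len(self.spacer) + 6 + len(self.disc)
        return seq, tss, len(self.spacer), len(self.disc)


def _backbone(rng: np.random.Generator, hex35: str = CONSENSUS_35, hex10: str = CONSENSUS_10) -> _Backbone:
    """Consensus-hexamer baseline in an optimized random background."""
    bg = generate_background(
        20 + 17 + 6 + 20,
        seed=int(rng.integers(0, 2**31)),
        forbidden_sites=("GGATCC", "AAGCTT", "GAATTC", "ACTAGT"),
    )
    return _Backbone(
        up=bg[:20], hex35=hex35, spacer=bg[20:37], hex10=hex10, disc=bg[37:43], itr=bg[43:63]
    )


def _with_at_content(rng: np.random.Generator, length: int, n_at: int) -> str:
    bases = [rng.choice(["A", "T"]) for _ in range(n_at)] + [
        rng.choice(["G", "C"]) for _ in range(length - n_at)
    ]
    rng.shuffle(bases)
    return "".join(bases)


def _unique_add(pool: set[str], candidate: str) -> bool:
    if candidate in pool:
        return False
    pool.add(candidate)
    return True


def generate_library(spec: LibrarySpec | None = None) -> pd.DataFrame:
    """Emit the designed promoter library as a data frame.

    Columns: ``id, subset, sequence, tss, spacer_length, disc_length,
    design``.  Hexamer and extended -10 subsets are exhaustive
    enumerations; UP, spacer, discriminator and ITR subsets are generated
    by their design rules (AT-content series and CA-repeat UP sites, spacer
    lengths 1-32 bp with varied composition, discriminator GC/length grid
    plus first-half 3-mer series, ITR purine/GC/pause-element series) with
    the subset sizes taken from the spec.  Each subset is built in its own
    optimized background so all emitted variants are unique.
    """
    spec = spec or LibrarySpec()
    sizes = dict(spec.subset_sizes)
    rng = np.random.default_rng(spec.seed)
    records: list[dict] = []
    seen: set[str] = set()

    def emit(subset: str, backbone: _Backbone, design: str) -> None:
        seq, tss, s, d = backbone.assemble()
        if not _unique_add(seen, seq):
            raise RuntimeError(f"duplicate variant in subset {subset}: {design}")
        records.append(
            {
                "id": f"{subset}_{len(records):05d}",
                "subset": subset,
                "sequence": seq,
                "tss": tss,
                "spacer_length": s,
                "disc_length": d,
                "design": design,
            }
        )

    hexamers = ["".join(p) for p in itertools.product(_BASES, repeat=6)]

    # -10 subset: all 4096 hexamers, consensus -35, 17-bp spacer
    bb = _backbone(rng)
    for hex10 in hexamers[: sizes["hex10"]]:
        emit("hex10", _Backbone(bb.up, bb.hex35, bb.spacer, hex10, bb.disc, bb.itr), hex10)

    # -35 subset: all 4096 hexamers, consensus -10
    bb = _backbone(rng)
    for hex35 in hexamers[: sizes["hex35"]]:
        emit("hex35", _Backbone(bb.up, hex35, bb.spacer, bb.hex10, bb.disc, bb.itr), hex35)

    # extended -10 subset: all 256 4-mers in 8 hexamer-combination backgrounds
    combos = [
        (CONSENSUS_35, CONSENSUS_10),
        (CONSENSUS_35, ANTI_10),
        (ANTI_35, CONSENSUS_10),
        (ANTI_35, ANTI_10),
        (MUT_35, CONSENSUS_10),
        (CONSENSUS_35, MUT_10),
        (MUT_35, ANTI_10),
        (ANTI_35, MUT_10),
    ]
    quad_per_bg = sizes["ext10"] // len(combos)
    quads = ["".join(p) for p in itertools.product(_BASES, repeat=4)]
    for hex35, hex10 in combos:
        bb = _backbone(rng, hex35, hex10)
        for quad in quads[:quad_per_bg]:
            spacer = bb.spacer[:-4] + quad
            emit("ext10", _Backbone(bb.up, hex35, spacer, hex10, bb.disc, bb.itr), f"{hex35}/{hex10}/{quad}")

    # UP subset: AT-content and CA-repeat series x 4 hexamer combinations
    n_up_seqs = sizes["up"] // 4
    up_pool: list[tuple[str, str]] = []
    up_seen: set[str] = set()
    level = 0
    while len(up_pool) < (n_up_seqs * 2) // 3:  # rule (i): AT-content series
        n_at = level % 21
        cand = _with_at_content(rng, 20, n_at)
        if _unique_add(up_seen, cand):
            up_pool.append((cand, f"at{n_at}"))
        level += 1
    while len(up_pool) < n_up_seqs:  # rule (ii): short C/A repeats in both half-sites
        n_at = int(rng.integers(0, 13))
        rep = str(rng.choice(["CCCC", "AAAA", "CACA"]))
        base = _with_at_content(rng, 20, n_at + 8)
        pos_d, pos_p = int(rng.integers(0, 7)), int(rng.integers(10, 17))
        cand = base[:pos_d] + rep + base[pos_d + 4 : pos_p] + rep + base[pos_p + 4 :]
        if len(cand) == 20 and _unique_add(up_seen, cand):
            up_pool.append((cand, f"repeat{rep}"))
    up_combos = combos[:4]
    for hex35, hex10 in up_combos:
        bb = _backbone(rng, hex35, hex10)
        for up, tag in up_pool:
            emit("up", _Backbone(up, hex35, bb.spacer, hex10, bb.disc, bb.itr), f"{hex35}/{hex10}/{tag}")

    # spacer subset: lengths 1-32 bp, varied composition, round-robin fill
    bb = _backbone(rng)
    spacer_lengths = list(range(1, 33))
    spacer_seen: set[str] = set()
    emitted = 0
    while emitted < sizes["spacer"]:
        for length in spacer_lengths:
            if emitted >= sizes["spacer"]:
                break
            if len(spacer_seen) >= sum(min(4**l, 10**9) for l in spacer_lengths):
                raise RuntimeError("spacer design space exhausted")
            cand = _rand_seq(rng, length, gc=float(rng.uniform(0.1, 0.9)))
            if not _unique_add(spacer_seen, f"{length}:{cand}"):
                continue
            emit(
                "spacer",
                _Backbone(bb.up, bb.hex35, cand, bb.hex10, bb.disc, bb.itr),
                f"len{length}",
            )
            emitted += 1

    # discriminator subset: GC/length grid plus first-half 3-mer series
    bb = _backbone(rng)
    disc_seen: set[str] = set()
    emitted = 0
    grid = [(length, n_gc) for length in (6, 7, 8) for n_gc in range(length + 1)]
    for length, n_gc in grid:  # rule (i): 5 random sequences per grid cell
        for _ in range(5):
            while True:
                cand = _with_at_content(rng, length, length - n_gc)
                if _unique_add(disc_seen, cand):
                    break
            emit("disc", _Backbone(bb.up, bb.hex35, bb.spacer, bb.hex10, cand, bb.itr), f"len{length}_gc{n_gc}")
            emitted += 1
    trimers = ["".join(p) for p in itertools.product(_BASES, repeat=3)]
    while emitted < sizes["disc"]:  # rule (ii): all 3-mers in the first half
        for trimer in trimers:
            if emitted >= sizes["disc"]:
                break
            n_gc = int(rng.integers(0, 5))
            tail = _with_at_content(rng, 4, 4 - n_gc)
            cand = trimer + tail
            if not _unique_add(disc_seen, cand):
                continue
            emit("disc", _Backbone(bb.up, bb.hex35, bb.spacer, bb.hex10, cand, bb.itr), f"3mer{trimer}")
            emitted += 1

    # ITR subset: purine content, GC content and pause-element series
    bb = _backbone(rng)
    itr_seen: set[str] = set()
    emitted = 0
    while emitted < sizes["itr"]:
        n_purine = int(rng.integers(0, 21))
        bases = [str(rng.choice(["A", "G"])) for _ in range(n_purine)] + [
            str(rng.choice(["C", "T"])) for _ in range(20 - n_purine)
        ]
        rng.shuffle(bases)
        cand = "".join(bases)
        tag = f"purine{n_purine}"
        if emitted % 3 == 2:  # embed a -10-like pause element
            pos = int(rng.integers(0, 15))
            cand = cand[:pos] + CONSENSUS_10 + cand[pos + 6 :]
            tag += "_pause"
        if not _unique_add(itr_seen, cand):
            continue
        emit("itr", _Backbone(bb.up, bb.hex35, bb.spacer, bb.hex10, bb.disc, cand), tag)
        emitted += 1

    frame = pd.DataFrame.from_records(records)
    if len(frame) != spec.total or frame["sequence"].nunique() != spec.total:
        raise RuntimeError(
            f"library generation produced {frame['sequence'].nunique()} unique variants, "
            f"expected {spec.total}"
        )
    return frame


@dataclass
class DesignObjective:
    """Target profile for the promoter annealer.

    ``targets`` maps construct positions (forward-strand TSS coordinates)
    to desired TX rates; the cost is the summed squared log-rate error at
    the targets plus ``off_target_penalty`` times the maximum off-target
    log rate.  Flanks are never mutated.
    """

    targets: Mapping[int, float]
    off_target_penalty: float = 0.0
    five_flank: str = ""
    three_flank: str = ""
    mutable_length: int = 75
    forbidden_motifs: Sequence[str] = ()
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.off_target_penalty < 0:
            raise ValueError("off-target penalty must be non-negative")
        if self.mutable_length < 1:
            raise ValueError("mutable window must be non-empty")


@dataclass
class DesignResult:
    sequence: str
    mutable_start: int
    mutable_end: int
    cost: float
    trace: list[float]
    profile: object  # TranscriptionProfile of the final construct


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the single-nucleotide annealer."""

    t_start: float = 2.0
    t_end: float = 0.01
    steps: int = 5000


def _anneal(
    initial: str,
    mutable: tuple[int, int],
    cost_fn,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
    propose=None,
    forbidden: Sequence[str] = (),
) -> tuple[str, float, list[float]]:
    """Generic simulated annealing over sequence space; returns best-so-far."""
    lo, hi = mutable
    seq = initial
    cost = cost_fn(seq)
    best_seq, best_cost = seq, cost
    trace = [cost]
    accepted_any = False
    ratio = (schedule.t_end / schedule.t_start) ** (1.0 / max(schedule.steps - 1, 1))
    temp = schedule.t_start
    for _ in range(schedule.steps):
        if propose is not None:
            cand = propose(seq, rng)
        else:
            pos = int(rng.integers(lo, hi))
            base = _BASES[int(rng.integers(0, 4))]
            cand = seq[:pos] + base + seq[pos + 1 :]
        if cand == seq or any(m in cand for m in forbidden):
            temp *= ratio
            trace.append(best_cost)
            continue
        assert cand[:lo] == initial[:lo] and cand[hi:] == initial[hi:]
        c = cost_fn(cand)
        if c < cost or rng.random() < math.exp(-(c - cost) / temp):
            seq, cost = cand, c
            accepted_any = True
            if c < best_cost:
                best_seq, best_cost = cand, c
        temp *= ratio
        trace.append(best_cost)
    if not accepted_any and schedule.steps > 0:
        raise RuntimeError("annealing frozen: no move accepted")
    return best_seq, best_cost, trace


def design_promoter(
    objective: DesignObjective,
    params: EnergyModelParams,
    tables: ShapeTables | None = None,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    initial: str | None = None,
) -> DesignResult:
    """Anneal a promoter toward desired rates at desired start sites.

    The mutable window sits between the fixed flanks; single-nucleotide
    substitution moves are accepted by the Metropolis rule under geometric
    cooling, and the best-so-far sequence is returned, so the reported cost
    is non-increasing along the trace.
    """
    tables = tables or load_default_tables()
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    lo = len(objective.five_flank)
    hi = lo + objective.mutable_length
    if initial is not None:
        if len(initial) != objective.mutable_length:
            raise ValueError("initial sequence must fill the mutable window")
        core = initial
    else:
        core = _rand_seq(rng, objective.mutable_length)
    start = objective.five_flank + core + objective.three_flank
    target_log = {p: math.log(tx) for p, tx in objective.targets.items()}
    compiled = CompiledModel(params, tables)

    def cost_fn(seq: str) -> float:
        if objective.off_target_penalty == 0:
            # only the target sites matter; skip the full profile scan
            cost = 0.0
            for pos, desired in target_log.items():
                _, bd = best_configuration(seq, pos, "forward", compiled)
                cost += (math.log(compiled.tx(bd.dg_total)) - desired) ** 2
            return cost
        profile = scan_profile(
            seq, params, tables=tables, both_strands=objective.both_strands
        )
        by_pos = {c.position: c for c in profile.forward}
        cost = 0.0
        for pos, desired in target_log.items():
            call = by_pos.get(pos)
            if call is None:
                raise ValueError(f"target TSS {pos} is not evaluable in this construct")
            cost += (math.log(call.tx_rate) - desired) ** 2
        if objective.off_target_penalty > 0:
            off = [
                math.log(c.tx_rate)
                for c in profile.forward + profile.reverse
                if c.position not in target_log
            ]
            if off:
                cost += objective.off_target_penalty * max(off)
        return cost

    seq, cost, trace = _anneal(
        start, (lo, hi), cost_fn, schedule, rng, forbidden=objective.forbidden_motifs
    )
    profile = scan_profile(seq, params, tables=tables, both_strands=objective.both_strands)
    return DesignResult(
        sequence=seq, mutable_start=lo, mutable_end=hi, cost=cost, trace=trace, profile=profile
    )


def _max_tx(seq: str, params: EnergyModelParams, tables: ShapeTables) -> float:
    profile = scan_profile(seq, params, tables=tables, both_strands=True)
    calls = profile.forward + profile.reverse
    return max((c.tx_rate for c in calls), default=0.0)


def minimize_tx_design(
    mode: str,
    input_sequence: str | int,
    params: EnergyModelParams,
    tables: ShapeTables | None = None,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    five_flank: str | None = None,
    three_flank: str | None = None,
) -> str:
    """Design transcriptionally silent DNA.

    ``no_promoter`` mode takes a target length (int) and anneals a sequence
    minimizing the maximum predicted rate on both strands within fixed
    flanking context.  ``cds_synonymous`` mode takes a protein coding
    sequence and swaps synonymous codons to the same end; the translation
    is preserved exactly.
    """
    tables = tables or load_default_tables()
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    if five_flank is None:
        five_flank = generate_background(70, seed=seed + 101)
    if three_flank is None:
        three_flank = generate_background(70, seed=seed + 202)

    if mode == "no_promoter":
        length = int(input_sequence)
        core = _rand_seq(rng, length)
        propose = None
    elif mode == "cds_synonymous":
        core = str(input_sequence).upper()
        if len(core) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        table = unambiguous_dna_by_id[1]
        if any(core[i : i + 3] in table.stop_codons for i in range(0, len(core) - 3, 3)):
            raise ValueError("internal stop codon in CDS")
        synonyms: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            synonyms.setdefault(aa, []).append(codon)
        lo_ = len(five_flank)

        def propose(seq: str, rng_: np.random.Generator) -> str:
            idx = int(rng_.integers(0, len(core) // 3)) * 3
            codon = seq[lo_ + idx : lo_ + idx + 3]
            if codon in table.stop_codons:
                return seq
            choices = synonyms[table.forward_table[codon]]
            new = choices[int(rng_.integers(0, len(choices)))]
            return seq[: lo_ + idx] + new + seq[lo_ + idx + 3 :]

    else:
        raise ValueError("mode must be 'no_promoter' or 'cds_synonymous'")

    lo = len(five_flank)
    hi = lo + len(core)
    start = five_flank + core + three_flank
    cost_fn = lambda seq: _max_tx(seq, params, tables)  # noqa: E731
    seq, _, _ = _anneal(start, (lo, hi), cost_fn, schedule, rng, propose=propose)
    designed = seq[lo:hi]
    if mode == "cds_synonymous":
        assert str(Seq(designed).translate()) == str(Seq(core).translate())
    return designed
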