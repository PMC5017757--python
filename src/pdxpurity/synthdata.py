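"""Synthetic inputs for the whole pipeline: genome homolog pairs with
embedded ssPAL loci, electropherograms, sequencing reads, and somatic
mutation truth sets.

Everything downstream (peak quantitation, hybrid alignment, virtual-PDX
construction, somatic-call benchmarking) runs on data produced here, so each
generator is deterministic for a fixed seed and records full ground truth.

The two-species model is deliberately simple: the human sequence is the
ancestor and the mouse homolog derives from it by i.i.d. substitutions at a
configurable per-base rate outside the ssPAL loci.  Inside each locus the
primer sites are kept identical between species and a single internal indel
shifts the amplicon to its mouse length, so both loci stay amplifiable and
species-resolvable by size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sspal import Electropherogram, SsPALLocus

# base encoding used throughout: A=0, C=1, G=2, T=3 (complement = 3 - code)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (A=0, C=1, G=2, T=3)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> DNA string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return decode(3 - encode(seq)[::-1])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusPlacement:
    """Where an ssPAL locus sits on the (human/ancestral) contig: the human
    amplicon occupies ``[offset, offset + locus.human_len)``."""

    locus: SsPALLocus
    offset: int


@dataclass
class GenomePairConfig:
    """Configuration for one human/mouse homologous contig pair."""

    length: int                      # bases of the human (ancestral) contig
    divergence: float = 0.10         # substitutions per base, in [0,1)
    loci: Sequence[LocusPlacement] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("contig length must be >= 1000 bases")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0,1)")
        spans = []
        for pl in self.loci:
            loc = pl.locus
            if pl.offset < 0 or pl.offset + loc.human_len > self.length:
                raise ValueError(f"{loc.pair_id}: locus outside genome")
            flank = len(loc.forward_primer) + len(loc.reverse_primer)
            if loc.human_len - flank <= abs(loc.mouse_len - loc.human_len) + 2:
                raise ValueError(f"{loc.pair_id}: amplicon interior too "
                                 "short for the inter-species indel")
            spans.append((pl.offset, pl.offset + loc.human_len))
        spans.sort()
        if any(b0 < a1 for (_, a1), (b0, _) in zip(spans, spans[1:])):
            raise ValueError("loci must not overlap")


@dataclass
class Contig:
    name: str
    species: str     # "human" | "mouse"
    sequence: str

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ValueError(f"bad species {self.species!r}")
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be non-empty over ACGT")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesGenome:
    """A set of named, species-labelled contigs."""

    contigs: list[Contig]

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")

    def get(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, species: str) -> "SpeciesGenome":
        return SpeciesGenome([c for c in self.contigs
                              if c.species == species])

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class SomaticMutation:
    """One spiked-in single-nucleotide somatic mutation with its true VAF."""

    contig: str
    pos: int        # 0-based
    ref: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError("ref/alt must be single ACGT bases")
        if not 0 < self.vaf <= 1:
            raise ValueError("vaf must lie in (0,1]")


@dataclass
class Read:
    """A simulated single-end read with full ground truth attached."""

    id: str
    sequence: str
    truth_species: str
    truth_contig: str
    truth_pos: int
    truth_strand: str   # "+" | "-"


@dataclass(frozen=True)
class TraceNoiseModel:
    """Noise model for synthetic electropherograms.

    ``peak_sigma`` is the Gaussian peak width in bp; ``noise_sd`` is the SD
    of additive i.i.d. Gaussian noise as a fraction of the tallest peak's
    height; ``baseline`` is a constant offset in intensity units.
    """

    peak_sigma: float = 0.4
    noise_sd: float = 0.002
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("noise_sd and baseline must be >= 0")


DEFAULT_NOISE = TraceNoiseModel()
NOISE_FREE = TraceNoiseModel(noise_sd=0.0)


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

def default_genome_config(length: int = 100_000, divergence: float = 0.10,
                          seed: int = 0) -> GenomePairConfig:
    """A convenient pair configuration carrying both built-in ssPAL loci."""
    from .sspal import PAIR5, PAIR43
    return GenomePairConfig(
        length=length, divergence=divergence, seed=seed,
        loci=(LocusPlacement(PAIR5, length // 4),
              LocusPlacement(PAIR43, 3 * length // 4)))


def make_genome_pair(config: GenomePairConfig,
                     human_name: str = "human_1",
                     mouse_name: str = "mouse_1",
                     ) -> tuple[SpeciesGenome, SpeciesGenome]:
    """Generate a homologous human/mouse contig pair.

    The human contig is uniform random ACGT with each configured locus's
    primer sites written in (forward primer at the amplicon start, reverse
    complement of the reverse primer at its end).  The mouse contig derives
    from the human one by i.i.d. substitutions at ``config.divergence``
    outside the loci; each locus is copied unchanged except for a single
    mid-amplicon indel that resizes it to the mouse amplicon length.
    """
    rng = np.random.default_rng(config.seed)
    human = rng.integers(0, 4, config.length, dtype=np.uint8)

    placements = sorted(config.loci, key=lambda pl: pl.offset)
    for pl in placements:
        loc = pl.locus
        fwd = encode(loc.forward_primer)
        rev_site = encode(revcomp(loc.reverse_primer))
        human[pl.offset:pl.offset + fwd.size] = fwd
        end = pl.offset + loc.human_len
        human[end - rev_site.size:end] = rev_site

    # substitutions outside loci: a substituted base always changes
    sub = rng.random(config.length) < config.divergence
    shifts = rng.integers(1, 4, config.length, dtype=np.uint8)
    for pl in placements:
        sub[pl.offset:pl.offset + pl.locus.human_len] = False
    mouse_flat = human.copy()
    mouse_flat[sub] = (mouse_flat[sub] + shifts[sub]) % 4

    # apply per-locus indels, assembling the mouse contig from segments
    segments: list[np.ndarray] = []
    cursor = 0
    for pl in placements:
        loc = pl.locus
        segments.append(mouse_flat[cursor:pl.offset])
        amp = human[pl.offset:pl.offset + loc.human_len].copy()
        delta = loc.mouse_len - loc.human_len
        mid = loc.human_len // 2
        if delta > 0:
            ins = rng.integers(0, 4, delta, dtype=np.uint8)
            amp = np.concatenate([amp[:mid], ins, amp[mid:]])
        elif delta < 0:
            amp = np.concatenate([amp[:mid + delta], amp[mid:]])
        segments.append(amp)
        cursor = pl.offset + loc.human_len
    segments.append(mouse_flat[cursor:])
    mouse = np.concatenate(segments) if segments else mouse_flat

    return (SpeciesGenome([Contig(human_name, "human", decode(human))]),
            SpeciesGenome([Contig(mouse_name, "mouse", decode(mouse))]))


def amplicon_length(genome: SpeciesGenome, locus: SsPALLocus) -> int:
    """Measure the amplicon length of ``locus`` in a genome by locating the
    primer annealing sites (first occurrence of the forward primer through
    the end of the reverse-primer site)."""
    rev_site = revcomp(locus.reverse_primer)
    for contig in genome.contigs:
        start = contig.sequence.find(locus.forward_primer)
        if start < 0:
            continue
        hit = contig.sequence.find(rev_site, start)
        if hit < 0:
            continue
        return hit + len(rev_site) - start
    raise ValueError(f"{locus.pair_id}: primer sites not found")


# ---------------------------------------------------------------------------
# electropherograms
# ---------------------------------------------------------------------------

#: fragment-size grid step (bp) for synthetic traces
TRACE_STEP_BP = 0.1
#: margin (bp) added on either side of the amplicon sizes
TRACE_MARGIN_BP = 15.0
#: total peak area shared by the two species (intensity * bp)
TRACE_TOTAL_AREA = 1000.0


def synth_electropherogram(locus: SsPALLocus, mouse_fraction: float,
                           noise: TraceNoiseModel = DEFAULT_NOISE,
                           ) -> Electropherogram:
    """Synthesize a two-peak trace whose peak areas are proportional to the
    murine and human template amounts.

    The trace lives on a 0.1 bp size grid spanning both amplicon sizes plus
    a 15 bp margin, and equals ``baseline`` + a Gaussian at the mouse
    amplicon size with area proportional to ``mouse_fraction`` + a Gaussian
    at the human size with area proportional to ``1 - mouse_fraction`` +
    i.i.d. Gaussian noise, truncated at zero.
    """
    if not 0 <= mouse_fraction <= 1:
        raise ValueError("mouse_fraction must lie in [0,1]")
    lo = min(locus.human_len, locus.mouse_len) - TRACE_MARGIN_BP
    hi = max(locus.human_len, locus.mouse_len) + TRACE_MARGIN_BP
    n = int(round((hi - lo) / TRACE_STEP_BP)) + 1
    sizes = lo + TRACE_STEP_BP * np.arange(n)
    sigma = noise.peak_sigma
    norm = sigma * math.sqrt(2 * math.pi)
    amp_mouse = TRACE_TOTAL_AREA * mouse_fraction / norm
    amp_human = TRACE_TOTAL_AREA * (1 - mouse_fraction) / norm
    y = np.full(n, noise.baseline, dtype=float)
    y += amp_mouse * np.exp(-0.5 * ((sizes - locus.mouse_len) / sigma) ** 2)
    y += amp_human * np.exp(-0.5 * ((sizes - locus.human_len) / sigma) ** 2)
    if noise.noise_sd > 0:
        rng = np.random.default_rng(noise.seed)
        y += rng.normal(0.0, noise.noise_sd * max(amp_mouse, amp_human), n)
    np.clip(y, 0.0, None, out=y)
    return Electropherogram(pair_id=locus.pair_id, sizes=sizes, intensities=y)


# ---------------------------------------------------------------------------
# somatic mutation truth sets
# ---------------------------------------------------------------------------

def spike_mutation_set(genome: SpeciesGenome, n: int,
                       vafs: Sequence[float], seed: int,
                       ) -> list[SomaticMutation]:
    """Sample ``n`` distinct SNV positions uniformly on the human contigs.

    The alternate base is drawn uniformly from the three non-reference
    bases; VAFs are cycled from ``vafs`` over the position-sorted mutations
    (so ``n`` divisible by ``len(vafs)`` gives an exactly balanced design).
    """
    human = [c for c in genome.contigs if c.species == "human"]
    if not human:
        raise ValueError("genome has no human contigs")
    if not vafs or any(not 0 < v <= 1 for v in vafs):
        raise ValueError("vafs must be non-empty fractions in (0,1]")
    total = sum(len(c) for c in human)
    if n > total:
        raise ValueError(f"n={n} exceeds {total} eligible positions")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    flat = np.sort(rng.choice(total, size=n, replace=False))
    bounds = np.cumsum([0] + [len(c) for c in human])
    muts: list[SomaticMutation] = []
    for i, fp in enumerate(flat):
        ci = int(np.searchsorted(bounds, fp, side="right")) - 1
        pos = int(fp - bounds[ci])
        ref = human[ci].sequence[pos]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        muts.append(SomaticMutation(contig=human[ci].name, pos=pos,
                                    ref=ref, alt=alt,
                                    vaf=float(vafs[i % len(vafs)])))
    return muts


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(genome: SpeciesGenome, mean_depth: float, read_len: int,
                   error_rate: float, seed: int) -> list[Read]:
    """Simulate uniform-coverage single-end reads with i.i.d. substitution
    errors.

    Per contig, ``round(mean_depth * contig_length / read_len)`` reads are
    drawn with uniform start positions on ``[0, L - read_len]`` and uniform
    strand; minus-strand reads report the reverse complement.  Truth fields
    (species, contig, 0-based start, strand) are recorded on every read.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must lie in [0,1)")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for contig in genome.contigs:
        L = len(contig)
        if read_len > L:
            raise ValueError(f"read_len {read_len} exceeds contig "
                             f"{contig.name} ({L} bp)")
        n = int(round(mean_depth * L / read_len))
        if n == 0:
            continue
        codes = encode(contig.sequence)
        starts = rng.integers(0, L - read_len + 1, size=n)
        minus = rng.random(n) < 0.5
        mat = codes[starts[:, None] + np.arange(read_len)[None, :]].copy()
        mat[minus] = 3 - mat[minus, ::-1]
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            shifts = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
            mat[err] = (mat[err] + shifts[err]) % 4
        chars = _BASES[mat]
        for i in range(n):
            reads.append(Read(
                id=f"{contig.name}:{i}",
                sequence=chars[i].tobytes().decode("ascii"),
                truth_species=contig.species,
                truth_contig=contig.name,
                truth_pos=int(starts[i]),
                truth_strand="-" if minus[i] else "+"))
    return reads
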