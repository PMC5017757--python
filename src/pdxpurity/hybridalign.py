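"""Hybrid two-species reference alignment and coverage.

Sequencing reads from a xenograft are a mixture of human (tumor) and mouse
(stroma) molecules.  Aligning against a *hybrid* reference -- every human
and mouse contig concatenated into a single alignment target -- lets each
read compete for its best placement across both species, after which reads
placed on mouse contigs (and reads with several equally good placements,
which carry no reliable species assignment) are excluded from human-side
analysis.

The aligner is a deliberately small exact-seed / ungapped-extend design:
``k``-mer seeds at three fixed read offsets (start, middle, end) on both
strands nominate candidate placements, each candidate is scored by
full-length ungapped comparison, and the best score wins.  Score is
``matches - mismatches``; a tie among best placements defines ``ambiguous``
and a best placement with more than ``max_mismatch`` mismatches defines
``unmapped``.  No gapped alignment is attempted: the read simulator
introduces no indels outside the ssPAL loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synthdata import Read, SpeciesGenome, encode

DEFAULT_K = 15
#: default mismatch budget as a fraction of read length
DEFAULT_MAX_MISMATCH_FRAC = 0.10
#: coverage summary thresholds (x-fold)
DEFAULT_COVERAGE_THRESHOLDS = (1, 5, 10, 15, 20, 30)


@dataclass
class RefContig:
    name: str
    species: str
    codes: np.ndarray    # uint8 A=0,C=1,G=2,T=3

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass
class HybridReference:
    """Concatenated reference with an exact k-mer index over both strands.

    ``index`` maps a k-mer (as bytes of base codes) to a list of
    ``(contig_index, position, strand)``; a ``-`` entry at position ``p``
    means the k-mer equals the reverse complement of the reference k-mer
    starting at ``p``.
    """

    contigs: list[RefContig]
    k: int
    index: dict[bytes, list[tuple[int, int, str]]]

    def contig_idx(self, name: str) -> int:
        for i, c in enumerate(self.contigs):
            if c.name == name:
                return i
        raise KeyError(name)

    def species_of(self, name: str) -> str:
        return self.contigs[self.contig_idx(name)].species


@dataclass
class AlignmentRecord:
    read_id: str
    contig: str | None
    pos: int
    strand: str
    score: int
    n_best: int
    status: str    # unique | ambiguous | unmapped


@dataclass
class CoverageProfile:
    """Per-base depth over one contig plus summary statistics."""

    contig: str
    depth: np.ndarray
    mean_doc: float
    frac_ge: dict[int, float]


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def build_reference(human: SpeciesGenome,
                    mouse: SpeciesGenome | None = None,
                    k: int = DEFAULT_K) -> HybridReference:
    """Build a (hybrid or human-only) reference with a full two-strand
    k-mer index.  ``k`` must lie in [11, 31]."""
    if not 11 <= k <= 31:
        raise ValueError("k must lie in [11, 31]")
    contig_sets = [human] + ([mouse] if mouse is not None else [])
    names = [c.name for g in contig_sets for c in g.contigs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names across the reference")
    contigs: list[RefContig] = []
    index: dict[bytes, list[tuple[int, int, str]]] = {}
    for g in contig_sets:
        for c in g.contigs:
            ci = len(contigs)
            codes = encode(c.sequence)
            contigs.append(RefContig(c.name, c.species, codes))
            fwd = codes.tobytes()
            rev = (3 - codes[::-1]).tobytes()
            L = codes.size
            for p in range(L - k + 1):
                index.setdefault(fwd[p:p + k], []).append((ci, p, "+"))
                index.setdefault(rev[L - k - p:L - p], []).append((ci, p, "-"))
    return HybridReference(contigs=contigs, k=k, index=index)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_read(read: Read, ref: HybridReference,
               max_mismatch: int | None = None) -> AlignmentRecord:
    """Place one read on the reference by seed-and-extend.

    Exact k-mer seeds are taken at the read start, middle and end; hits on
    either strand nominate candidate (contig, start, strand) placements,
    each scored by ungapped full-length comparison.  ``max_mismatch``
    defaults to 10% of the read length.
    """
    L = len(read.sequence)
    k = ref.k
    if L < k:
        raise ValueError(f"read shorter than k={k}")
    if max_mismatch is None:
        max_mismatch = int(DEFAULT_MAX_MISMATCH_FRAC * L)
    codes = encode(read.sequence)
    rc = 3 - codes[::-1]
    fwd_bytes = codes.tobytes()
    cands: set[tuple[int, int, str]] = set()
    for o in {0, (L - k) // 2, L - k}:
        for ci, p, strand in ref.index.get(fwd_bytes[o:o + k], ()):
            start = p - o if strand == "+" else p - (L - k - o)
            cands.add((ci, start, strand))
    best_mm = L + 1
    best: list[tuple[int, int, str]] = []
    for ci, start, strand in cands:
        arr = ref.contigs[ci].codes
        if start < 0 or start + L > arr.size:
            continue
        query = codes if strand == "+" else rc
        mm = int(np.count_nonzero(arr[start:start + L] != query))
        if mm < best_mm:
            best_mm, best = mm, [(ci, start, strand)]
        elif mm == best_mm:
            best.append((ci, start, strand))
    if not best or best_mm > max_mismatch:
        return AlignmentRecord(read_id=read.id, contig=None, pos=-1,
                               strand=".", score=0, n_best=0,
                               status="unmapped")
    ci, start, strand = min(best)
    return AlignmentRecord(
        read_id=read.id, contig=ref.contigs[ci].name, pos=start,
        strand=strand, score=(L - best_mm) - best_mm, n_best=len(best),
        status="unique" if len(best) == 1 else "ambiguous")


def align_reads(reads: Iterable[Read], ref: HybridReference,
                max_mismatch: int | None = None) -> list[AlignmentRecord]:
    """Align a collection of reads (thin loop over :func:`align_read`)."""
    return [align_read(r, ref, max_mismatch) for r in reads]


def exclude_mouse(alignments: Iterable[AlignmentRecord],
                  ref: HybridReference) -> list[AlignmentRecord]:
    """Drop mouse-placed and ambiguous records.

    Only uniquely placed records on human contigs survive; ambiguous
    (multi-mapping) records carry no reliable species assignment and are
    removed entirely rather than assigned at random.
    """
    return [a for a in alignments
            if a.status == "unique" and a.contig is not None
            and ref.species_of(a.contig) == "human"]


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def coverage(ref: HybridReference, alignments: Iterable[AlignmentRecord],
             contig: str, read_len: int,
             thresholds: Sequence[int] = DEFAULT_COVERAGE_THRESHOLDS,
             ) -> CoverageProfile:
    """Per-base depth of coverage on one contig from fixed-length records.

    ``frac_ge[t]`` is the fraction of bases with depth >= t; the threshold
    15 is always included.
    """
    ci = ref.contig_idx(contig)   # raises KeyError for an unknown contig
    L = len(ref.contigs[ci])
    diff = np.zeros(L + 1, dtype=np.int64)
    for a in alignments:
        if a.contig != contig:
            continue
        if a.pos < 0 or a.pos + read_len > L:
            raise ValueError(f"record {a.read_id} extends beyond {contig}")
        diff[a.pos] += 1
        diff[a.pos + read_len] -= 1
    depth = np.cumsum(diff[:-1])
    ts = sorted(set(thresholds) | {15})
    frac_ge = {int(t): float(np.count_nonzero(depth >= t) / L) for t in ts}
    return CoverageProfile(contig=contig, depth=depth,
                           mean_doc=float(depth.sum() / L), frac_ge=frac_ge)
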