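"""Virtual-sample construction: virtual normal, virtual tumor, virtual
xenograft.

The effect of mouse-read contamination on somatic mutation calling is
studied on three simulated samples built from the same synthetic human
genome:

* **virtual normal** -- plain human reads at the normal depth (30x by
  convention), used as the matched normal in somatic calling;
* **virtual tumor** -- an independently simulated human read set at the
  tumor depth (60x) into which a fully known somatic mutation profile is
  spiked at chosen variant allele frequencies;
* **virtual xenograft** -- the virtual tumor with each read independently
  replaced, with probability ``lambda`` (the contamination level), by a
  mouse read drawn without replacement from a mouse read pool.  The total
  read count is preserved exactly, so contamination manifests downstream as
  loss of human depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .synthdata import Read, SomaticMutation, SpeciesGenome, simulate_reads

logger = logging.getLogger("pdxpurity.virtualpdx")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ContaminationConfig:
    """The grid of contamination levels to sweep, plus the master seed."""

    lambdas: Sequence[float]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lambdas) == 0:
            raise ValueError("lambda grid must be non-empty")
        if any(not 0 <= lam <= 1 for lam in self.lambdas):
            raise ValueError("every lambda must lie in [0,1]")


@dataclass
class VirtualSample:
    label: str               # virtual_normal | virtual_tumor | virtual_xenograft
    reads: list[Read]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("virtual_normal", "virtual_tumor",
                              "virtual_xenograft"):
            raise ValueError(f"bad sample label {self.label!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def downsample(reads: Sequence[Read], current_depth: float,
               target_depth: float, seed: int) -> list[Read]:
    """Thin a read set from ``current_depth`` to ``target_depth`` by keeping
    each read independently with probability ``target/current``."""
    if target_depth > current_depth:
        raise ValueError("target depth exceeds current depth")
    if current_depth <= 0:
        raise ValueError("current depth must be positive")
    p = target_depth / current_depth
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < p
    return [r for r, k in zip(reads, keep) if k]


def spike_reads(reads: Sequence[Read], mutations: Sequence[SomaticMutation],
                seed: int) -> list[Read]:
    """Introduce known somatic mutations directly into reads.

    For each mutation, every read whose truth interval covers the mutated
    position has the covering base switched to the alternate allele
    independently with probability ``vaf`` (strand-aware: minus-strand reads
    receive the complement at the mirrored offset).  Reads not overlapping
    any mutation are returned byte-identical.
    """
    rng = np.random.default_rng(seed)
    out = list(reads)
    edited: dict[int, bytearray] = {}
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in {r.truth_contig for r in reads}:
        idx = np.array([i for i, r in enumerate(reads)
                        if r.truth_contig == name])
        order = np.argsort([reads[i].truth_pos for i in idx],
                           kind="stable")
        idx = idx[order]
        starts = np.array([reads[i].truth_pos for i in idx])
        by_contig[name] = (idx, starts)
    for mut in mutations:
        if mut.contig not in by_contig:
            logger.warning("mutation %s:%d on a contig absent from the "
                           "reads; skipped", mut.contig, mut.pos)
            continue
        idx, starts = by_contig[mut.contig]
        j = int(np.searchsorted(starts, mut.pos, side="right"))
        for i in idx[:j][::-1]:
            r = reads[i]
            off = mut.pos - r.truth_pos
            if off >= len(r.sequence):
                break   # fixed-length reads: earlier starts lie even farther
            if off < 0:
                continue
            if rng.random() >= mut.vaf:
                continue
            buf = edited.setdefault(i, bytearray(r.sequence, "ascii"))
            if r.truth_strand == "+":
                buf[off] = ord(mut.alt)
            else:
                buf[len(buf) - 1 - off] = ord(_COMP[mut.alt])
    for i, buf in edited.items():
        out[i] = replace(reads[i], sequence=buf.decode("ascii"))
    return out


def contaminate(tumor_reads: Sequence[Read], mouse_reads: Sequence[Read],
                lam: float, seed: int) -> VirtualSample:
    """Replace tumor reads with mouse reads at contamination level ``lam``.

    Each tumor read is independently replaced with probability ``lam`` by a
    mouse read drawn without replacement from the pool; the total read count
    is preserved exactly.  Raises if the pool is too shallow, reporting the
    required pool size.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0,1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(len(tumor_reads)) < lam
    need = int(mask.sum())
    if need > len(mouse_reads):
        raise ValueError(f"mouse read pool exhausted: need {need}, "
                         f"have {len(mouse_reads)}")
    picks = rng.permutation(len(mouse_reads))[:need]
    out = list(tumor_reads)
    for slot, pick in zip(np.flatnonzero(mask), picks):
        out[slot] = mouse_reads[pick]
    return VirtualSample(
        label="virtual_xenograft", reads=out,
        provenance={"lambda": float(lam), "n_reads": len(out),
                    "n_replaced": need, "seed": int(seed)})


# ---------------------------------------------------------------------------
# sample builders
# ---------------------------------------------------------------------------

def build_virtual_samples(human: SpeciesGenome, mouse: SpeciesGenome,
                          mutations: Sequence[SomaticMutation],
                          normal_doc: float = 30.0, tumor_doc: float = 60.0,
                          read_len: int = 100, error_rate: float = 0.001,
                          mouse_pool_factor: float = 1.2, seed: int = 0,
                          ) -> tuple[VirtualSample, VirtualSample, list[Read]]:
    """Build (virtual normal, virtual tumor, mouse read pool).

    Normal and tumor derive from two independently seeded simulations of the
    same human genome; each is simulated at twice its target depth and then
    downsampled to it, mirroring the downsample step of real pipelines.  The
    mouse pool is sized at ``mouse_pool_factor * tumor_doc`` so that even
    near-total contamination can be drawn without replacement.
    """
    ss = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    normal_reads = downsample(
        simulate_reads(human, 2 * normal_doc, read_len, error_rate, seeds[0]),
        2 * normal_doc, normal_doc, seeds[1])
    tumor_base = downsample(
        simulate_reads(human, 2 * tumor_doc, read_len, error_rate, seeds[2]),
        2 * tumor_doc, tumor_doc, seeds[3])
    tumor_reads = spike_reads(tumor_base, mutations, seeds[4])
    mouse_pool = simulate_reads(mouse, mouse_pool_factor * tumor_doc,
                                read_len, error_rate, seeds[0])
    normal = VirtualSample("virtual_normal", normal_reads,
                           {"doc": normal_doc, "read_len": read_len})
    tumor = VirtualSample("virtual_tumor", tumor_reads,
                          {"doc": tumor_doc, "read_len": read_len,
                           "n_mutations": len(mutations)})
    return normal, tumor, mouse_pool
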