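"""Somatic variant calling on virtual samples and its evaluation against
the known truth set, including the contamination sweep.

The caller is a transparent binomial tumor-vs-normal test standing in for a
production somatic caller: a site is called when the tumor pileup is deep
enough, carries enough alternate reads, the alternate count is inconsistent
with sequencing error (upper-tail binomial test at per-base error rate
``e/3`` toward any one specific alternate base), and the matched normal is
clean at that site (germline/artifact exclusion).  Calls are scored against
the spiked-in truth set as precision / recall / F1, overall and per VAF bin,
and a sweep over contamination levels lambda reproduces the depth-loss ->
lost-subclonal-sensitivity effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .hybridalign import (AlignmentRecord, CoverageProfile, HybridReference,
                          align_reads, build_reference, coverage,
                          exclude_mouse)
from .synthdata import (GenomePairConfig, Read, SomaticMutation,
                        SpeciesGenome, encode, make_genome_pair,
                        spike_mutation_set)
from .virtualpdx import (ContaminationConfig, VirtualSample,
                         build_virtual_samples, contaminate)

logger = logging.getLogger("pdxpurity.somaticeval")

#: default half-open VAF bins partitioning (0, 1]
DEFAULT_VAF_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.1), (0.1, 0.2), (0.2, 0.33), (0.33, 1.0))


@dataclass
class CallerParams:
    """Binomial tumor-vs-normal caller parameters."""

    min_tumor_depth: int = 10
    min_alt: int = 3
    error_rate: float = 0.01     # assumed per-base sequencing error
    alpha: float = 1e-3          # per-site binomial tail threshold
    normal_max_alt_frac: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must lie in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")


@dataclass
class Pileup:
    """Base counts at one covered reference position."""

    contig: str
    pos: int
    base_counts: tuple[int, int, int, int]   # A, C, G, T

    @property
    def depth(self) -> int:
        return sum(self.base_counts)


@dataclass
class VariantCall:
    contig: str
    pos: int       # 0-based
    ref: str
    alt: str
    depth: int
    alt_count: int
    p_value: float


@dataclass
class EvalPoint:
    """Precision/recall/F1 at one (contamination, VAF-bin) cell.

    Conventions for empty cells: precision is 1 when nothing was called and
    nothing was missed (tp+fp = 0 and fn = 0), else 0 when tp+fp = 0;
    recall is 1 when the bin holds no truth (tp+fn = 0); F1 is 0 when both
    precision and recall are 0.
    """

    lam: float | None
    vaf_bin: tuple[float, float]
    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp == 0:
            self.precision = 1.0 if self.fn == 0 else 0.0
        else:
            self.precision = self.tp / (self.tp + self.fp)
        self.recall = 1.0 if self.tp + self.fn == 0 \
            else self.tp / (self.tp + self.fn)
        s = self.precision + self.recall
        self.f1 = 0.0 if s == 0 else 2 * self.precision * self.recall / s


class PileupTable:
    """Dense per-contig base-count arrays (shape ``(4, L)``, rows A,C,G,T)."""

    def __init__(self, counts: dict[str, np.ndarray]):
        self.counts = counts

    @classmethod
    def empty(cls, contig_lengths: Mapping[str, int]) -> "PileupTable":
        return cls({name: np.zeros((4, L), dtype=np.int32)
                    for name, L in contig_lengths.items()})

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=0)

    def sites(self) -> list[Pileup]:
        """Covered positions as :class:`Pileup` records (depth 0 omitted)."""
        out: list[Pileup] = []
        for name, c in self.counts.items():
            for pos in np.flatnonzero(c.sum(axis=0) > 0):
                out.append(Pileup(contig=name, pos=int(pos),
                                  base_counts=tuple(int(v)
                                                    for v in c[:, pos])))
        return out


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def pileup(alignments: Iterable[AlignmentRecord], reads: Sequence[Read],
           reference: HybridReference) -> PileupTable:
    """Accumulate per-base A/C/G/T counts from uniquely placed reads.

    Minus-strand records contribute the reverse complement of the read so
    that counts are always in reference orientation.
    """
    by_id = {r.id: r for r in reads}
    table = PileupTable.empty({c.name: len(c) for c in reference.contigs
                               if c.species == "human"})
    for a in alignments:
        if a.status != "unique" or a.contig not in table.counts:
            continue
        read = by_id.get(a.read_id)
        if read is None:
            raise ValueError(f"alignment {a.read_id} has no matching read")
        codes = encode(read.sequence)
        if a.strand == "-":
            codes = 3 - codes[::-1]
        counts = table.counts[a.contig]
        np.add.at(counts, (codes, np.arange(a.pos, a.pos + codes.size)), 1)
    return table


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _ref_codes(reference, contig: str) -> np.ndarray:
    if isinstance(reference, HybridReference):
        return reference.contigs[reference.contig_idx(contig)].codes
    if isinstance(reference, SpeciesGenome):
        return encode(reference.get(contig).sequence)
    raise TypeError("reference must be a HybridReference or SpeciesGenome")


def call_somatic(tumor: PileupTable, normal: PileupTable, reference,
                 params: CallerParams | None = None) -> list[VariantCall]:
    """Binomial tumor-vs-normal somatic SNV calling.

    A site is called iff (i) tumor depth >= ``min_tumor_depth``, (ii) the
    top non-reference allele has >= ``min_alt`` reads, (iii) the upper-tail
    binomial probability ``P(X >= alt_count | n=depth, p=error_rate/3)`` is
    below ``alpha``, and (iv) the matched normal carries that allele at a
    fraction <= ``normal_max_alt_frac`` (a site with zero normal depth
    counts as clean; real pipelines would flag it instead).
    """
    params = params or CallerParams()
    calls: list[VariantCall] = []
    for contig, counts in tumor.counts.items():
        refc = _ref_codes(reference, contig)
        if refc.size != counts.shape[1]:
            raise ValueError(f"{contig}: pileup/reference length mismatch")
        depth = counts.sum(axis=0)
        masked = counts.copy()
        masked[refc, np.arange(refc.size)] = -1
        alt = masked.argmax(axis=0)
        alt_count = masked[alt, np.arange(refc.size)]
        cand = np.flatnonzero((depth >= params.min_tumor_depth)
                              & (alt_count >= params.min_alt))
        if cand.size == 0:
            continue
        pvals = _stats.binom.sf(alt_count[cand] - 1, depth[cand],
                                params.error_rate / 3.0)
        ncounts = normal.counts.get(contig)
        for pos, p in zip(cand, pvals):
            if p >= params.alpha:
                continue
            a = int(alt[pos])
            if ncounts is not None:
                nd = int(ncounts[:, pos].sum())
                na = int(ncounts[a, pos])
                nfrac = na / nd if nd > 0 else 0.0
                if nfrac > params.normal_max_alt_frac:
                    continue
            calls.append(VariantCall(
                contig=contig, pos=int(pos), ref="ACGT"[int(refc[pos])],
                alt="ACGT"[a], depth=int(depth[pos]),
                alt_count=int(alt_count[pos]), p_value=float(p)))
    return calls


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _check_bins(bins: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    bs = sorted((float(a), float(b)) for a, b in bins)
    if any(b <= a for a, b in bs):
        raise ValueError("each bin must be a non-empty (lo, hi] interval")
    if any(b0 != a1 for (_, b0), (a1, _) in zip(bs, bs[1:])):
        raise ValueError("bins must be contiguous and non-overlapping")
    if bs[0][0] != 0.0 or bs[-1][1] != 1.0:
        raise ValueError("bins must partition (0, 1]")
    return bs


def _bin_of(value: float, bins: Sequence[tuple[float, float]]) -> tuple[float, float]:
    for lo, hi in bins:
        if lo < value <= hi:
            return (lo, hi)
    return bins[0]   # value <= 0 can only arise from degenerate input


def evaluate(calls: Sequence[VariantCall], truth: Sequence[SomaticMutation],
             vaf_bins: Sequence[tuple[float, float]] = DEFAULT_VAF_BINS,
             lam: float | None = None) -> list[EvalPoint]:
    """Score calls against the truth set, per VAF bin and overall.

    A call is a TP iff (contig, pos, alt) exactly matches a truth entry;
    otherwise it is an FP, binned by its *observed* alternate fraction.
    Truth entries never called are FNs, binned (like TPs) by their true VAF.
    The last returned point is the overall (0, 1] summary.
    """
    bins = _check_bins(vaf_bins)
    truth_by_key = {(m.contig, m.pos, m.alt): m for m in truth}
    if len(truth_by_key) != len(truth):
        raise ValueError("duplicate truth entries")
    tp = {b: 0 for b in bins}
    fp = {b: 0 for b in bins}
    fn = {b: 0 for b in bins}
    hit: set[tuple[str, int, str]] = set()
    for c in calls:
        key = (c.contig, c.pos, c.alt)
        m = truth_by_key.get(key)
        if m is not None and key not in hit:
            tp[_bin_of(m.vaf, bins)] += 1
            hit.add(key)
        elif m is None:
            fp[_bin_of(c.alt_count / c.depth if c.depth else 0.0,
                       bins)] += 1
    for key, m in truth_by_key.items():
        if key not in hit:
            fn[_bin_of(m.vaf, bins)] += 1
    points = [EvalPoint(lam=lam, vaf_bin=b, tp=tp[b], fp=fp[b], fn=fn[b])
              for b in bins]
    points.append(EvalPoint(lam=lam, vaf_bin=(0.0, 1.0),
                            tp=sum(tp.values()), fp=sum(fp.values()),
                            fn=sum(fn.values())))
    return points


def eval_table(points: Iterable[EvalPoint]) -> pd.DataFrame:
    """Tidy DataFrame (lambda, vaf_lo, vaf_hi, tp, fp, fn, precision,
    recall, f1) from evaluation points."""
    return pd.DataFrame(
        [{"lambda": p.lam, "vaf_lo": p.vaf_bin[0], "vaf_hi": p.vaf_bin[1],
          "tp": p.tp, "fp": p.fp, "fn": p.fn, "precision": p.precision,
          "recall": p.recall, "f1": p.f1} for p in points])


# ---------------------------------------------------------------------------
# contamination sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    table: pd.DataFrame                       # one row per (lambda, bin)
    coverage: dict[float, CoverageProfile]    # human-contig DoC per lambda
    calls: dict[float, list[VariantCall]]
    truth: list[SomaticMutation]


def contamination_sweep(config: ContaminationConfig,
                        genome_cfg: GenomePairConfig,
                        n_mutations: int = 80,
                        vafs: Sequence[float] = (0.05, 0.1, 0.2, 0.5),
                        normal_doc: float = 30.0, tumor_doc: float = 60.0,
                        read_len: int = 100, error_rate: float = 0.001,
                        k: int = 15, caller: CallerParams | None = None,
                        vaf_bins: Sequence[tuple[float, float]] = DEFAULT_VAF_BINS,
                        ) -> SweepResult:
    """Full virtual-PDX benchmark over a contamination grid.

    For each lambda: build the virtual xenograft, align every read to the
    hybrid reference, exclude mouse-placed and ambiguous reads, pile up,
    call somatic variants against the matched virtual normal, and score
    against the truth set.  The per-lambda child seeds derive from
    ``config.seed`` via ``numpy`` SeedSequence spawning, so a single lambda
    can be rerun reproducibly.

    Because a read's best placement does not depend on which sample it sits
    in, tumor and mouse-pool reads are aligned once and their records reused
    across the lambda grid.
    """
    caller = caller or CallerParams()
    bins = _check_bins(vaf_bins)
    master = np.random.SeedSequence(config.seed)
    seed_mut, seed_samples, *lam_seeds = (
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in master.spawn(2 + len(config.lambdas)))

    human, mouse = make_genome_pair(genome_cfg)
    ref = build_reference(human, mouse, k=k)
    truth = spike_mutation_set(human, n_mutations, vafs, seed_mut)
    normal, tumor, mouse_pool = build_virtual_samples(
        human, mouse, truth, normal_doc=normal_doc, tumor_doc=tumor_doc,
        read_len=read_len, error_rate=error_rate, seed=seed_samples)

    normal_keep = exclude_mouse(align_reads(normal.reads, ref), ref)
    normal_pt = pileup(normal_keep, normal.reads, ref)
    aln_cache = {r.id: a for r, a in
                 zip(tumor.reads, align_reads(tumor.reads, ref))}
    aln_cache.update({r.id: a for r, a in
                      zip(mouse_pool, align_reads(mouse_pool, ref))})

    human_contig = next(c.name for c in ref.contigs if c.species == "human")
    rows, cov, calls_by_lam = [], {}, {}
    for lam, lam_seed in zip(config.lambdas, lam_seeds):
        sample = contaminate(tumor.reads, mouse_pool, lam, lam_seed)
        keep = exclude_mouse([aln_cache[r.id] for r in sample.reads], ref)
        cov[lam] = coverage(ref, keep, human_contig, read_len)
        pt = pileup(keep, sample.reads, ref)
        calls = call_somatic(pt, normal_pt, ref, caller)
        calls_by_lam[lam] = calls
        rows.extend(evaluate(calls, truth, bins, lam=lam))
    return SweepResult(table=eval_table(rows), coverage=cov,
                       calls=calls_by_lam, truth=truth)


def plot_f1(table: pd.DataFrame, path) -> None:
    """Plot F1 vs contamination level, one line per VAF bin."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sub = table[(table["vaf_lo"] != 0.0) | (table["vaf_hi"] != 1.0)]
    for (lo, hi), grp in sub.groupby(["vaf_lo", "vaf_hi"]):
        grp = grp.sort_values("lambda")
        ax.plot(grp["lambda"], grp["f1"], marker="o",
                label=f"VAF ({lo:g}, {hi:g}]")
    ax.set_xlabel("mouse read contamination $\\lambda$")
    ax.set_ylabel("F1")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
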