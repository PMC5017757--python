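"""Mouse vs. human DNA quantitation from fragment-analysis traces (ssPAL).

ssPAL (species-specific PCR amplicon length) quantifies the murine and human
DNA content of a xenograft sample by PCR-amplifying orthologous loci whose
products differ slightly in length between the two species.  After capillary
electrophoresis, the two products appear as separate peaks in the
electropherogram, and the peak areas are proportional to the amounts of mouse
and human template DNA.  Two well-characterised primer pairs are built in:

* ``pair 5``  -- RPP38 region on human 10p13; 272 bp (human) / 278 bp (mouse)
* ``pair 43`` -- region downstream of RC3H2 on human 9q34; 211 bp (human) /
  206 bp (mouse)

This module takes a trace (or a pre-called peak table), calls peaks, assigns
them to species by fragment size, converts peak areas into mouse/human DNA
fractions, averages the two primer pairs, and applies the ">95% murine"
red-flag rule for suspected spontaneous mouse tumors.  Helpers cover dilution
series (sensitivity of the assay), passage series (stability of stromal
content over serial transplantation), and cohort summaries.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

logger = logging.getLogger("pdxpurity.sspal")

#: default peak-calling threshold, as a fraction of the tallest peak
DEFAULT_MIN_REL_HEIGHT = 0.005
#: default half-window (bp) used to match a peak centroid to an amplicon size
DEFAULT_TOL_BP = 1.5
#: peaks are integrated at most this far (bp) from the centroid
AREA_HALFWIDTH_BP = 3.0
#: local maxima closer than this (bp) are merged into one peak; must stay
#: below the smallest inter-species amplicon gap (5 bp for pair 43)
MIN_PEAK_SEPARATION_BP = 2.0
#: mouse fraction above which a sample is flagged as a suspected mouse tumor
MOUSE_ORIGIN_THRESHOLD = 0.95
#: assay sensitivity window; combined estimates outside it are censored
SENSITIVITY_RANGE = (0.01, 0.99)


class NoAmplificationError(ValueError):
    """Raised when neither a mouse nor a human peak is present."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SsPALLocus:
    """A primer pair amplifying orthologous mouse/human products of
    slightly different lengths."""

    pair_id: str
    forward_primer: str
    reverse_primer: str
    human_len: int
    mouse_len: int

    def __post_init__(self) -> None:
        if self.human_len <= 0 or self.mouse_len <= 0:
            raise ValueError("amplicon lengths must be positive")
        if self.human_len == self.mouse_len:
            raise ValueError("human and mouse amplicon lengths must differ")
        for p in (self.forward_primer, self.reverse_primer):
            if not p or set(p) - set("ACGT"):
                raise ValueError(f"primer must be non-empty over ACGT: {p!r}")

    @property
    def gap(self) -> float:
        """Absolute mouse/human amplicon size difference in bp."""
        return abs(self.human_len - self.mouse_len)


PAIR5 = SsPALLocus(
    pair_id="pair5",
    forward_primer="TCATTGGCTTAAAATGTGT",
    reverse_primer="TTTATTTTAAGGGGTTGTAATG",
    human_len=272,
    mouse_len=278,
)
PAIR43 = SsPALLocus(
    pair_id="pair43",
    forward_primer="CTATTCCTATAGCACAAAGG",
    reverse_primer="GATGGTGTACACCCATCATG",
    human_len=211,
    mouse_len=206,
)
BUILTIN_LOCI: dict[str, SsPALLocus] = {"pair5": PAIR5, "pair43": PAIR43}


@dataclass
class Electropherogram:
    """A capillary-electrophoresis trace: fluorescence vs. fragment size."""

    pair_id: str
    sizes: np.ndarray        # bp, strictly increasing
    intensities: np.ndarray  # fluorescence units, >= 0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.sizes.shape != self.intensities.shape or self.sizes.ndim != 1:
            raise ValueError("sizes and intensities must be 1-D and congruent")
        if self.sizes.size < 2:
            raise ValueError("trace needs at least two points")
        if not np.all(np.diff(self.sizes) > 0):
            raise ValueError("sizes must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Peak:
    """A called peak: fragment-size centroid, height, trapezoid area and the
    species it was assigned to (``unassigned`` until :func:`assign_species`)."""

    centroid: float
    height: float
    area: float
    bounds: tuple[float, float]
    species: str = "unassigned"

    def __post_init__(self) -> None:
        left, right = self.bounds
        if not (left < self.centroid < right):
            raise ValueError("centroid must lie strictly inside bounds")
        if self.area <= 0:
            raise ValueError("peak area must be positive")
        if self.species not in ("mouse", "human", "unassigned"):
            raise ValueError(f"bad species label {self.species!r}")


@dataclass
class FractionEstimate:
    """Per-primer-pair and pair-averaged mouse/human DNA fractions."""

    per_pair: dict[str, tuple[float, float]]   # pair_id -> (mouse, human)
    combined_mouse_fraction: float
    censor_flag: str = "none"                  # none | below_1pct | above_99pct

    def __post_init__(self) -> None:
        for pid, (mf, hf) in self.per_pair.items():
            if not math.isclose(mf + hf, 1.0, rel_tol=0, abs_tol=1e-12):
                raise ValueError(f"{pid}: fractions must sum to exactly 1")
        if self.censor_flag not in ("none", "below_1pct", "above_99pct"):
            raise ValueError(f"bad censor flag {self.censor_flag!r}")


@dataclass
class OriginCall:
    """Species-of-origin verdict from the pair-averaged murine fraction."""

    combined_mouse_fraction: float
    threshold: float
    verdict: str  # human_tumor | suspect_mouse


@dataclass
class PassageSeries:
    """Fraction estimates for one PDX line across serial passages."""

    line_id: str
    entries: list[tuple[int, FractionEstimate]]

    def __post_init__(self) -> None:
        passages = [p for p, _ in self.entries]
        if any(p < 0 for p in passages):
            raise ValueError("passage numbers must be >= 0")
        if any(b <= a for a, b in zip(passages, passages[1:])):
            raise ValueError("passages must be strictly increasing")


# ---------------------------------------------------------------------------
# peak calling and quantitation
# ---------------------------------------------------------------------------

def detect_peaks(trace: Electropherogram,
                 min_rel_height: float = DEFAULT_MIN_REL_HEIGHT) -> list[Peak]:
    """Call peaks in a trace.

    The median intensity is subtracted as baseline; local maxima rising above
    ``min_rel_height`` of the global maximum become peaks.  Each peak is
    integrated by the trapezoid rule between its flanking minima, capped at
    ``centroid +/- 3 bp``; the centroid is the intensity-weighted mean size
    inside those bounds.  Local maxima closer than
    :data:`MIN_PEAK_SEPARATION_BP` are merged (tallest wins), so additive
    noise cannot fragment one physical peak into several calls.  An all-zero
    (or all-constant) trace yields no peaks.
    """
    if not 0 < min_rel_height < 1:
        raise ValueError("min_rel_height must be in (0,1)")
    x = trace.sizes
    y = trace.intensities - np.median(trace.intensities)
    ymax = float(y.max())
    if ymax <= 0:
        return []
    sep = max(1, int(round(MIN_PEAK_SEPARATION_BP
                           / float(np.median(np.diff(x))))))
    idx, _ = _signal.find_peaks(y, height=min_rel_height * ymax,
                                distance=sep)
    if idx.size == 0:
        return []
    step = float(np.median(np.diff(x)))
    cap = max(1, int(round(AREA_HALFWIDTH_BP / step)))
    peaks: list[Peak] = []
    for j, i in enumerate(idx):
        prev = int(idx[j - 1]) if j > 0 else 0
        nxt = int(idx[j + 1]) if j + 1 < idx.size else y.size - 1
        left = prev + int(np.argmin(y[prev:i + 1])) if i > prev else i
        right = i + int(np.argmin(y[i:nxt + 1])) if nxt > i else i
        left = max(left, i - cap)
        right = min(right, i + cap)
        if right - left < 2:
            continue
        w = np.clip(y[left:right + 1], 0.0, None)
        area = float(np.trapezoid(w, x[left:right + 1]))
        if area <= 0 or w.sum() <= 0:
            continue
        centroid = float(np.sum(x[left:right + 1] * w) / np.sum(w))
        if not (x[left] < centroid < x[right]):
            continue
        peaks.append(Peak(centroid=centroid, height=float(y[i]), area=area,
                          bounds=(float(x[left]), float(x[right]))))
    peaks.sort(key=lambda p: p.centroid)
    return peaks


def assign_species(peaks: Sequence[Peak], locus: SsPALLocus,
                   tol: float = DEFAULT_TOL_BP) -> list[Peak]:
    """Label peaks mouse/human by proximity to the locus amplicon sizes.

    A peak is assigned to a species when its centroid lies within ``tol`` bp
    of that species' amplicon length; if several qualify, the largest-area
    peak wins and the rest stay unassigned.  ``tol`` must be strictly smaller
    than half the mouse/human size gap, otherwise assignment is ambiguous.
    """
    if not (0 < tol < locus.gap / 2):
        raise ValueError(
            f"tol must be in (0, {locus.gap / 2}) bp for {locus.pair_id}")
    out = [dataclasses.replace(p, species="unassigned") for p in peaks]
    for species, target in (("mouse", locus.mouse_len),
                            ("human", locus.human_len)):
        cands = [k for k, p in enumerate(out)
                 if abs(p.centroid - target) <= tol]
        if cands:
            best = max(cands, key=lambda k: out[k].area)
            out[best] = dataclasses.replace(out[best], species=species)
    return out


def estimate_fraction(peaks: Sequence[Peak],
                      pair_id: str | None = None) -> tuple[float, float]:
    """Peak areas -> (mouse_fraction, human_fraction).

    ``mouse_fraction = A_mouse / (A_mouse + A_human)``; a missing species peak
    contributes area 0.  Raises :class:`NoAmplificationError` when neither
    species peak is present.
    """
    a_mouse = sum(p.area for p in peaks if p.species == "mouse")
    a_human = sum(p.area for p in peaks if p.species == "human")
    if a_mouse + a_human <= 0:
        raise NoAmplificationError(
            f"no amplification{f' for {pair_id}' if pair_id else ''}")
    mf = a_mouse / (a_mouse + a_human)
    return mf, 1.0 - mf


def quant_trace(trace: Electropherogram, locus: SsPALLocus,
                min_rel_height: float = DEFAULT_MIN_REL_HEIGHT,
                tol: float = DEFAULT_TOL_BP) -> tuple[float, float]:
    """Full quantitation chain for one trace: detect, assign, estimate."""
    peaks = assign_species(detect_peaks(trace, min_rel_height), locus, tol)
    return estimate_fraction(peaks, locus.pair_id)


def combine_pairs(per_pair: Mapping[str, tuple[float, float]]) -> FractionEstimate:
    """Average the primer pairs' mouse fractions into one estimate.

    The combined value is the arithmetic mean of the available pairs'
    mouse fractions.  Estimates below 1% or above 99% murine are censored
    (the assay loses sensitivity outside that window).  A single available
    pair is used as-is, with a warning.
    """
    if not per_pair:
        raise ValueError("at least one primer pair is required")
    if len(per_pair) == 1:
        only = next(iter(per_pair))
        logger.warning("only one primer pair (%s) available; "
                       "combined estimate falls back to it", only)
    combined = float(np.mean([mf for mf, _ in per_pair.values()]))
    lo, hi = SENSITIVITY_RANGE
    flag = "below_1pct" if combined < lo else (
        "above_99pct" if combined > hi else "none")
    return FractionEstimate(per_pair=dict(per_pair),
                            combined_mouse_fraction=combined,
                            censor_flag=flag)


def classify_origin(est: FractionEstimate | float,
                    threshold: float = MOUSE_ORIGIN_THRESHOLD) -> OriginCall:
    """Apply the strict >95% murine rule for suspected mouse-origin tumors.

    The verdict is ``suspect_mouse`` iff the pair-averaged mouse fraction is
    *strictly* greater than ``threshold``; a value exactly at the threshold
    is still called ``human_tumor``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    combined = (est.combined_mouse_fraction
                if isinstance(est, FractionEstimate) else float(est))
    verdict = "suspect_mouse" if combined > threshold else "human_tumor"
    return OriginCall(combined_mouse_fraction=combined,
                      threshold=threshold, verdict=verdict)


# ---------------------------------------------------------------------------
# dilution series / passage series / cohorts
# ---------------------------------------------------------------------------

def dilution_series(locus: SsPALLocus, fractions: Sequence[float],
                    replicates: int, noise, seed: int,
                    min_rel_height: float = DEFAULT_MIN_REL_HEIGHT,
                    tol: float = DEFAULT_TOL_BP) -> pd.DataFrame:
    """Run the quantitation chain on synthetic pre-set mouse/human mixtures.

    For each true mouse fraction, ``replicates`` electropherograms are
    simulated with the given noise model and quantified.  Returns a table
    with columns ``true_fraction, mean_estimate, sd, detected_rate`` where
    ``detected_rate`` is the fraction of replicates in which a murine peak
    was detected at all.
    """
    from .synthdata import synth_electropherogram  # deferred: avoids cycle

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("fractions must lie in [0,1]")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        ests, detected = [], 0
        for _ in range(replicates):
            child = int(rng.integers(0, 2**31 - 1))
            trace = synth_electropherogram(
                locus, f, dataclasses.replace(noise, seed=child))
            peaks = assign_species(detect_peaks(trace, min_rel_height),
                                   locus, tol)
            if any(p.species == "mouse" for p in peaks):
                detected += 1
            try:
                mf, _ = estimate_fraction(peaks, locus.pair_id)
            except NoAmplificationError:
                continue
            ests.append(mf)
        rows.append({
            "true_fraction": float(f),
            "mean_estimate": float(np.mean(ests)) if ests else float("nan"),
            "sd": float(np.std(ests, ddof=1)) if len(ests) > 1 else 0.0,
            "detected_rate": detected / replicates,
        })
    return pd.DataFrame(rows).sort_values("true_fraction",
                                          ignore_index=True)


def detection_limit(table: pd.DataFrame, min_rate: float = 0.95) -> float:
    """Smallest tested mouse fraction detected in >= ``min_rate`` of
    replicates; NaN if no level qualifies."""
    ok = table[table["detected_rate"] >= min_rate]
    return float(ok["true_fraction"].min()) if len(ok) else float("nan")


def passage_stability(series: PassageSeries) -> dict:
    """Summarise the murine fraction of one PDX line over serial passages.

    Returns mean, sample SD, range (max - min) of the combined mouse
    fraction, plus the per-passage values for plotting.
    """
    if len(series.entries) < 2:
        raise ValueError("need at least two passages")
    values = np.array([e.combined_mouse_fraction for _, e in series.entries])
    return {
        "line_id": series.line_id,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "range": float(values.max() - values.min()),
        "per_passage": [(p, float(e.combined_mouse_fraction))
                        for p, e in series.entries],
    }


def cohort_summary(
    estimates: Mapping[str, tuple[FractionEstimate, str]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summarise a cohort of PDX lines.

    ``estimates`` maps line id -> (FractionEstimate, histology label).
    Returns (per-line table, per-histology group table, pairwise two-tailed
    t-test table between histology groups with >= 2 lines each).
    """
    if not estimates:
        raise ValueError("cohort is empty")
    lines = pd.DataFrame(
        [{"line_id": lid, "histology": hist,
          "combined_mouse_fraction": est.combined_mouse_fraction,
          "censor_flag": est.censor_flag}
         for lid, (est, hist) in estimates.items()])
    groups = (lines.groupby("histology")["combined_mouse_fraction"]
              .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
              .reset_index())
    pairs = []
    labels = sorted(lines["histology"].unique())
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va = lines.loc[lines["histology"] == a,
                           "combined_mouse_fraction"].to_numpy()
            vb = lines.loc[lines["histology"] == b,
                           "combined_mouse_fraction"].to_numpy()
            if len(va) >= 2 and len(vb) >= 2:
                t, p = _stats.ttest_ind(va, vb)
                pairs.append({"group_a": a, "group_b": b,
                              "t": float(t), "p_value": float(p)})
    return lines, groups, pd.DataFrame(pairs)


# ---------------------------------------------------------------------------
# published screening example
# ---------------------------------------------------------------------------

#: ssPAL peak-area percentages (murine %, human %) reported for four PDX
#: lines suspected of being spontaneous mouse tumors (all were subsequently
#: confirmed non-human).  Rows whose percentages do not sum to exactly 100
#: (rounding in the source report) are renormalized by their sum before use.
MOUSE_ORIGIN_SCREEN: dict[str, dict[str, tuple[float, float]]] = {
    "JHU-LX82": {"pair5": (99.4, 0.6), "pair43": (98.4, 1.7)},
    "JHU-LX21": {"pair5": (96.6, 3.4), "pair43": (100.0, 0.0)},
    "MSK-LX38": {"pair5": (99.2, 0.8), "pair43": (99.8, 0.2)},
    "NHJ29":    {"pair5": (94.5, 5.5), "pair43": (97.0, 3.0)},
}


def screen_mouse_origin(
    screen: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    threshold: float = MOUSE_ORIGIN_THRESHOLD,
) -> pd.DataFrame:
    """Apply the >95% rule to per-pair murine/human percentage tables.

    Each pair's percentages are renormalized by their sum (guards against
    rounding), converted to fractions, pair-averaged, and classified.
    Defaults to the built-in screening example.
    """
    screen = MOUSE_ORIGIN_SCREEN if screen is None else screen
    rows = []
    for line_id, pairs in screen.items():
        per_pair = {}
        for pid, (m_pct, h_pct) in pairs.items():
            total = m_pct + h_pct
            if total <= 0:
                raise ValueError(f"{line_id}/{pid}: empty percentages")
            mf = m_pct / total
            per_pair[pid] = (mf, 1.0 - mf)
        est = combine_pairs(per_pair)
        call = classify_origin(est, threshold)
        row = {"line_id": line_id,
               "combined_mouse_fraction": est.combined_mouse_fraction,
               "verdict": call.verdict}
        row.update({f"{pid}_mouse_fraction": mf
                    for pid, (mf, _) in per_pair.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabular I/O (Peak-Scanner-style exports)
# ---------------------------------------------------------------------------

def read_trace_tsv(path, pair_id: str) -> Electropherogram:
    """Read a raw trace from a two-column TSV (``size_bp``, ``intensity``,
    header line required)."""
    df = pd.read_csv(path, sep="\t")
    if not {"size_bp", "intensity"} <= set(df.columns):
        raise ValueError("trace TSV must have columns size_bp, intensity")
    return Electropherogram(pair_id=pair_id,
                            sizes=df["size_bp"].to_numpy(float),
                            intensities=df["intensity"].to_numpy(float))


def write_trace_tsv(trace: Electropherogram, path) -> None:
    pd.DataFrame({"size_bp": trace.sizes,
                  "intensity": trace.intensities}).to_csv(
        path, sep="\t", index=False)


def read_peak_table(path) -> dict[str, list[Peak]]:
    """Read a pre-called peak table TSV (``pair_id, size_bp, height, area``)
    in the style of fragment-analysis software exports.  Peak bounds are not
    part of such exports and are set to a nominal +/- 1 bp window."""
    df = pd.read_csv(path, sep="\t")
    need = {"pair_id", "size_bp", "height", "area"}
    if not need <= set(df.columns):
        raise ValueError(f"peak table must have columns {sorted(need)}")
    out: dict[str, list[Peak]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.pair_id), []).append(
            Peak(centroid=float(row.size_bp), height=float(row.height),
                 area=float(row.area),
                 bounds=(float(row.size_bp) - 1.0, float(row.size_bp) + 1.0)))
    return out
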