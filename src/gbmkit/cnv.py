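"""SNP-array copy-number calling from Log-R-Ratio (LRR) tracks.

The stage ingests an ordered autosomal marker track (marker id, chromosome,
1-based position, LRR, optional BAF, 1 Mb-window GC fraction, allelic-balance
flag) and runs four steps:

1. **GC-waviness correction** — long-range LRR oscillation correlated with
   regional GC content is an array artifact, not copy number. The correction
   subtracts the median-centred GC fraction times a coefficient chosen to
   minimize the variance of the corrected LRR; that minimizer has the closed
   form ``Cov(lrr, gc~)/Var(gc~)`` and is fitted genome-wide per sample
   (per-chromosome fitting is available).
2. **Segmentation** — recursive binary splitting: at each step the split
   maximizing the two-sample t-statistic is accepted while a within-segment
   permutation p-value stays below ``alpha`` and both sides keep at least
   ``min_markers`` markers; afterwards an *SD-undo* pass merges adjacent
   segments (weakest first) whose mean difference is below ``undo_sd``
   standard errors of that difference, with the marker noise SD estimated
   robustly from median absolute successive differences.
3. **State calling** — segment mean LRRs are mapped to the five-state coding
   0 = homozygous loss, 1 = hemizygous loss, 2 = normal, 3 = gain,
   4 = amplification, using fixed, configurable thresholds.
4. **Reporting** — only non-normal segments strictly longer than
   ``min_length_bp`` (default 1 Mb) are reported; multi-sample calls can be
   compressed onto the union of segment boundaries for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MARKER_COLUMNS",
    "WavinessFit",
    "WavinessCorrector",
    "LrrSegmenter",
    "autosomal_markers",
    "gc_windows",
    "fit_waviness",
    "segment_lrr",
    "call_states",
    "filter_cnvs",
    "compress_regions",
    "segments_to_bed",
]

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "lrr", "baf", "gc_fraction", "is_allelic"]
DEFAULT_STATE_THRESHOLDS = (-1.0, -0.3, 0.3, 0.9)
_NON_AUTOSOMES = {"x", "y", "m", "mt", "chrx", "chry", "chrm", "chrmt"}


def _check_track(track: pd.DataFrame, need=("chrom", "pos", "lrr")) -> None:
    missing = set(need) - set(track.columns)
    if missing:
        raise ValueError(f"marker track is missing columns: {sorted(missing)}")
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise ValueError(
                f"markers on chromosome {chrom!r} are not sorted with unique positions"
            )


def autosomal_markers(track: pd.DataFrame) -> pd.DataFrame:
    """Restrict a track to allelic-balance-probing markers on autosomes."""
    out = track
    if "is_allelic" in out.columns:
        out = out[out["is_allelic"].astype(bool)]
    mask = ~out["chrom"].astype(str).str.lower().isin(_NON_AUTOSOMES)
    return out[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# GC windows
# ---------------------------------------------------------------------------


def gc_windows(
    source,
    markers: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Fill ``gc_fraction`` from a GC source, using a window centred on each marker.

    ``source`` is either a mapping ``chrom -> DNA sequence string`` (e.g. from
    a FASTA read with Biopython) or a binned GC track: a DataFrame with columns
    ``chrom, start, end, gc`` (1-based inclusive bins). The fraction covers
    ``[pos - window/2, pos + window/2]``, truncated at the chromosome (or
    track) ends with renormalization over the available span. G/C bases are
    counted among A/C/G/T only, so runs of N do not dilute the fraction.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    _check_track(markers, need=("chrom", "pos"))
    half = window_bp // 2
    out = markers.copy()
    fractions = np.empty(len(out), dtype=float)

    if isinstance(source, pd.DataFrame):
        need = {"chrom", "start", "end", "gc"}
        if not need <= set(source.columns):
            raise ValueError(f"binned GC track needs columns {sorted(need)}")
        by_chrom = {c: g.sort_values("start") for c, g in source.groupby("chrom")}
        for i, (chrom, pos) in enumerate(zip(out["chrom"], out["pos"])):
            if chrom not in by_chrom:
                raise ValueError(f"no GC bins for chromosome {chrom!r}")
            bins = by_chrom[chrom]
            limit = int(bins["end"].max())
            if pos < int(bins["start"].min()) or pos > limit:
                raise ValueError(
                    f"marker at {chrom}:{pos} outside the GC track bounds"
                )
            lo, hi = max(1, pos - half), min(limit, pos + half)
            starts = bins["start"].to_numpy()
            ends = bins["end"].to_numpy()
            overlap = np.minimum(ends, hi) - np.maximum(starts, lo) + 1
            overlap = np.clip(overlap, 0, None).astype(float)
            total = overlap.sum()
            fractions[i] = float((overlap * bins["gc"].to_numpy()).sum() / total)
    else:
        sequences = {str(c): str(s).upper() for c, s in dict(source).items()}
        for i, (chrom, pos) in enumerate(zip(out["chrom"], out["pos"])):
            seq = sequences.get(str(chrom))
            if seq is None or not 1 <= pos <= len(seq):
                raise ValueError(f"marker at {chrom}:{pos} outside sequence bounds")
            lo, hi = max(1, pos - half), min(len(seq), pos + half)
            window = seq[lo - 1 : hi]
            acgt = sum(window.count(b) for b in "ACGT")
            if acgt == 0:
                raise ValueError(f"window around {chrom}:{pos} has no A/C/G/T bases")
            fractions[i] = (window.count("G") + window.count("C")) / acgt

    out["gc_fraction"] = fractions
    return out


# ---------------------------------------------------------------------------
# waviness correction
# ---------------------------------------------------------------------------


@dataclass
class WavinessFit:
    coefficient: float
    variance_before: float
    variance_after: float
    gc_median: float


class WavinessCorrector(TransformerMixin, BaseEstimator):
    """Remove the GC-correlated LRR wave by variance-minimizing regression.

    Let ``g~ = gc_fraction - median(gc_fraction)``. ``Var(lrr - c*g~)`` is a
    quadratic in ``c`` with unique minimizer ``c* = Cov(lrr, g~)/Var(g~)``;
    ``fit`` computes it (``coefficient_``) and ``transform`` subtracts
    ``c* * g~`` from the LRR. ``per_chromosome=True`` fits one coefficient
    per chromosome instead of genome-wide.
    """

    def __init__(self, per_chromosome: bool = False):
        self.per_chromosome = per_chromosome

    def fit(self, track: pd.DataFrame, y=None):
        _check_track(track, need=("chrom", "pos", "lrr", "gc_fraction"))
        if len(track) < 3:
            raise ValueError("waviness fit needs at least 3 markers")
        if self.per_chromosome:
            self.fits_ = {
                str(chrom): self._fit_one(grp)
                for chrom, grp in track.groupby("chrom", sort=False)
            }
            self.coefficient_ = {c: f.coefficient for c, f in self.fits_.items()}
        else:
            self.fit_ = self._fit_one(track)
            self.coefficient_ = self.fit_.coefficient
        return self

    @staticmethod
    def _fit_one(track: pd.DataFrame) -> WavinessFit:
        lrr = track["lrr"].to_numpy(dtype=float)
        gc = track["gc_fraction"].to_numpy(dtype=float)
        gc_median = float(np.median(gc))
        g = gc - gc_median
        var_g = float(np.var(g))
        var_before = float(np.var(lrr))
        if var_g == 0:
            warnings.warn(
                "GC fractions are constant; no waviness correction possible",
                stacklevel=3,
            )
            coef = 0.0
        else:
            coef = float(np.mean((lrr - lrr.mean()) * g) / var_g)
        var_after = float(np.var(lrr - coef * g))
        return WavinessFit(coef, var_before, var_after, gc_median)

    def transform(self, track: pd.DataFrame) -> pd.DataFrame:
        out = track.copy()
        if self.per_chromosome:
            corrected = []
            for chrom, grp in out.groupby("chrom", sort=False):
                f = self.fits_[str(chrom)]
                corrected.append(
                    grp["lrr"].to_numpy()
                    - f.coefficient * (grp["gc_fraction"].to_numpy() - f.gc_median)
                )
            out["lrr"] = np.concatenate(corrected)
        else:
            f = self.fit_
            out["lrr"] = out["lrr"].to_numpy() - f.coefficient * (
                out["gc_fraction"].to_numpy() - f.gc_median
            )
        return out


def fit_waviness(track: pd.DataFrame) -> tuple[WavinessFit, pd.DataFrame]:
    """Genome-wide waviness fit; returns the fit and the corrected track."""
    corrector = WavinessCorrector().fit(track)
    return corrector.fit_, corrector.transform(track)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _split_statistics(x: np.ndarray, min_markers: int) -> np.ndarray:
    """|t| for every admissible split (both sides >= min_markers); empty if none."""
    n = len(x)
    if n < 2 * min_markers:
        return np.empty(0)
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    i = np.arange(min_markers, n - min_markers + 1)  # left part is x[:i]
    n_l = i.astype(float)
    n_r = n - n_l
    sum_l = cs[i - 1]
    sum_r = cs[-1] - sum_l
    mean_l = sum_l / n_l
    mean_r = sum_r / n_r
    ss_l = cs2[i - 1] - sum_l**2 / n_l
    ss_r = (cs2[-1] - cs2[i - 1]) - sum_r**2 / n_r
    pooled = (ss_l + ss_r) / np.maximum(n - 2, 1)
    se = np.sqrt(pooled * (1.0 / n_l + 1.0 / n_r))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_l - mean_r) / se
    t[np.isnan(t)] = 0.0  # zero variance, equal means
    t[np.isinf(t)] = np.finfo(float).max  # zero variance, different means
    return t


def _best_split(x: np.ndarray, min_markers: int) -> tuple[int, float]:
    t = _split_statistics(x, min_markers)
    if t.size == 0:
        return -1, 0.0
    k = int(np.argmax(t))
    return min_markers + k, float(t[k])


def _split_pvalue(
    x: np.ndarray, t_obs: float, min_markers: int, n_perm: int, rng
) -> float:
    """Permutation p-value for the best split: add-one corrected."""
    exceed = 0
    perm = x.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        t = _split_statistics(perm, min_markers)
        if t.size and t.max() >= t_obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


class LrrSegmenter(BaseEstimator):
    """Changepoint segmentation of an LRR track with SD-undo merging.

    Per chromosome the signal is split recursively at the position with the
    largest two-sample t-statistic; a split is accepted while its
    within-segment permutation p-value is below ``alpha`` and both sides keep
    ``min_markers`` markers. The SD-undo pass then merges adjacent segments
    (weakest boundary first) whose |mean difference| is below ``undo_sd``
    standard errors of that difference, with the marker noise SD estimated
    robustly as ``median(|successive differences|) / (sqrt(2) * 0.6745)``;
    segment means over many markers are thus held to a much tighter bar
    than single markers, so modest but well-supported shifts survive while
    sub-noise splits are undone.

    ``fit`` sets ``segments_``: a DataFrame with ``chrom, start, end,
    n_markers, mean_lrr`` (1-based inclusive marker-position coordinates),
    tiling each chromosome's markers without gaps.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        n_perm: int = 100,
        min_markers: int = 5,
        undo_sd: float = 3.0,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_markers = min_markers
        self.undo_sd = undo_sd
        self.random_state = random_state

    def fit(self, track: pd.DataFrame, y=None):
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        _check_track(track)
        rng = np.random.default_rng(self.random_state)
        rows = []
        for chrom, grp in track.groupby("chrom", sort=False):
            x = grp["lrr"].to_numpy(dtype=float)
            pos = grp["pos"].to_numpy()
            if len(x) < self.min_markers:
                warnings.warn(
                    f"chromosome {chrom!r} has fewer than {self.min_markers} "
                    "markers; emitting a single segment",
                    stacklevel=2,
                )
                boundaries = [0, len(x)]
            else:
                boundaries = self._segment_chromosome(x, rng)
                boundaries = self._sd_undo(x, boundaries)
                boundaries = self._refine_boundaries(x, boundaries)
            for lo, hi in zip(boundaries[:-1], boundaries[1:]):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[lo]),
                        "end": int(pos[hi - 1]),
                        "n_markers": hi - lo,
                        "mean_lrr": float(x[lo:hi].mean()),
                    }
                )
        self.segments_ = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_markers", "mean_lrr"]
        )
        return self

    def _refine_boundaries(self, x: np.ndarray, boundaries: list[int]) -> list[int]:
        # each accepted split is found under the min_markers side constraint,
        # which can park a boundary a few markers off when the true change
        # sits near a segment edge; re-locate every boundary by maximizing
        # the two-sample t over the full span of its two adjacent segments
        bounds = list(boundaries)
        for i in range(1, len(bounds) - 1):
            lo, hi = bounds[i - 1], bounds[i + 1]
            split, t = _best_split(x[lo:hi], 1)
            if split > 0 and t > 0:
                bounds[i] = lo + split
        return sorted(set(bounds))

    def _segment_chromosome(self, x: np.ndarray, rng) -> list[int]:
        boundaries = [0, len(x)]
        stack = [(0, len(x))]
        while stack:
            lo, hi = stack.pop()
            seg = x[lo:hi]
            split, t_obs = _best_split(seg, self.min_markers)
            if split < 0 or t_obs == 0.0:
                continue
            p = _split_pvalue(seg, t_obs, self.min_markers, self.n_perm, rng)
            if p < self.alpha:
                boundaries.append(lo + split)
                stack.append((lo, lo + split))
                stack.append((lo + split, hi))
        return sorted(set(boundaries))

    def _sd_undo(self, x: np.ndarray, boundaries: list[int]) -> list[int]:
        # merge while the mean difference is small relative to its standard
        # error (undo_sd multiples), with the noise SD estimated robustly
        # from median absolute successive differences
        noise_sd = float(
            np.median(np.abs(np.diff(x))) / (np.sqrt(2) * 0.6745)
        ) if len(x) > 1 else 0.0
        bounds = list(boundaries)
        while len(bounds) > 2:
            sizes = np.diff(bounds)
            means = [x[lo:hi].mean() for lo, hi in zip(bounds[:-1], bounds[1:])]
            gaps = np.abs(np.diff(means))
            ses = noise_sd * np.sqrt(1.0 / sizes[:-1] + 1.0 / sizes[1:])
            excess = gaps - self.undo_sd * ses
            weakest = int(np.argmin(excess))
            if excess[weakest] < 0:
                del bounds[weakest + 1]
            else:
                break
        return bounds


def segment_lrr(
    track: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 100,
    min_markers: int = 5,
    undo_sd: float = 3.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Segment a (corrected) LRR track; returns the segment table (states unset)."""
    seg = LrrSegmenter(
        alpha=alpha,
        n_perm=n_perm,
        min_markers=min_markers,
        undo_sd=undo_sd,
        random_state=seed,
    ).fit(track)
    return seg.segments_


# ---------------------------------------------------------------------------
# state calling, filtering, compression
# ---------------------------------------------------------------------------


def call_states(
    segments: pd.DataFrame,
    thresholds: tuple[float, float, float, float] = DEFAULT_STATE_THRESHOLDS,
) -> pd.DataFrame:
    """Assign 5-state copy-number calls from segment mean LRRs.

    State coding: 0 homozygous loss, 1 hemizygous loss, 2 normal, 3 gain,
    4 amplification. With cut points ``t1 < t2 < t3 < t4``:
    ``mean <= t1 -> 0``, ``(t1, t2] -> 1``, ``(t2, t3) -> 2``,
    ``[t3, t4) -> 3``, ``>= t4 -> 4``.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != 4 or any(np.diff(thresholds) <= 0):
        raise ValueError(
            f"thresholds must be 4 strictly increasing cut points, got {thresholds}"
        )
    t1, t2, t3, t4 = thresholds
    means = segments["mean_lrr"].to_numpy(dtype=float)
    states = np.full(len(means), 2, dtype=int)
    states[means <= t2] = 1
    states[means <= t1] = 0
    states[means >= t3] = 3
    states[means >= t4] = 4
    out = segments.copy()
    out["state"] = states
    return out


def filter_cnvs(
    segments: pd.DataFrame, min_length_bp: int = 1_000_000
) -> pd.DataFrame:
    """Report non-normal segments strictly longer than ``min_length_bp``.

    Length is ``end - start + 1`` (1-based inclusive coordinates); the
    default reproduces a "only CNVs larger than 1 Mb" reporting rule.
    """
    if "state" not in segments.columns:
        raise ValueError("call_states must run before filter_cnvs")
    length = segments["end"] - segments["start"] + 1
    keep = (segments["state"] != 2) & (length > min_length_bp)
    out = segments[keep].copy()
    out["length_bp"] = length[keep]
    return out.reset_index(drop=True)


def compress_regions(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Compress per-sample segmentations onto shared comparable regions.

    Region boundaries are the union of all samples' segment boundaries per
    chromosome; each (region, sample) cell carries the state of the sample's
    covering segment. All samples must cover the same chromosome set.
    """
    if not reports:
        raise ValueError("need at least one sample")
    chrom_sets = {s: set(seg["chrom"]) for s, seg in reports.items()}
    reference_set = next(iter(chrom_sets.values()))
    for sample, chroms in chrom_sets.items():
        if chroms != reference_set:
            diff = chroms.symmetric_difference(reference_set)
            raise ValueError(
                f"inconsistent chromosome sets (sample {sample!r} differs on {sorted(diff)})"
            )
    samples = list(reports)
    rows = []
    for chrom in sorted(reference_set, key=str):
        cuts: set[int] = set()
        for seg in reports.values():
            sub = seg[seg["chrom"] == chrom]
            cuts.update(int(v) for v in sub["start"])
            cuts.update(int(v) + 1 for v in sub["end"])  # exclusive right edge
        edges = sorted(cuts)
        for lo, hi in zip(edges[:-1], edges[1:]):
            row = {"chrom": chrom, "start": lo, "end": hi - 1}
            for sample in samples:
                sub = reports[sample]
                sub = sub[(sub["chrom"] == chrom)]
                cover = sub[(sub["start"] <= lo) & (sub["end"] >= hi - 1)]
                row[sample] = int(cover["state"].iloc[0]) if len(cover) else np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", *samples])


def segments_to_bed(segments: pd.DataFrame) -> pd.DataFrame:
    """BED view of a segment table: 0-based half-open, name = state."""
    bed = pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"].astype(int) - 1,
            "end": segments["end"].astype(int),
            "name": segments["state"].astype(int)
            if "state" in segments.columns
            else ".",
        }
    )
    return bed
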