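"""Strand-specific sequencing quantification of DNA end resection.

The pipeline mirrors the two readouts of a resection ChIP-seq experiment:

* total DNA — samples subsampled to a common depth, per-strand coverage
  divided by the uninduced (t0) sample, averaged in fixed bins across a
  window around the break; loss of signal on the degraded strand reports
  how far resection has travelled;
* RPA-ChIP — coverage normalized between samples via DSB-independent RPA
  reference peaks (threshold at a multiple of the genome-wide median
  coverage, width-filtered, required to recur across samples), then
  profiled over a wider window around the break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import STRANDS, BinnedProfile, Genome, Peak, PeakSet, RatioTrack, ReadSet, StrandCoverage


@dataclass
class QuantConfig:
    """Analysis geometry and thresholds.

    Defaults follow the published analysis: a 20-kb total-DNA window in
    2-kb bins, a 25-kb half-width RPA window, reference peaks at 6x the
    genome-wide median coverage with widths in [100, 500] bp.
    """

    dsb_chrom: str = ""
    dsb_pos: int = 0
    total_half_width: int = 10_000
    total_bin_width: int = 2_000
    rpa_half_width: int = 25_000
    rpa_bin_width: int = 500
    peak_threshold_multiplier: float = 6.0
    peak_width_bounds: tuple[int, int] = (100, 500)
    dsb_exclusion_half_width: int = 50_000
    min_score: float | None = None

    def __post_init__(self) -> None:
        if self.total_half_width % self.total_bin_width:
            raise ValueError("total bin width must divide the window half-width")
        if self.rpa_half_width % self.rpa_bin_width:
            raise ValueError("RPA bin width must divide the window half-width")
        if self.peak_threshold_multiplier <= 0:
            raise ValueError("peak threshold multiplier must be positive")
        lo, hi = self.peak_width_bounds
        if not 0 < lo < hi:
            raise ValueError("peak width bounds must satisfy 0 < min < max")


def subsample_to_common_depth(samples: list[ReadSet], seed: int) -> list[ReadSet]:
    """Subsample every read set to the size of the smallest one.

    Reads are drawn uniformly without replacement, independently per
    sample (seeded per sample index), so each output is a subset of its
    input with exactly ``min(sizes)`` reads.
    """
    if not samples:
        raise ValueError("need at least one sample")
    for s in samples:
        if len(s) == 0:
            raise ValueError(f"sample {s.name!r} is empty; cannot subsample")
    depth = min(len(s) for s in samples)
    out = []
    for i, s in enumerate(samples):
        if len(s) == depth:
            out.append(ReadSet(reads=s.reads.copy(), name=s.name))
            continue
        rng = np.random.default_rng([seed, i])
        idx = np.sort(rng.choice(len(s), size=depth, replace=False))
        out.append(ReadSet(reads=s.reads.iloc[idx].reset_index(drop=True), name=s.name))
    return out


def coverage_from_reads(
    reads: ReadSet, genome: Genome, min_score: float | None = None
) -> StrandCoverage:
    """Pile up strand-tagged read intervals into per-base coverage."""
    df = reads.reads
    if min_score is not None:
        if "score" not in df.columns:
            raise ValueError("min_score requested but reads carry no score column")
        df = df[df["score"] >= min_score]
    cov = StrandCoverage.zeros(genome)
    for chrom, start, end, strand in zip(
        df["chrom"], df["start"], df["end"], df["strand"]
    ):
        if chrom not in genome:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        if start < 0 or end > genome[chrom]:
            raise ValueError(
                f"read {chrom}:{start}-{end} outside chromosome bounds"
            )
        target = cov.fwd if strand == "+" else cov.rev
        # difference-array increments, cumulated once per chromosome below
        target[chrom][start] += 1
        if end < genome[chrom]:
            target[chrom][end] -= 1
    for vectors in (cov.fwd, cov.rev):
        for chrom in genome:
            vectors[chrom] = np.cumsum(vectors[chrom])
    return cov


def t0_ratio(cov_t: StrandCoverage, cov_t0: StrandCoverage) -> RatioTrack:
    """Positionwise coverage ratio against the uninduced sample.

    Positions with zero t0 coverage are masked (NaN) rather than given a
    pseudocount, so unmappable or dropout positions never masquerade as
    signal loss.
    """
    if cov_t.genome != cov_t0.genome:
        raise ValueError("coverage tracks are on different genomes")
    tracks: dict[str, dict[str, np.ndarray]] = {}
    for strand in STRANDS:
        tracks[strand] = {}
        for chrom in cov_t.genome:
            num = cov_t.strand(strand)[chrom]
            den = cov_t0.strand(strand)[chrom]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            tracks[strand][chrom] = ratio
    return RatioTrack(genome=cov_t.genome, fwd=tracks["fwd"], rev=tracks["rev"])


def _bin_track(
    track: RatioTrack, cfg: QuantConfig, half_width: int, bin_width: int
) -> BinnedProfile:
    chrom = cfg.dsb_chrom
    if chrom not in track.genome:
        raise ValueError(f"DSB chromosome {chrom!r} not in genome")
    lo = cfg.dsb_pos - half_width
    hi = cfg.dsb_pos + half_width
    if lo < 0 or hi > track.genome[chrom]:
        raise ValueError("window around the DSB exceeds chromosome bounds")
    edges = np.arange(-half_width, half_width + bin_width, bin_width, dtype=float)
    n_bins = len(edges) - 1
    values = {}
    for strand in STRANDS:
        window = track.strand(strand)[chrom][lo:hi]
        binned = window.reshape(n_bins, bin_width)
        with warnings.catch_warnings():
            # a fully masked bin is a legitimate NaN result, not a warning
            warnings.simplefilter("ignore", category=RuntimeWarning)
            values[strand] = np.nanmean(binned, axis=1)
    return BinnedProfile(edges=edges, fwd=values["fwd"], rev=values["rev"])


def bin_dsb_window(track: RatioTrack, cfg: QuantConfig) -> BinnedProfile:
    """Average a ratio track in fixed bins tiling the total-DNA window."""
    return _bin_track(track, cfg, cfg.total_half_width, cfg.total_bin_width)


def rpa_window_profile(track: RatioTrack, cfg: QuantConfig) -> BinnedProfile:
    """Average a normalized RPA track in bins over the wider RPA window."""
    return _bin_track(track, cfg, cfg.rpa_half_width, cfg.rpa_bin_width)


def slice_reference_peaks(
    cov: StrandCoverage,
    cfg: QuantConfig,
    exclude: tuple[str, int, int] | None = None,
) -> PeakSet:
    """Select candidate DSB-independent reference peaks.

    The threshold is ``multiplier`` times the genome-wide median of the
    strand-summed coverage (zeros included). Peaks are maximal runs of
    positions at or above the threshold; runs outside the configured width
    bounds, or intersecting the exclusion interval (by default a window
    around the break), are discarded.
    """
    summed = {c: cov.summed(c) for c in cov.genome}
    median = float(np.median(np.concatenate(list(summed.values()))))
    if median == 0:
        raise ValueError(
            "genome-wide median coverage is zero; threshold would be degenerate"
        )
    threshold = cfg.peak_threshold_multiplier * median
    lo_w, hi_w = cfg.peak_width_bounds
    peaks: list[Peak] = []
    for chrom in cov.genome:
        above = summed[chrom] >= threshold
        bounded = np.concatenate(([False], above, [False]))
        changes = np.flatnonzero(np.diff(bounded.astype(np.int8)))
        for start, end in zip(changes[::2], changes[1::2]):
            width = end - start
            if not lo_w <= width <= hi_w:
                continue
            if exclude is not None:
                ex_chrom, ex_start, ex_end = exclude
                if chrom == ex_chrom and start < ex_end and ex_start < end:
                    continue
            peaks.append(Peak(chrom, int(start), int(end)))
    return PeakSet(peaks=peaks)


def intersect_across_samples(peaksets: list[PeakSet]) -> PeakSet:
    """Keep anchor peaks that recur (>=1 bp overlap) in every other set.

    The first set is the anchor; its intervals are returned unchanged when
    retained.
    """
    if not peaksets:
        raise ValueError("need at least one peak set")
    anchor, *others = peaksets
    kept = []
    for peak in anchor:
        if all(any(peak.overlaps(q) for q in other) for other in others):
            kept.append(peak)
    return PeakSet(peaks=kept)


def select_reference_peaks(
    samples: list[StrandCoverage],
    cfg: QuantConfig,
    exclude: tuple[str, int, int] | None = None,
) -> PeakSet:
    """Reference-peak selection across samples and replicates.

    Candidate peaks are sliced from the pooled (summed) coverage of all
    samples (the anchor) and retained only where every individual sample
    also shows a peak, so the final references are stable, DSB-independent
    loci shared by the whole experiment.
    """
    if not samples:
        raise ValueError("need at least one sample")
    genome = samples[0].genome
    pooled = StrandCoverage(
        genome=genome,
        fwd={c: sum(s.fwd[c] for s in samples) for c in genome},
        rev={c: sum(s.rev[c] for s in samples) for c in genome},
    )
    anchor = slice_reference_peaks(pooled, cfg, exclude=exclude)
    per_sample = [slice_reference_peaks(s, cfg, exclude=exclude) for s in samples]
    return intersect_across_samples([anchor, *per_sample])


def rpa_normalize(
    cov: StrandCoverage, refpeaks: PeakSet
) -> tuple[RatioTrack, float]:
    """Normalize RPA coverage to the DSB-independent reference peaks.

    The scale factor is the mean strand-summed coverage over all positions
    inside the reference peaks; both strand tracks are divided by it, so
    the normalized signal is comparable between samples of different
    immunoprecipitation efficiency or depth.
    """
    if len(refpeaks) == 0:
        raise ValueError("reference peak set is empty")
    total = 0.0
    n_pos = 0
    for peak in refpeaks:
        if peak.chrom not in cov.genome:
            raise ValueError(f"reference peak on unknown chromosome {peak.chrom!r}")
        total += float(cov.summed(peak.chrom)[peak.start : peak.end].sum())
        n_pos += peak.width
    scale = total / n_pos
    if scale == 0:
        raise ValueError("zero coverage inside reference peaks")
    normalized = RatioTrack(
        genome=cov.genome,
        fwd={c: cov.fwd[c] / scale for c in cov.genome},
        rev={c: cov.rev[c] / scale for c in cov.genome},
    )
    return normalized, scale


def estimate_resection_front(profile: BinnedProfile, side: str) -> float | None:
    """Distance at which the degraded strand's t0-ratio recovers to 0.5.

    Scans the degraded strand (forward right of the break, reverse left of
    it) outward bin by bin and linearly interpolates the first upward
    crossing of 0.5 between adjacent bin centers. Returns None when the
    ratio never crosses (no detectable loss, or loss beyond the window).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    centers = profile.centers
    if side == "right":
        mask = centers > 0
        distances = centers[mask]
        values = profile.fwd[mask]
    else:
        mask = centers < 0
        distances = -centers[mask][::-1]
        values = profile.rev[mask][::-1]
    keep = ~np.isnan(values)
    if not keep.any():
        raise ValueError("profile is fully masked on the requested side")
    distances = distances[keep]
    values = values[keep]
    for i in range(1, len(values)):
        if values[i - 1] < 0.5 <= values[i]:
            frac = (0.5 - values[i - 1]) / (values[i] - values[i - 1])
            return float(distances[i - 1] + frac * (distances[i] - distances[i - 1]))
    return None
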