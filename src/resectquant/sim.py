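"""Synthetic resection data with known ground truth.

The generator emulates a population of cells carrying a site-specific,
non-repairable double-strand break (HO-endonuclease style, incomplete
cutting), in which each cut end undergoes stochastic 5'->3' resection.
From the per-cell tract lengths it renders the two sequencing readouts the
pipeline quantifies — strand-specific total-DNA coverage (loss of the
5'-terminated strands) and RPA-ChIP enrichment on the persisting 3'
ssDNA — plus restriction-protection qPCR threshold cycles and
Luria-Delbruck fluctuation cultures.

Strand geometry (see :mod:`resectquant.core`): at a break at ``x0`` the
right fragment loses the forward strand over ``[x0, x0 + d_right)`` and the
left fragment loses the reverse strand over ``[x0 - d_left, x0)``; RPA-bound
ssDNA therefore sits on the reverse strand right of the break and on the
forward strand left of it. A position at mirror offset ``k`` means
``x0 + k`` on the right and ``x0 - 1 - k`` on the left, so symmetric speeds
produce profiles that are exact mirror images in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Genome, StrandCoverage


@dataclass(frozen=True)
class BackgroundPeak:
    """A DSB-independent RPA site: constant fold-enrichment over baseline."""

    chrom: str
    center: int
    width: int
    amplitude: float  # fold over baseline, > 1

    def __post_init__(self) -> None:
        if not 50 <= self.width <= 2000:
            raise ValueError(f"peak width {self.width} outside [50, 2000] bp")
        if self.amplitude <= 1:
            raise ValueError("peak amplitude must exceed 1 (fold over baseline)")

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass
class GenomeSpec:
    """Synthetic genome: chromosomes, the DSB locus, and background RPA sites."""

    genome: Genome
    dsb_chrom: str
    dsb_pos: int  # 0-based; break falls between dsb_pos - 1 and dsb_pos
    background_peaks: list[BackgroundPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dsb_chrom not in self.genome:
            raise ValueError(f"DSB chromosome {self.dsb_chrom!r} not in genome")
        if not 0 < self.dsb_pos < self.genome[self.dsb_chrom]:
            raise ValueError("dsb_pos must be strictly inside the DSB chromosome")
        for p in self.background_peaks:
            if p.chrom not in self.genome:
                raise ValueError(f"background peak on unknown chromosome {p.chrom!r}")
            if p.start < 0 or p.end > self.genome[p.chrom]:
                raise ValueError("background peak exceeds chromosome bounds")


@dataclass
class ResectionModel:
    """Population resection kinetics.

    A cell is cut with probability ``cut_efficiency``. Each cut end resects
    independently; at time ``t`` (hours) the tract length is lognormal with
    mean ``speed_mean * max(0, t - init_delay)`` nt and coefficient of
    variation ``speed_cv`` (cv 0 means a deterministic tract).
    """

    cut_efficiency: float = 0.9
    speed_mean: float = 4000.0  # nt/h per end
    speed_cv: float = 0.3
    init_delay: float = 0.0  # h
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        if not 0 <= self.cut_efficiency <= 1:
            raise ValueError("cut_efficiency must lie in [0, 1]")
        if self.speed_mean < 0 or self.speed_cv < 0 or self.init_delay < 0:
            raise ValueError("speed_mean, speed_cv and init_delay must be >= 0")

    def expected_extent(self, t: float) -> float:
        return self.speed_mean * max(0.0, t - self.init_delay)


@dataclass
class LibraryParams:
    """Sequencing library rendering parameters.

    ``mean_depth`` is the expected fragment depth per base of intact
    double-stranded DNA. ``chip_enrichment`` (alpha) is the coverage a
    position fully occupied by RPA-bound ssDNA adds over the
    ``uniform_background`` (beta) floor. Fragment lengths (sonication range,
    roughly 200-500 bp) are carried for metadata; coverage is rendered
    directly as per-base expected depth.
    """

    mean_depth: float = 50.0
    fragment_length_range: tuple[int, int] = (200, 500)
    chip_enrichment: float = 40.0  # alpha
    uniform_background: float = 2.0  # beta
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        lo, hi = self.fragment_length_range
        if not 1 <= lo <= hi <= 10000:
            raise ValueError("fragment_length_range must lie within [1, 10000]")
        if self.chip_enrichment <= 0 or self.uniform_background < 0:
            raise ValueError("chip_enrichment > 0 and uniform_background >= 0 required")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


@dataclass
class ResectionTruth:
    """Ground-truth per-cell resection state at one time point."""

    spec: GenomeSpec
    cut: np.ndarray  # bool, shape (n_cells,)
    left_extent: np.ndarray  # nt, >= 0, 0 for uncut cells
    right_extent: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.cut = np.asarray(self.cut, dtype=bool)
        self.left_extent = np.asarray(self.left_extent, dtype=float)
        self.right_extent = np.asarray(self.right_extent, dtype=float)
        n = self.cut.shape[0]
        if self.left_extent.shape != (n,) or self.right_extent.shape != (n,):
            raise ValueError("extent arrays must match the number of cells")
        if np.any(self.left_extent < 0) or np.any(self.right_extent < 0):
            raise ValueError("extents must be non-negative")
        if np.any(self.left_extent[~self.cut] > 0) or np.any(
            self.right_extent[~self.cut] > 0
        ):
            raise ValueError("uncut cells cannot have non-zero extents")

    @property
    def n_cells(self) -> int:
        return self.cut.shape[0]

    def fraction_resected_past(self, distance: float, side: str) -> float:
        """Fraction of all cells whose tract on ``side`` exceeds ``distance``."""
        extents = self.right_extent if side == "right" else self.left_extent
        return float(np.mean(extents > distance))

    def median_extent(self, side: str) -> float:
        extents = self.right_extent if side == "right" else self.left_extent
        return float(np.median(extents))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(self.n_cells),
                "cut": self.cut.astype(int),
                "left_extent": self.left_extent,
                "right_extent": self.right_extent,
            }
        )


def simulate_population(
    spec: GenomeSpec,
    model: ResectionModel,
    t: float,
    n_cells: int,
    seed: int,
) -> ResectionTruth:
    """Draw per-cell cut states and resection tract lengths at time ``t``.

    Tracts are lognormal with mean ``speed_mean * max(0, t - init_delay)``
    and CV ``speed_cv``, drawn independently per end, then clipped to the
    chromosome bounds. Uncut cells have zero extents.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = np.random.default_rng(seed)
    cut = rng.random(n_cells) < model.cut_efficiency
    mean_extent = model.expected_extent(t)
    if mean_extent == 0:
        left = np.zeros(n_cells)
        right = np.zeros(n_cells)
    elif model.speed_cv == 0:
        left = np.where(cut, mean_extent, 0.0)
        right = np.where(cut, mean_extent, 0.0)
    else:
        # lognormal parameterized by arithmetic mean M and CV c:
        # sigma^2 = ln(1 + c^2), mu = ln(M) - sigma^2 / 2
        sigma2 = np.log1p(model.speed_cv**2)
        mu = np.log(mean_extent) - sigma2 / 2
        left = np.where(cut, rng.lognormal(mu, np.sqrt(sigma2), n_cells), 0.0)
        right = np.where(cut, rng.lognormal(mu, np.sqrt(sigma2), n_cells), 0.0)
    x0 = spec.dsb_pos
    chrom_len = spec.genome[spec.dsb_chrom]
    left = np.minimum(left, x0)
    right = np.minimum(right, chrom_len - x0)
    return ResectionTruth(spec=spec, cut=cut, left_extent=left, right_extent=right, time=t)


def _intact_fractions(truth: ResectionTruth) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset fraction of cells NOT resected past each mirror offset.

    Returns (right, left) arrays; entry ``k`` refers to position
    ``x0 + k`` (right, forward strand) or ``x0 - 1 - k`` (left, reverse
    strand). A tract of length d destroys offsets ``k < d``.
    """
    spec = truth.spec
    x0 = spec.dsb_pos
    chrom_len = spec.genome[spec.dsb_chrom]
    n = truth.n_cells
    right_off = np.arange(chrom_len - x0, dtype=float)
    left_off = np.arange(x0, dtype=float)
    sorted_right = np.sort(truth.right_extent)
    sorted_left = np.sort(truth.left_extent)
    # intact at offset k <=> extent <= k
    intact_right = np.searchsorted(sorted_right, right_off, side="right") / n
    intact_left = np.searchsorted(sorted_left, left_off, side="right") / n
    return intact_right, intact_left


def _maybe_poisson(expected: dict[str, np.ndarray], lib: LibraryParams, rng) -> dict:
    if lib.noise == "none":
        return expected
    return {c: rng.poisson(v).astype(float) for c, v in expected.items()}


def render_total_dna(
    truth: ResectionTruth, spec: GenomeSpec, lib: LibraryParams
) -> StrandCoverage:
    """Render strand-specific total-DNA coverage from ground truth.

    Expected coverage is ``mean_depth`` everywhere except on the degraded
    strands near the break, where it is ``mean_depth`` times the fraction of
    cells whose tract has not yet reached the position.
    """
    rng = np.random.default_rng(lib.seed)
    x0 = spec.dsb_pos
    fwd = {c: np.full(spec.genome[c], lib.mean_depth) for c in spec.genome}
    rev = {c: np.full(spec.genome[c], lib.mean_depth) for c in spec.genome}
    intact_right, intact_left = _intact_fractions(truth)
    chrom = spec.dsb_chrom
    fwd[chrom][x0:] = lib.mean_depth * intact_right
    rev[chrom][:x0] = lib.mean_depth * intact_left[::-1]
    fwd = _maybe_poisson(fwd, lib, rng)
    rev = _maybe_poisson(rev, lib, rng)
    return StrandCoverage(genome=spec.genome, fwd=fwd, rev=rev)


def render_rpa_chip(
    truth: ResectionTruth, spec: GenomeSpec, lib: LibraryParams
) -> StrandCoverage:
    """Render strand-specific RPA-ChIP coverage from ground truth.

    Expected coverage is ``beta + alpha * occ`` where ``occ`` is the
    fraction of cells in which the position is RPA-coated ssDNA: the
    reverse strand right of the break and the forward strand left of it.
    DSB-independent background peaks add ``beta * (amplitude - 1)`` on both
    strands over their footprint.
    """
    rng = np.random.default_rng(lib.seed + 1)
    beta = lib.uniform_background
    alpha = lib.chip_enrichment
    x0 = spec.dsb_pos
    fwd = {c: np.full(spec.genome[c], float(beta)) for c in spec.genome}
    rev = {c: np.full(spec.genome[c], float(beta)) for c in spec.genome}
    intact_right, intact_left = _intact_fractions(truth)
    chrom = spec.dsb_chrom
    rev[chrom][x0:] = beta + alpha * (1.0 - intact_right)
    fwd[chrom][:x0] = beta + alpha * (1.0 - intact_left[::-1])
    for peak in spec.background_peaks:
        bump = beta * (peak.amplitude - 1.0)
        fwd[peak.chrom][peak.start : peak.end] += bump
        rev[peak.chrom][peak.start : peak.end] += bump
    fwd = _maybe_poisson(fwd, lib, rng)
    rev = _maybe_poisson(rev, lib, rng)
    return StrandCoverage(genome=spec.genome, fwd=fwd, rev=rev)


@dataclass
class QpcrSimParams:
    """Restriction-protection qPCR simulation parameters.

    ``site_offsets`` are signed distances of restriction sites from the
    break (negative = upstream / left). The classic assay interrogates
    sites 120 bp upstream and 98 bp, 640 bp, 2.5 kb and 5 kb downstream.
    """

    site_offsets: tuple[int, ...] = (-120, 98, 640, 2500, 5000)
    control_locus: str = "control"
    pcr_efficiency: float = 1.0
    ct_cap: float = 40.0
    ct_noise_sd: float = 0.0
    ct_reference: float = 15.0  # Ct of the undigested, unresected reference
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(o == 0 for o in self.site_offsets):
            raise ValueError("site offsets must be non-zero")
        if not 0 < self.pcr_efficiency <= 1:
            raise ValueError("pcr_efficiency must lie in (0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


def _ct_from_fraction(fraction: float, params: QpcrSimParams) -> float:
    """Ct for a template amount given as a fraction of the reference."""
    if fraction <= 0:
        return params.ct_cap
    ct = params.ct_reference - np.log2(fraction) / np.log2(1 + params.pcr_efficiency)
    return min(ct, params.ct_cap)


def simulate_qpcr_resection(truth: ResectionTruth, params: QpcrSimParams) -> pd.DataFrame:
    """Generate a digested/undigested Ct table from ground-truth tracts.

    Template counting per cell at a restriction site: an unresected locus
    contributes 2 amplifiable strands in the undigested tube, a resected
    one contributes 1 (its 3' ssDNA strand), and only resected loci (1
    strand) survive digestion. Fractions are relative to the undigested
    unresected reference (2 strands/cell). An "HOcut" amplicon spanning the
    break reports the uncut fraction; the control locus has no restriction
    site and is never degraded.
    """
    spec = truth.spec
    x0 = spec.dsb_pos
    chrom_len = spec.genome[spec.dsb_chrom]
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []

    def emit(target: str, tube: str, fraction: float) -> None:
        base_ct = _ct_from_fraction(fraction, params)
        for rep in range(params.n_replicates):
            ct = base_ct
            if params.ct_noise_sd > 0 and base_ct < params.ct_cap:
                ct = min(ct + rng.normal(0, params.ct_noise_sd), params.ct_cap)
            rows.append({"target": target, "tube": tube, "replicate": rep, "ct": ct})

    for offset in params.site_offsets:
        if offset > 0 and offset > chrom_len - x0:
            raise ValueError(f"site offset {offset} beyond chromosome end")
        if offset < 0 and -offset > x0:
            raise ValueError(f"site offset {offset} beyond chromosome start")
        extents = truth.right_extent if offset > 0 else truth.left_extent
        f = float(np.mean(extents >= abs(offset)))
        name = f"site_{offset:+d}"
        emit(name, "undigested", (2 - f) / 2)
        emit(name, "digested", f / 2)

    cut_fraction = float(np.mean(truth.cut))
    emit("HOcut", "undigested", 1 - cut_fraction)
    emit("HOcut", "digested", 1 - cut_fraction)
    emit(params.control_locus, "undigested", 1.0)
    emit(params.control_locus, "digested", 1.0)
    return pd.DataFrame(rows)


@dataclass
class FluctuationSimParams:
    """Luria-Delbruck culture simulation parameters.

    A culture grows from ``n0`` to ``nt`` cells; each of the ``nt - n0``
    cell births mutates with probability ``mu``, and a mutant clone founded
    when the population has N cells grows deterministically to ``nt / N``
    cells, so the expected mutations per culture is ``m = mu * (nt - n0)``.
    """

    mu: float = 1e-7
    n0: int = 100
    nt: int = 10_000_000
    n_cultures: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mu < 0.1:
            raise ValueError("mu must lie in [0, 0.1)")
        if not self.nt > self.n0 >= 1:
            raise ValueError("nt > n0 >= 1 required")
        if self.n_cultures < 1:
            raise ValueError("n_cultures must be >= 1")


def simulate_fluctuation(params: FluctuationSimParams) -> np.ndarray:
    """Simulate per-culture final mutant counts.

    For each culture the number of mutations is Binomial(nt - n0, mu); each
    mutation arises at a population size N drawn uniformly over the growth
    interval and founds a clone of final size floor(nt / N). The zero-class
    probability is (1 - mu)^(nt - n0) ~ exp(-m), and for nt >> n0 the clone
    size distribution has the 1/(j (j+1)) tail of the Luria-Delbruck
    distribution, so counts follow the same law as the MSS likelihood
    recursion used for estimation.
    """
    rng = np.random.default_rng(params.seed)
    divisions = params.nt - params.n0
    counts = np.zeros(params.n_cultures, dtype=np.int64)
    n_mut = rng.binomial(divisions, params.mu, size=params.n_cultures)
    total = int(n_mut.sum())
    if total:
        birth_sizes = rng.uniform(params.n0, params.nt, size=total)
        clone_sizes = np.floor(params.nt / birth_sizes).astype(np.int64)
        owner = np.repeat(np.arange(params.n_cultures), n_mut)
        np.add.at(counts, owner, clone_sizes)
    return counts
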