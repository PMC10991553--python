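"""qPCR quantification: restriction-protection ssDNA assay, HO cut
efficiency, standard curves, and the gene-conversion recombination ratio.

ssDNA fraction from restriction protection
------------------------------------------
Genomic DNA is digested with a restriction enzyme whose site lies at a
known distance from the break; qPCR amplifies across the site. A locus
that has been resected past the site is single-stranded there, escapes
digestion, and still amplifies. Template counting per cell gives the
conversion from Ct values to the resected fraction f:

* undigested tube: an unresected locus contributes both strands (2
  templates), a resected locus only its surviving 3' strand (1 template)
  -> 2 - f templates per cell;
* digested tube: only resected loci survive -> f templates per cell.

With exact-doubling chemistry the digested/undigested template ratio is
r = 2^(-ddCt) where ddCt = (Ct_dig - Ct_undig)_target - (Ct_dig -
Ct_undig)_control, and r = f / (2 - f), hence

    f = 2 r / (1 + r) = 2 / (2^ddCt + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("target", "tube", "replicate", "ct")
TUBES = ("digested", "undigested")


@dataclass
class CtTable:
    """Threshold-cycle table: one row per (target, tube, replicate)."""

    data: pd.DataFrame
    ct_cap: float = 40.0

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"Ct table missing column {col!r}")
        bad_tube = ~self.data["tube"].isin(TUBES)
        if bad_tube.any():
            raise ValueError(
                f"unknown tube value(s): {self.data.loc[bad_tube, 'tube'].unique()!r}"
            )
        ct = self.data["ct"]
        if (ct <= 0).any() or (ct > self.ct_cap + 1e-9).any():
            raise ValueError(f"Ct values must lie in (0, {self.ct_cap}]")

    def _rows(self, target: str, tube: str) -> pd.Series:
        sel = self.data[(self.data["target"] == target) & (self.data["tube"] == tube)]
        if sel.empty:
            raise ValueError(f"no Ct rows for target {target!r}, tube {tube!r}")
        return sel["ct"]

    def mean_ct(self, target: str, tube: str) -> float:
        return float(self._rows(target, tube).mean())

    def var_of_mean(self, target: str, tube: str) -> float:
        """Variance of the replicate mean (0 for a single replicate)."""
        rows = self._rows(target, tube)
        if len(rows) < 2:
            return 0.0
        return float(rows.var(ddof=1) / len(rows))

    def at_cap(self, target: str, tube: str, tol: float = 1e-9) -> bool:
        return bool((self._rows(target, tube) >= self.ct_cap - tol).all())


@dataclass
class SsdnaResult:
    fraction: float
    sd: float
    ddct: float


def ssdna_fraction(
    ct: CtTable,
    target: str,
    control_target: str,
    tol: float = 0.1,
    cut_correction: float | None = None,
) -> SsdnaResult:
    """Resected (ssDNA) fraction at one restriction site.

    ``control_target`` is an amplicon without a restriction site, so its
    digested - undigested Ct difference absorbs loading differences
    between the two tubes. Replicate scatter is propagated to the fraction
    by first-order (delta-method) error propagation. A digested target at
    the Ct cap means no surviving template: fraction 0.

    ``cut_correction`` optionally rescales the fraction by a measured cut
    efficiency (f / cut_fraction), expressing resection per cut molecule
    rather than per cell; off by default.
    """
    if cut_correction is not None and not 0 < cut_correction <= 1:
        raise ValueError("cut_correction must lie in (0, 1]")
    if ct.at_cap(target, "digested"):
        return SsdnaResult(fraction=0.0, sd=0.0, ddct=math.inf)
    dct_target = ct.mean_ct(target, "digested") - ct.mean_ct(target, "undigested")
    dct_control = ct.mean_ct(control_target, "digested") - ct.mean_ct(
        control_target, "undigested"
    )
    ddct = dct_target - dct_control
    f = 2.0 / (2.0**ddct + 1.0)
    if f > 1.0 + tol:
        raise ValueError(
            f"ssDNA fraction {f:.3f} exceeds 1 beyond tolerance; assay failure "
            f"(ddCt = {ddct:.3f})"
        )
    f = min(f, 1.0)
    var_ddct = sum(
        ct.var_of_mean(t, tube)
        for t in (target, control_target)
        for tube in TUBES
    )
    # |df/dddCt| = 2 ln2 * 2^ddct / (2^ddct + 1)^2
    deriv = 2.0 * math.log(2.0) * 2.0**ddct / (2.0**ddct + 1.0) ** 2
    sd = deriv * math.sqrt(var_ddct)
    if cut_correction is not None:
        f = min(f / cut_correction, 1.0)
        sd /= cut_correction
    return SsdnaResult(fraction=f, sd=sd, ddct=ddct)


def cut_fraction(
    ct: CtTable, ct_t0: CtTable, hocut_target: str, control_target: str
) -> float:
    """HO cut efficiency from an amplicon spanning the cut site.

    Only uncut molecules amplify across the break; the surviving-template
    ratio relative to the uninduced reference is r = 2^(-ddCt) with the
    control amplicon correcting for input amounts, and the cut fraction is
    1 - r (clipped to [0, 1]).
    """
    dct_t = ct.mean_ct(hocut_target, "undigested") - ct.mean_ct(
        control_target, "undigested"
    )
    dct_0 = ct_t0.mean_ct(hocut_target, "undigested") - ct_t0.mean_ct(
        control_target, "undigested"
    )
    r = 2.0 ** (-(dct_t - dct_0))
    return float(min(max(1.0 - r, 0.0), 1.0))


@dataclass
class StandardCurve:
    """Log-linear qPCR calibration: Ct = intercept + slope * log10(quantity)."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    ct_range: tuple[float, float] = (0.0, math.inf)

    def quantity(self, ct_value: float) -> float:
        return 10.0 ** ((ct_value - self.intercept) / self.slope)

    def in_range(self, ct_value: float) -> bool:
        lo, hi = self.ct_range
        return lo <= ct_value <= hi


def fit_standard_curve(quantities: list[float], cts: list[float]) -> StandardCurve:
    """Least-squares calibration of Ct against log10(template quantity).

    Amplification efficiency derives from the slope as
    ``E = 10^(-1/slope) - 1``; exact doubling chemistry gives the textbook
    slope of -1/log10(2) = -3.3219 cycles per decade and E = 1.
    """
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cts, dtype=float)
    if len(q) != len(c):
        raise ValueError("quantities and cts must have equal length")
    if len(np.unique(q)) < 3:
        raise ValueError("need at least 3 distinct quantities for a standard curve")
    if (q <= 0).any():
        raise ValueError("quantities must be positive")
    fit = stats.linregress(np.log10(q), c)
    if fit.slope >= 0:
        raise ValueError(
            f"standard curve slope {fit.slope:.3f} is not negative; degenerate dilution series"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    if not 0 < efficiency <= 1.2:
        raise ValueError(
            f"implied amplification efficiency {efficiency:.3f} outside (0, 1.2]"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
        ct_range=(float(c.min()), float(c.max())),
    )


@dataclass
class RecombinationResult:
    ratio: float
    replicate_ratios: np.ndarray
    sd: float
    warnings: list[str] = field(default_factory=list)


def recombination_ratio(
    ct: CtTable,
    recomb_target: str,
    control_target: str,
    recomb_curve: StandardCurve,
    control_curve: StandardCurve,
    tube: str = "undigested",
) -> RecombinationResult:
    """Relative recombination rate from calibrated amplicon quantities.

    Each amplicon's Ct is converted to a template quantity through its own
    calibration curve; the result is the recombination-amplicon quantity
    divided by the control-amplicon quantity, which cancels the amount of
    input DNA. Ct values outside a curve's calibrated range are flagged but
    still evaluated.
    """
    warnings: list[str] = []
    pairs = (
        (recomb_target, recomb_curve),
        (control_target, control_curve),
    )
    quantities = {}
    replicate_q = {}
    for name, curve in pairs:
        rows = ct._rows(name, tube)
        mean_ct = float(rows.mean())
        if not curve.in_range(mean_ct):
            warnings.append(
                f"mean Ct {mean_ct:.2f} for {name!r} outside calibrated range "
                f"{curve.ct_range}"
            )
        quantities[name] = curve.quantity(mean_ct)
        replicate_q[name] = np.array([curve.quantity(v) for v in rows])
    ratio = quantities[recomb_target] / quantities[control_target]
    n = min(len(replicate_q[recomb_target]), len(replicate_q[control_target]))
    rep_ratios = replicate_q[recomb_target][:n] / replicate_q[control_target][:n]
    sd = float(np.std(rep_ratios, ddof=1)) if n > 1 else 0.0
    return RecombinationResult(
        ratio=float(ratio), replicate_ratios=rep_ratios, sd=sd, warnings=warnings
    )
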