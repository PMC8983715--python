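"""Downstream assay arithmetic: qPCR effect sizes, expression indices,
kinetic and equilibrium binding, viability and imaging ratios.

These are the scalar/curve computations applied to candidate aptamers and
their saRNA conjugates once sequencing analysis has produced a short list:
the delta-Ct effect-size statistic used to rank saRNAs, the 18S-normalized
expression index, the equilibrium dissociation constant from SPR rate
constants, a one-site saturation fit for apparent K_D from titration MFI,
the dye-based viability index, and the in-vivo imaging signal-to-background
ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "QpcrTriplicate",
    "KineticRates",
    "BindingCurve",
    "SaturationFit",
    "effect_size",
    "classify_effect",
    "expression_index",
    "kd_from_kinetics",
    "fit_saturation",
    "viability_index",
    "signal_to_background",
]


@dataclass(frozen=True)
class QpcrTriplicate:
    """Replicate CT values for a target gene and the 18S reference under
    one condition.  ``delta_ct`` is CT_gene - CT_ref per replicate and
    ``linear`` its 2^-dCT transform."""

    condition: str
    ct_gene: tuple[float, ...]
    ct_ref: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_gene) != len(self.ct_ref):
            raise ValueError("ct_gene and ct_ref must have equal length")
        if len(self.ct_gene) < 2:
            raise ValueError("need at least two replicates")
        for v in (*self.ct_gene, *self.ct_ref):
            if not 0.0 < v < 45.0:
                raise ValueError(f"CT value {v} outside (0, 45)")

    @property
    def delta_ct(self) -> np.ndarray:
        return np.asarray(self.ct_gene) - np.asarray(self.ct_ref)

    @property
    def linear(self) -> np.ndarray:
        return np.exp2(-self.delta_ct)


def effect_size(exp: QpcrTriplicate, ctrl: QpcrTriplicate) -> float:
    """saRNA activity statistic ``(mean 2^-dCT_exp - mean 2^-dCT_ctrl) / SD_exp``.

    SD_exp is the sample standard deviation (n-1) of the experimental
    replicates' linear values -- the only scale on which the published
    formula is dimensionally coherent.  Zero experimental SD leaves the
    statistic undefined.
    """
    l_exp = exp.linear
    l_ctrl = ctrl.linear
    sd = l_exp.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("SD of experimental replicates is zero; "
                                "effect size undefined")
    return float((l_exp.mean() - l_ctrl.mean()) / sd)


def classify_effect(es: float, up_strong: float = 4.0, up_modest: float = 2.0,
                    down: float = -2.0) -> str:
    """Categorize an effect size: ``strong_up`` (es > 4), ``modest_up``
    (4 >= es > 2), ``down`` (es <= -2 by default), else ``neutral``."""
    if not down < up_modest < up_strong:
        raise ValueError("need down < up_modest < up_strong")
    if es > up_strong:
        return "strong_up"
    if es > up_modest:
        return "modest_up"
    if es <= down:
        return "down"
    return "neutral"


def expression_index(ct_gene, ct_ref) -> float:
    """Reference-normalized expression ``2^-(CT_gene - CT_ref) x 1000``.

    Accepts scalars or replicate vectors (evaluated on the means).
    """
    g = float(np.mean(ct_gene))
    r = float(np.mean(ct_ref))
    return 2.0 ** (-(g - r)) * 1000.0


@dataclass(frozen=True)
class KineticRates:
    """SPR association/dissociation rate constants."""

    ka: float  # M^-1 s^-1
    kd: float  # s^-1

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("ka must be positive")
        if self.kd < 0:
            raise ValueError("kd must be non-negative")


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def kd_from_kinetics(rates: KineticRates, sig_figs: int | None = None) -> float:
    """Equilibrium dissociation constant ``K_D = kd / ka`` (molar), with
    optional rounding to ``sig_figs`` significant figures."""
    kd = rates.kd / rates.ka
    if sig_figs is not None:
        kd = _round_sig(kd, sig_figs)
    return kd


@dataclass(frozen=True)
class BindingCurve:
    """Titration of ligand concentration (M) against measured MFI."""

    concentrations: tuple[float, ...]
    mfi: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.mfi):
            raise ValueError("concentrations and mfi must have equal length")
        if len(set(self.concentrations)) < 4:
            raise ValueError("need at least 4 distinct concentrations")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class SaturationFit:
    """One-site specific-binding fit ``MFI(L) = Bmax L / (K_D + L) + c``."""

    bmax: float
    kd_app: float
    baseline: float
    rss: float

    def predict(self, conc) -> np.ndarray:
        L = np.asarray(conc, dtype=float)
        return self.bmax * L / (self.kd_app + L) + self.baseline


class UnidentifiableFitError(RuntimeError):
    """The apparent K_D cannot be determined from the titration."""


def _one_site(L, bmax, kd, c):
    return bmax * L / (kd + L) + c


def fit_saturation(curve: BindingCurve) -> SaturationFit:
    """Least-squares one-site fit with multi-start K_D initialization.

    K_D is initialized at the minimum, geometric mean and maximum of the
    concentration range; the best fit by residual sum of squares wins.
    Raises :class:`UnidentifiableFitError` when no start converges or the
    fitted K_D falls outside ``[min(L)/100, 100 max(L)]`` (a flat or
    unsaturated curve).
    """
    L = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.mfi, dtype=float)
    span = y.max() - y.min()
    geo = float(np.exp(np.mean(np.log(L))))
    best: SaturationFit | None = None
    for kd0 in (L.min(), geo, L.max()):
        p0 = (span if span > 0 else 1.0, kd0, y.min())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_one_site, L, y, p0=p0, maxfev=20_000)
        except RuntimeError:
            continue
        bmax, kd, c = popt
        rss = float(((y - _one_site(L, *popt)) ** 2).sum())
        fit = SaturationFit(float(bmax), float(kd), float(c), rss)
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        raise UnidentifiableFitError("no start converged")
    if abs(best.bmax) <= 1e-6 * (np.abs(y).max() + 1.0):
        raise UnidentifiableFitError(
            "no concentration-dependent signal (Bmax ~ 0); K_D undefined")
    if not (L.min() / 100.0 <= best.kd_app <= 100.0 * L.max()):
        raise UnidentifiableFitError(
            f"fitted K_D {best.kd_app:.3g} M outside the identifiable range")
    return best


def viability_index(green_area: float, red_area: float) -> float:
    """Dye-based viability: ``green / (green + red) x 100`` (percent)."""
    if green_area < 0 or red_area < 0:
        raise ValueError("areas must be non-negative")
    total = green_area + red_area
    if total == 0:
        raise ZeroDivisionError("both areas are zero; viability undefined")
    return 100.0 * green_area / total


def signal_to_background(roi_radiance: float, bg_radiance: float,
                         auto_roi: float = 0.0, auto_bg: float = 0.0) -> float:
    """Imaging ratio ``(ROI - auto_ROI) / (background - auto_background)``
    after subtracting the autofluorescence of non-injected animals."""
    denom = bg_radiance - auto_bg
    if denom <= 0:
        raise ValueError("background minus autofluorescence must be positive")
    return (roi_radiance - auto_roi) / denom
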