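"""Absolute qPCR quantification of ribotype copy number per 2C.

A plasmid standard of known insert length L carries a computable number of
template copies per nanogram (Avogadro arithmetic at 660 g/mol/bp).  A
10-fold dilution series of the standard yields a calibration line

    Cq = a x log10(copies) + b,      E = 10^(-1/a) - 1,

whose inversion converts sample Cq values to copies per reaction.  Dividing
by the template input (ng) and multiplying by the genome size (pg per 2C)
gives copies per 2C, the scale used throughout the package.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

AVOGADRO = 6.022e23
#: mean molecular weight of one dsDNA base pair, g/mol
BP_MOLAR_MASS = 660.0

#: default detection limit: below one template copy per reaction -> "n.d."
DETECTION_LIMIT_COPIES = 1.0


def copies_per_ng(insert_length_L: int) -> float:
    """Copies of a linear dsDNA fragment of length L in 1 ng.

    copies/ng = 6.022e23 / (L x 1e9 x 660); the 1e9 converts g/mol to
    ng/mol.  (A widely circulated variant of this formula prints the
    exponent as 10^-9, which is a units error of 10^18.)
    """
    if insert_length_L <= 0:
        raise ValueError("insert length must be positive")
    return AVOGADRO / (insert_length_L * 1e9 * BP_MOLAR_MASS)


def make_standard_series(
    insert_length_L: int,
    plasmid_conc_ng_per_ul: float = 1.0,
    dilution_factor: float = 10.0,
    n_points: int = 8,
) -> np.ndarray:
    """Copies per microlitre at each point of a serial dilution.

    Point i carries copies_per_ng(L) x conc / dilution_factor**i.
    """
    if n_points < 2:
        raise ValueError("need at least 2 dilution points")
    c0 = copies_per_ng(insert_length_L) * plasmid_conc_ng_per_ul
    return c0 / dilution_factor ** np.arange(n_points)


def dilution_indices_for_range(
    start_copies: float,
    dilution_factor: float = 10.0,
    high: float = 1e6,
    low: float = 1.0,
) -> tuple[int, int]:
    """Inclusive dilution-index range whose copies fall within [low, high].

    Used to locate the 10^6 -> 1 working range of a standard series that
    starts from the undiluted plasmid concentration.
    """
    if start_copies < low:
        raise ValueError("start_copies below the requested range")
    first = max(0, math.ceil(math.log(start_copies / high, dilution_factor)))
    last = math.floor(math.log(start_copies / low, dilution_factor))
    return first, last


# ---------------------------------------------------------------------------
# standard curves


@dataclasses.dataclass
class StandardCurve:
    """A fitted calibration line Cq = a log10(copies) + b.

    ``efficiency_e`` is the per-cycle amplification efficiency implied by
    the slope (E = 1 means perfect doubling).
    """

    assay: str
    slope_a: float
    intercept_b: float
    r_squared: float
    efficiency_e: float
    n_obs: int = 0

    def predict_cq(self, copies) -> np.ndarray:
        return self.slope_a * np.log10(copies) + self.intercept_b

    def copies_from_cq(self, cq) -> np.ndarray:
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept_b) / self.slope_a)

    def summary(self) -> str:
        return "\n".join(
            [
                f"Standard curve [{self.assay}]",
                "=" * 40,
                f"slope a:        {self.slope_a:.4f} Cq per log10(copies)",
                f"intercept b:    {self.intercept_b:.4f} Cq",
                f"R-squared:      {self.r_squared:.6f}",
                f"efficiency E:   {self.efficiency_e:.4f}  (1.0 = perfect doubling)",
                f"observations:   {self.n_obs}",
            ]
        )

    def plot(self, points=None, ax=None):
        """Diagnostic plot of the calibration line (and optional points)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if points is not None:
            copies, cqs = _flatten_points(points)
            ax.scatter(np.log10(copies), cqs, s=12, label="standards")
        span = np.array([0.0, 7.0])
        ax.plot(span, self.slope_a * span + self.intercept_b, label=f"E = {self.efficiency_e:.3f}")
        ax.set_xlabel("log10(copies per reaction)")
        ax.set_ylabel("Cq")
        ax.legend()
        return ax


def _flatten_points(points) -> tuple[np.ndarray, np.ndarray]:
    """Normalize the accepted point containers to flat (copies, cq) arrays."""
    if hasattr(points, "wells"):  # QpcrPlateSim
        points = [(c, list(r)) for c, r in points.wells]
    if isinstance(points, pd.DataFrame):
        return points["true_copies"].to_numpy(float), points["cq"].to_numpy(float)
    copies, cqs = [], []
    for c, reps in points:
        reps = np.atleast_1d(reps)
        copies.extend([c] * reps.size)
        cqs.extend(float(v) for v in reps)
    return np.asarray(copies, dtype=float), np.asarray(cqs, dtype=float)


class StandardCurveModel:
    """Calibration-curve model over a dilution series.

    Accepts a QpcrPlateSim, a tidy DataFrame (true_copies, cq), or an
    iterable of (copies, replicate Cq list) pairs.  ``fit`` runs ordinary
    least squares of Cq on log10(copies) over all replicates.
    """

    def __init__(self, points, assay: str = "assay"):
        self.assay = getattr(points, "assay", assay)
        self.copies, self.cq = _flatten_points(points)
        if (self.copies <= 0).any():
            raise ValueError("standard copies must be positive")
        if np.unique(self.copies).size < 3:
            raise ValueError("degenerate design: need >= 3 distinct copy levels")

    def fit(self) -> StandardCurve:
        x = sm.add_constant(np.log10(self.copies))
        res = sm.OLS(self.cq, x).fit()
        intercept, slope = res.params
        if slope >= 0:
            warnings.warn("non-negative standard-curve slope; assay is not amplifying", stacklevel=2)
        efficiency = 10.0 ** (-1.0 / slope) - 1.0
        return StandardCurve(
            assay=self.assay,
            slope_a=float(slope),
            intercept_b=float(intercept),
            r_squared=float(res.rsquared),
            efficiency_e=float(efficiency),
            n_obs=int(res.nobs),
        )


def fit_standard_curve(points, assay: str = "assay") -> StandardCurve:
    """Least-squares calibration line over all replicates of a series."""
    return StandardCurveModel(points, assay=assay).fit()


# ---------------------------------------------------------------------------
# absolute quantification


@dataclasses.dataclass
class SampleQuant:
    """Per-sample, per-assay absolute quantification result."""

    sample: str
    assay: str
    copies_per_ng_template: float
    replicate_values: list[float]
    replicate_sd: float
    copies_per_2c: float | None = None
    sd_per_2c: float | None = None
    not_detected: bool = False


def quantify_absolute(
    cq_replicates: Sequence[float],
    curve: StandardCurve,
    template_ng_per_reaction: float = 1.0,
    *,
    sample: str = "sample",
    detection_limit_copies: float = DETECTION_LIMIT_COPIES,
) -> SampleQuant:
    """Invert replicate Cq values through the standard curve.

    Replicates are averaged on the copies scale after inversion (absolute-
    quantification semantics); non-finite Cq replicates are dropped with a
    warning.  A mean below ``detection_limit_copies`` per reaction flags the
    result as not detected.
    """
    if template_ng_per_reaction <= 0:
        raise ValueError("template_ng_per_reaction must be positive")
    cq = np.asarray(cq_replicates, dtype=float)
    finite = np.isfinite(cq)
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} non-finite Cq replicate(s)", stacklevel=2)
    cq = cq[finite]
    if cq.size == 0:
        raise ValueError("all Cq replicates non-finite")
    copies = curve.copies_from_cq(cq)
    mean_copies = float(copies.mean())
    sd = float(copies.std(ddof=1)) if copies.size > 1 else 0.0
    return SampleQuant(
        sample=sample,
        assay=curve.assay,
        copies_per_ng_template=mean_copies / template_ng_per_reaction,
        replicate_values=[float(c) for c in copies],
        replicate_sd=sd / template_ng_per_reaction,
        not_detected=mean_copies < detection_limit_copies,
    )


def normalize_to_2c(copies_per_ng_template: float, two_c_pg: float) -> float:
    """Copies per 2C = copies/ng x 2C size in pg x 10^-3 (1 pg = 10^-3 ng)."""
    if two_c_pg <= 0:
        raise ValueError("two_c_pg must be positive")
    return copies_per_ng_template * two_c_pg * 1e-3


def quant_to_2c(quant: SampleQuant, two_c_pg: float) -> SampleQuant:
    """Return a copy of *quant* with per-2C fields filled in."""
    return dataclasses.replace(
        quant,
        copies_per_2c=normalize_to_2c(quant.copies_per_ng_template, two_c_pg),
        sd_per_2c=normalize_to_2c(quant.replicate_sd, two_c_pg),
    )


def native_overestimation_bound(total_cn: float, foreign_cns: Mapping[str, float] | Iterable[float]) -> float:
    """Maximal relative overestimate of the native copy number.

    When a universal (native + foreign) assay proxies the native ribotype,
    the native estimate is inflated by at most sum(foreign) / total.
    """
    if total_cn <= 0:
        raise ValueError("total_cn must be positive")
    values = list(foreign_cns.values()) if isinstance(foreign_cns, Mapping) else list(foreign_cns)
    if any(v < 0 for v in values):
        raise ValueError("foreign copy numbers must be >= 0")
    return sum(values) / total_cn
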