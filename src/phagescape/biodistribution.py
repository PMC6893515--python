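"""Phage biodistribution arithmetic: titering, infectivity correction, qPCR
standard curves, and percent-injected-dose-per-gram.

Two complementary quantifications of phage recovered from tissue homogenates:
biological titering counts transducing units (TU, infectious particles) and is
corrected to physical virions with the batch infectivity; qPCR counts total
phage genomes against a 10-fold serial-dilution standard curve, normalized to
mammalian gDNA content and tissue mass to give vir/g and %ID/g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress

REPLICATE_CV_FLAG = 0.10  # flag replicate sets with CV above 10%


@dataclass(frozen=True)
class TiterMeasurement:
    colonies: int  # TU counted in the plated aliquot
    tissue_mass_in_volume: float  # g of tissue in the titered aliquot
    dilution_factor: float = 1.0
    batch_infectivity: float = 1.0  # TU per virion for the batch standard

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colony count must be >= 0")
        if not 0 < self.batch_infectivity <= 1:
            raise ValueError("infectivity must lie in (0, 1]")


@dataclass(frozen=True)
class StandardCurve:
    """Cq = slope * log10(concentration) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency in percent per cycle: 100 * (10^(-1/slope) - 1)."""
        return 100.0 * (10.0 ** (-1.0 / self.slope) - 1.0)


@dataclass(frozen=True)
class TissueQuantification:
    phage_concentration: float  # vir/uL
    mgdna_concentration: float  # ng mammalian gDNA/uL
    gdna_yield: float  # ng mgDNA recovered per g tissue
    injected_dose: float  # virions injected


def titer_per_gram(m: TiterMeasurement) -> float:
    """TU per gram of tissue from one titering measurement."""
    if m.tissue_mass_in_volume <= 0:
        raise ValueError("tissue mass in the titered volume must be > 0")
    return m.colonies * m.dilution_factor / m.tissue_mass_in_volume


def infectivity_correct(tu: float, infectivity: float) -> float:
    """Convert transducing units to physical virions using the batch
    infectivity (TU/vir)."""
    if infectivity <= 0:
        raise ValueError("infectivity must be > 0")
    return tu / infectivity


def fit_standard_curve(dilutions: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares Cq vs log10(concentration) fit of a serial-dilution series."""
    if len(dilutions) < 3:
        raise ValueError("need at least 3 standard points")
    conc = np.array([c for c, _ in dilutions], dtype=float)
    cq = np.array([q for _, q in dilutions], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")
    x = np.log10(conc)
    if x.max() - x.min() < 2.0:
        raise ValueError("standards must span at least two decades")
    fit = linregress(x, cq)
    return StandardCurve(slope=fit.slope, intercept=fit.intercept, r_squared=fit.rvalue**2)


def quantify_sample(cq: float, curve: StandardCurve, dilution: float = 1.0) -> float:
    """Invert the standard curve: concentration = dilution * 10^((cq - b)/m)."""
    return dilution * 10.0 ** ((cq - curve.intercept) / curve.slope)


def quantify_replicates(
    cqs: Sequence[float], curve: StandardCurve, dilution: float = 1.0
) -> tuple[float, float, bool]:
    """Mean +/- sample standard deviation (ddof=1) of replicate quantifications,
    with a flag raised when the replicate CV exceeds 10%."""
    values = np.array([quantify_sample(c, curve, dilution) for c in cqs], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    flagged = bool(mean > 0 and sd / mean > REPLICATE_CV_FLAG)
    return mean, sd, flagged


def vir_per_gram_and_id(q: TissueQuantification) -> tuple[float, float]:
    """(vir/g, %ID/g) from qPCR concentrations and gDNA yield.

    vir/g = (phage conc / mgDNA conc) * gDNA yield;
    %ID/g = 100 * (vir/g) / injected dose.
    """
    if q.mgdna_concentration <= 0:
        raise ValueError("mgDNA concentration must be > 0")
    if q.injected_dose <= 0:
        raise ValueError("injected dose must be > 0")
    vir_g = (q.phage_concentration / q.mgdna_concentration) * q.gdna_yield
    pct_id_g = 100.0 * vir_g / q.injected_dose
    return vir_g, pct_id_g
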