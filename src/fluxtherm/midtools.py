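"""Measurement-model utilities for MID tables.

Covers the corrections and inferences applied between the mass spectrometer
and the flux fit: removal of naturally occurring 13C from measured MIDs
(2H data pass through uncorrected, since 2H natural abundance is ~0.02%),
inference of unmeasurable precursors from surrogate metabolite pairs that
differ by one added unit (CO2 from ornithine/citrulline, the acetyl unit
from ornithine/acetylornithine, the one-carbon THF unit from
threonine/methionine), and isotope-ratio absolute quantitation against
internal standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .emu import C13_NATURAL_ABUNDANCE, MIDVector

#: precursor inferred from (product, precursor) surrogate pairs
SURROGATE_MAP = {
    "pyruvate": ("valine", None),
    "oxaloacetate": ("aspartate", None),
    "co2": ("citrulline", "ornithine"),
    "acetyl": ("acetylornithine", "ornithine"),
    "c1_thf": ("methionine", "threonine"),
}


@dataclass(frozen=True)
class ElementalFormula:
    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    S: int = 0

    def __post_init__(self):
        for el in ("C", "H", "N", "O", "P", "S"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")


def contamination_matrix(n_fragment: int, n_carbons: int,
                         p13: float = C13_NATURAL_ABUNDANCE) -> np.ndarray:
    """Binomial 13C contamination operator.

    Column j (j labeled carbons) spreads onto rows i >= j with probability
    of i - j natural 13C among the n_carbons - j remaining positions.
    Rows are truncated to the measured window 0..n_fragment.
    """
    from scipy.stats import binom
    C = np.zeros((n_fragment + 1, n_fragment + 1))
    for j in range(n_fragment + 1):
        rem = n_carbons - j
        for i in range(j, n_fragment + 1):
            k = i - j
            if k <= rem:
                C[i, j] = binom.pmf(k, rem, p13)
    return C


def correct_natural_abundance(raw: MIDVector, formula: ElementalFormula,
                              p13: float = C13_NATURAL_ABUNDANCE,
                              is_2h: bool = False) -> MIDVector:
    """Invert the natural-abundance contamination of a measured 13C MID.

    Solves C m = raw as non-negative least squares (a raw matrix inverse can
    return negative fractions on noisy data) and renormalizes.  2H data are
    returned unchanged (``is_2h=True``), matching common practice of not
    correcting for deuterium natural abundance.
    """
    if is_2h or p13 == 0.0:
        return MIDVector(raw.fragment, raw.fractions.copy(), raw.sd)
    nf = len(raw.fractions) - 1
    if formula.C < nf:
        raise ValueError(
            f"{raw.fragment}: formula has {formula.C} carbons but the MID "
            f"spans {nf}")
    C = contamination_matrix(nf, formula.C, p13)
    if np.linalg.cond(C) > 1e8:
        warnings.warn(f"{raw.fragment}: ill-conditioned correction matrix "
                      f"(formula C={formula.C}, fragment {nf})")
    m, _ = nnls(C, raw.fractions)
    total = m.sum()
    if total <= 0:
        raise ValueError(f"{raw.fragment}: correction annihilated the MID")
    return MIDVector(raw.fragment, m / total, raw.sd)


def corrupt_natural_abundance(true: MIDVector, formula: ElementalFormula,
                              p13: float = C13_NATURAL_ABUNDANCE) -> MIDVector:
    """Forward contamination operator (the model the correction inverts)."""
    nf = len(true.fractions) - 1
    C = contamination_matrix(nf, formula.C, p13)
    raw = C @ true.fractions
    return MIDVector(true.fragment, raw / raw.sum(), true.sd)


def deconvolve_surrogate(product: MIDVector, precursor: MIDVector,
                         residual_threshold: float = 1e-3
                         ) -> tuple[MIDVector, float, list[str]]:
    """Infer the MID of the unit added between a precursor and its product.

    Assumes product = precursor (x) unit, so the unit's MID is recovered by
    non-negative least-squares deconvolution.  Returns (unit, residual norm,
    diagnostics); a residual above threshold flags an inconsistent pair.
    """
    if len(product) < len(precursor):
        raise ValueError("product MID must be at least as long as precursor")
    n_unit = len(product) - len(precursor) + 1
    # convolution matrix: columns shift the precursor
    A = np.zeros((len(product), n_unit))
    for j in range(n_unit):
        A[j:j + len(precursor), j] = precursor.fractions
    unit, rnorm = nnls(A, product.fractions)
    total = unit.sum()
    if total <= 0:
        raise ValueError("deconvolution produced an empty unit MID")
    unit = unit / total
    diags = []
    resid = float(np.linalg.norm(A @ (unit * total) - product.fractions))
    if resid > residual_threshold:
        diags.append(f"inconsistent precursor/product pair (residual {resid:.3g})")
    return MIDVector(f"{product.fragment}/{precursor.fragment}", unit), resid, diags


@dataclass(frozen=True)
class QuantSample:
    labeled_intensity: float
    standard_intensity: float
    standard_conc: float                 # uM
    mixing_ratio: float = 1.0            # target:reference volume ratio

    def __post_init__(self):
        if self.labeled_intensity < 0 or self.standard_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.standard_conc <= 0:
            raise ValueError("standard concentration must be positive")
        if self.mixing_ratio <= 0:
            raise ValueError("mixing ratio must be positive")


def quantify_by_isotope_ratio(sample: QuantSample) -> float:
    """Concentration from the labeled/standard peak-intensity ratio (uM).

    For a two-extract mix the reference extract contributes the labeled
    peak at ``standard_conc``; the target's concentration scales with the
    observed ratio divided by the target:reference mixing ratio.
    """
    if sample.standard_intensity == 0:
        raise ValueError("standard peak intensity is zero")
    ratio = sample.labeled_intensity / sample.standard_intensity
    return ratio * sample.standard_conc / sample.mixing_ratio
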