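"""Diameter-based size conversions for trees and palms.

Basal area is the cross-sectional stem area at the point of measurement.
Above-ground biomass (AGB, kg) comes from a pan-tropical allometry in
diameter D (cm), wood density ``wd`` (g cm^-3) and the bioclimatic stress
variable E (dimensionless):

    ln AGB = c0 + c1*E + c2*ln(wd) + c3*ln(D) + c4*(ln D)^2

Palms lack secondary growth and use a diameter-only power law. Coefficients
are configuration, not code: the defaults carry provenance strings and every
pipeline stage accepts an :class:`AllometryParams` override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AllometryParams", "DEFAULT_PARAMS", "basal_area", "tree_agb", "palm_agb"]


@dataclass(frozen=True)
class AllometryParams:
    """Coefficients for the tree and palm biomass equations.

    Tree equation: ln AGB = intercept + e_coef*E + wd_exp*ln(wd)
    + lnd_coef*ln(D) + lnd2_coef*(ln D)^2, with D in cm, AGB in kg.

    Palm equation: ln AGB = palm_intercept + palm_lnd_coef*ln(D).
    Set the palm coefficients to ``None`` to disable palm conversion.
    """

    tree_intercept: float = -1.803
    tree_e_coef: float = -0.976
    tree_wd_exp: float = 0.976
    tree_lnd_coef: float = 2.673
    tree_lnd2_coef: float = -0.0299
    palm_intercept: float | None = -3.3488
    palm_lnd_coef: float | None = 2.7483
    provenance: str = (
        "tree: pan-tropical D/wd/E model, Chave et al. 2014 (eq. 7); "
        "palm: Arecaceae family diameter model, Goodman et al. 2013"
    )

    def __post_init__(self) -> None:
        vals = [
            self.tree_intercept,
            self.tree_e_coef,
            self.tree_wd_exp,
            self.tree_lnd_coef,
            self.tree_lnd2_coef,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("tree allometry coefficients must be finite")
        if not self.provenance:
            raise ValueError("provenance note must be non-empty")


DEFAULT_PARAMS = AllometryParams()


def basal_area(d):
    """Basal area (m^2) of a stem of diameter ``d`` (cm): pi*(d/200)^2."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.pi * (d / 200.0) ** 2
    return float(out) if out.ndim == 0 else out


def tree_agb(d, wd, e, params: AllometryParams = DEFAULT_PARAMS):
    """Above-ground biomass (kg) of a dicot tree.

    Parameters
    ----------
    d : array_like
        Diameter at the point of measurement, cm.
    wd : array_like
        Wood density, g cm^-3.
    e : array_like
        Environmental stress E of the plot (dimensionless).
    """
    d = np.asarray(d, dtype=float)
    wd = np.asarray(wd, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if np.any(wd <= 0):
        raise ValueError("wood density must be positive")
    if not np.all(np.isfinite(e)):
        raise ValueError("E must be finite")
    lnd = np.log(d)
    ln_agb = (
        params.tree_intercept
        + params.tree_e_coef * e
        + params.tree_wd_exp * np.log(wd)
        + params.tree_lnd_coef * lnd
        + params.tree_lnd2_coef * lnd**2
    )
    out = np.exp(ln_agb)
    return float(out) if out.ndim == 0 else out


def palm_agb(d, params: AllometryParams = DEFAULT_PARAMS):
    """Above-ground biomass (kg) of a palm from diameter alone."""
    if params.palm_intercept is None or params.palm_lnd_coef is None:
        raise ValueError(
            "palm allometry coefficients are unset; supply palm_intercept and "
            "palm_lnd_coef via AllometryParams (config block)"
        )
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.exp(params.palm_intercept + params.palm_lnd_coef * np.log(d))
    return float(out) if out.ndim == 0 else out
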