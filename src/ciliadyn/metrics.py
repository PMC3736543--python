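"""Closed-form transport metrics: Péclet number and transit times.

The Péclet number Pe = U·R/D compares advection by fluid motion (speed U
over a structure of radius R) with diffusion (coefficient D); Pe < 1 means
diffusion outpaces advection.  For a cilium, U is of the order of IFT motor
speeds and R the ciliary radius, so Pe quantifies how much the constant
traffic of IFT trains could stir the ciliary content.
"""

from __future__ import annotations

__all__ = ["peclet", "diffusive_transit_time", "ballistic_transit_time"]


def peclet(U: float, R: float, D: float) -> float:
    """Péclet number U·R/D (dimensionless).

    Units of U, R and D must be consistent (all cm-based or all μm-based);
    the ratio is invariant under a common rescaling.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if U <= 0 or R <= 0:
        raise ValueError("U and R must be positive")
    return U * R / D


def diffusive_transit_time(L: float, D: float) -> float:
    """Mean-squared-displacement time L²/(2·D) to traverse a 1D span L.

    With L in μm and D in μm²/s the result is in seconds.
    """
    if L <= 0 or D <= 0:
        raise ValueError("L and D must be positive")
    return L * L / (2.0 * D)


def ballistic_transit_time(L: float, v: float) -> float:
    """Time L/v for motor-driven transport to cover a span L at speed v."""
    if L <= 0 or v <= 0:
        raise ValueError("L and v must be positive")
    return L / v
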