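"""Extensible worm-like chain (XWLC) polymer mechanics.

Converts between applied force, tether extension, and base pairs of a DNA
hairpin unwound, for the standard dual-trap geometry in which a hairpin stem
is flanked by long dsDNA handles.  Unwinding one base pair of the stem
releases two nucleotides of ssDNA, so at constant force the change in
end-to-end extension is proportional to the number of base pairs opened.

The per-monomer extension uses the Marko-Siggia interpolation with an
additive enthalpic stretching term,

    xi(F) = h * (1 - 1/2 * sqrt(kBT / (F * P)) + F / S),

applied identically to the double-stranded (per bp) and single-stranded
(per nt) species with their respective persistence lengths, contour lengths
and stretch moduli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Thermal energy at 298 K, pN nm.
KBT_ROOM = 4.11


@dataclass(frozen=True)
class WlcParams:
    """Elastic parameters of one polymer species.

    Parameters
    ----------
    persistence_length : float
        Persistence length P, nm.
    contour_per_monomer : float
        Contour length h per bp (dsDNA) or per nt (ssDNA), nm.
    stretch_modulus : float
        Enthalpic stretch modulus S, pN.
    thermal_energy : float
        kBT, pN nm.  Default corresponds to room temperature (298 K).
    """

    persistence_length: float
    contour_per_monomer: float
    stretch_modulus: float = 1000.0
    thermal_energy: float = KBT_ROOM

    def __post_init__(self) -> None:
        for name in ("persistence_length", "contour_per_monomer",
                     "stretch_modulus", "thermal_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: dsDNA defaults: P = 50 nm, h = 0.34 nm/bp, S = 1000 pN.
DSDNA = WlcParams(persistence_length=50.0, contour_per_monomer=0.34)
#: ssDNA defaults: P = 1.0 nm, h = 0.59 nm/nt, S = 1000 pN.
SSDNA = WlcParams(persistence_length=1.0, contour_per_monomer=0.59)


@dataclass(frozen=True)
class ConstructGeometry:
    """Hairpin construct bookkeeping: an 89 bp stem capped by a 4 nt loop,
    flanked by dsDNA handles, with a 10 nt ssDNA helicase loading site."""

    handle_bp: int = 3050
    loading_site_nt: int = 10
    stem_bp: int = 89
    loop_nt: int = 4

    @property
    def open_ss_nt(self) -> int:
        """ssDNA nucleotides exposed when the stem is fully unwound."""
        return self.loading_site_nt + 2 * self.stem_bp + self.loop_nt

    def __post_init__(self) -> None:
        if min(self.handle_bp, self.loading_site_nt,
               self.stem_bp, self.loop_nt) < 0:
            raise ValueError("construct counts must be non-negative")


def monomer_extension(force, params: WlcParams):
    """Extension of one monomer (bp or nt) at a given force, nm.

    Marko-Siggia interpolation with enthalpic stretch:
    xi(F) = h (1 - 1/2 sqrt(kBT/(F P)) + F/S).  Strictly increasing in F
    and bounded above by h (1 + F/S).

    Parameters
    ----------
    force : float or array
        Applied force, pN.  Must be strictly positive.
    params : WlcParams
    """
    force = np.asarray(force, dtype=float)
    if np.any(force <= 0):
        raise ValueError("force must be strictly positive")
    rel = (1.0
           - 0.5 * np.sqrt(params.thermal_energy
                           / (force * params.persistence_length))
           + force / params.stretch_modulus)
    out = params.contour_per_monomer * rel
    return out if out.ndim else float(out)


def construct_extension(force, n_ds, n_ss, *,
                        ds_params: WlcParams = DSDNA,
                        ss_params: WlcParams = SSDNA):
    """End-to-end extension of a mixed ds/ss construct, nm.

    Additive superposition: x(F) = N_ds xi_ds(F) + N_ss xi_ss(F).
    """
    if n_ds < 0 or n_ss < 0:
        raise ValueError("monomer counts must be non-negative")
    return (n_ds * monomer_extension(force, ds_params)
            + n_ss * monomer_extension(force, ss_params))


def bp_unwound(delta_x, force, *, ss_params: WlcParams = SSDNA):
    """Base pairs unwound from a change in extension at constant force.

    Each broken base pair releases two ssDNA nucleotides, so
    n = delta_x / (2 xi_ss(F)).  Real-valued: discretisation into steps
    belongs to step detection, not here.
    """
    return np.asarray(delta_x, dtype=float) / (
        2.0 * monomer_extension(force, ss_params))


def extension_for_bp(n, force, *, ss_params: WlcParams = SSDNA):
    """Change in extension produced by unwinding ``n`` base pairs, nm.

    Exact inverse of :func:`bp_unwound`.
    """
    return np.asarray(n, dtype=float) * 2.0 * monomer_extension(force, ss_params)
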