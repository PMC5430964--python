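"""Mapping between simulation units and physical units.

The coarse-grained chain is a freely jointed (Gaussian) bead-spring polymer
whose bead diameter sigma is identified with the Kuhn segment length of
dye-labelled double-stranded DNA (~134 nm).  Lengths therefore convert as
``nm = sigma * sigma_nm``; diffusivities need, in addition, the physical
duration of one bead diffusion time ``t_D`` (the time for a single bead to
diffuse its own diameter), which is not fixed by the length mapping alone and
must be calibrated separately.
"""

from __future__ import annotations

from dataclasses import dataclass


class MissingCalibrationError(ValueError):
    """A conversion was requested that needs an unset calibration constant."""


@dataclass(frozen=True)
class UnitMap:
    """Length/time mapping between simulation and physical units.

    Parameters
    ----------
    sigma_nm : float
        Physical length of one bead diameter sigma, in nm.  Defaults to the
        Kuhn length of YOYO-labelled lambda-DNA, 134 nm.
    n_beads : int
        Number of beads of the mapped chain (160 for lambda-DNA).
    t_D_s : float or None
        Physical duration of one diffusion time t_D in seconds.  Unset by
        default; required only for diffusivity conversion.
    """

    sigma_nm: float = 134.0
    n_beads: int = 160
    t_D_s: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma_nm > 0:
            raise ValueError(f"sigma_nm must be positive, got {self.sigma_nm}")
        if self.n_beads < 1:
            raise ValueError(f"n_beads must be >= 1, got {self.n_beads}")
        if self.t_D_s is not None and not self.t_D_s > 0:
            raise ValueError(f"t_D_s must be positive, got {self.t_D_s}")

    @property
    def contour_length_nm(self) -> float:
        """Contour length of the mapped chain: (n_beads - 1) bonds x sigma."""
        return (self.n_beads - 1) * self.sigma_nm


def to_physical(unit_map: UnitMap, quantity: float, kind: str = "length") -> float:
    """Convert a simulation-unit quantity to physical units.

    Parameters
    ----------
    unit_map : UnitMap
    quantity : float
        Value in simulation units (sigma for lengths, sigma^2/t_D for
        diffusivities).
    kind : {"length", "diffusivity"}

    Returns
    -------
    float
        Lengths in nm, diffusivities in nm^2/s.
    """
    if kind == "length":
        return quantity * unit_map.sigma_nm
    if kind == "diffusivity":
        if unit_map.t_D_s is None:
            raise MissingCalibrationError(
                "diffusivity conversion requires t_D_s to be set on the UnitMap"
            )
        return quantity * unit_map.sigma_nm**2 / unit_map.t_D_s
    raise ValueError(f"unknown kind {kind!r}; expected 'length' or 'diffusivity'")
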