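"""Transwell apparatus geometry and hydrostatic volume matching.

The donor insert hangs inside the receptor well, separated by a porous
membrane.  If the fluid levels in the two compartments differ, hydrostatic
pressure drives bulk fluid across the membrane and corrupts the transfer
profile, so the medium volumes must be chosen to equalise the levels.  The
constants here come from 3D metrology of the 24 mm Transwell insert: each
compartment has an approximately constant cross-section over its working
height, so volume rises linearly with fluid height (mL per mm of rise) and
level matching reduces to a single affine relation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any, Mapping


class CapacityError(ValueError):
    """A requested fill volume exceeds a compartment's physical capacity."""


@dataclass(frozen=True)
class ApparatusGeometry:
    """Dimensional constants of the 24 mm Transwell system.

    Attributes
    ----------
    membrane_area : float
        Area of the polycarbonate membrane separating the compartments
        (``SM``), cm².
    donor_vol_per_mm : float
        Volume needed to raise the donor fluid level by 1 mm, mL/mm.
    receptor_annulus_vol_per_mm : float
        Volume per mm of rise in the receptor space above the membrane
        level (the annulus around the insert), mL/mm.
    receptor_min_volume : float
        Dead volume below the insert membrane; the minimum receptor fill
        that contacts the donor compartment, mL.
    filter_volume : float
        Volume of the drug-loaded glass-fibre filter paper sitting in the
        donor compartment (``V_f``), mL.  It displaces/absorbs medium and
        therefore counts towards the donor fluid height.
    membrane_wetting_volume : float
        Medium retained wetting the polycarbonate membrane (``W_v``), mL.
    donor_max_volume : float
        Donor capacity up to the side-wall holes, mL.
    receptor_max_volume : float
        Total receptor capacity up to the side-wall holes, mL.
    """

    membrane_area: float = 4.52
    donor_vol_per_mm: float = 0.47
    receptor_annulus_vol_per_mm: float = 0.35
    receptor_min_volume: float = 0.86
    filter_volume: float = 0.118
    membrane_wetting_volume: float = 0.1
    donor_max_volume: float = 4.52
    receptor_max_volume: float = 4.18

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ApparatusGeometry":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown geometry fields: {sorted(unknown)}")
        return cls(**dict(data))


def match_receptor_volume(
    donor_volume: float, geometry: ApparatusGeometry | None = None
) -> float:
    """Receptor volume giving equal fluid levels for a given donor volume.

    The donor fluid height above the membrane is ``(V_d + V_f) /
    donor_vol_per_mm``; filling the receptor annulus to the same height
    on top of the dead volume, plus the membrane wetting volume, gives

    ``V_r = ((V_d + V_f) / donor_vol_per_mm) * receptor_annulus_vol_per_mm
    + receptor_min_volume + W_v``

    Parameters
    ----------
    donor_volume : float
        Medium volume pipetted into the donor insert, mL (≥ 0).
    geometry : ApparatusGeometry, optional
        Apparatus constants; defaults to the measured 24 mm Transwell.

    Returns
    -------
    float
        Matched receptor volume in mL (unrounded).

    Raises
    ------
    CapacityError
        If the donor fill (including the filter) or the matched receptor
        fill would exceed the respective compartment capacity.
    """
    geom = geometry if geometry is not None else ApparatusGeometry()
    if donor_volume < 0:
        raise ValueError(f"donor_volume must be >= 0, got {donor_volume}")
    if donor_volume + geom.filter_volume > geom.donor_max_volume:
        raise CapacityError(
            f"donor fill {donor_volume} mL + filter {geom.filter_volume} mL "
            f"exceeds donor capacity {geom.donor_max_volume} mL"
        )
    height_mm = (donor_volume + geom.filter_volume) / geom.donor_vol_per_mm
    receptor = (
        height_mm * geom.receptor_annulus_vol_per_mm
        + geom.receptor_min_volume
        + geom.membrane_wetting_volume
    )
    # W_v wets the membrane rather than adding to the standing fluid column,
    # so the capacity check allows it on top of the geometric maximum.
    if receptor > geom.receptor_max_volume + geom.membrane_wetting_volume:
        raise CapacityError(
            f"matched receptor volume {receptor:.3f} mL exceeds receptor "
            f"capacity {geom.receptor_max_volume} mL"
        )
    return receptor
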