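"""Imaging-based quantification: detections → per-litre abundance and biovolume.

Two instruments are supported.  Confocal microscopy counts objects in a
small imaged subsample (Vi litres) of a net-concentrated sample; the
per-litre abundance in the original seawater is

    A = n_detections / (Vi × Cf),   Cf = (V_seawater / 3 L) × (45/50),

where Cf is the concentration factor of the net / cod-end-dilution /
fixation scheme.  The Underwater Vision Profiler (UVP5) images calibrated
in-situ volumes directly, so a colony concentration is simply
n / imaged_volume.  Object biovolumes come from the ellipsoid of the
measured major and minor axes; counting units are preserved per label
(symbiotic cells, filaments, colonies) and never summed across units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ImagingSample:
    """Sampling volumes for one imaged sample."""

    sample_id: str
    V_seawater: float
    Vi: float = 1e-3
    codend_dilution_volume: float = 3.0
    fixed_fraction: float = 45.0 / 50.0
    imaged_volume: float | None = None  # UVP5 calibrated in-situ volume, L

    def __post_init__(self) -> None:
        for v, name in (
            (self.V_seawater, "V_seawater"),
            (self.Vi, "Vi"),
            (self.codend_dilution_volume, "codend_dilution_volume"),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.fixed_fraction <= 1.0:
            raise ValueError("fixed_fraction must lie in (0, 1]")
        if self.imaged_volume is not None and self.imaged_volume <= 0:
            raise ValueError("imaged_volume must be > 0 when given")


def concentration_factor(sample: ImagingSample) -> float:
    """Cf = (V_seawater / cod-end dilution volume) × fixed fraction."""
    return (sample.V_seawater / sample.codend_dilution_volume) * sample.fixed_fraction


def abundance_from_detections(n_occurrences: int, sample: ImagingSample) -> float:
    """Per-litre abundance in the original seawater: A = n / (Vi × Cf)."""
    if n_occurrences < 0:
        raise ValueError("n_occurrences must be >= 0")
    cf = concentration_factor(sample)
    if sample.Vi <= 0 or cf <= 0:
        raise ValueError("Vi and Cf must be > 0")
    return n_occurrences / (sample.Vi * cf)


def ellipsoid_biovolume(major_um: float, minor_um: float, spheroid: str = "prolate") -> float:
    """Ellipsoid-equivalent biovolume (µm³) from the two measured axes.

    Images give only two axes; the third is taken equal to the minor axis
    (``prolate``, the default — (π/6)·major·minor²) or to the major axis
    (``oblate`` — (π/6)·major²·minor).
    """
    if major_um <= 0 or minor_um <= 0:
        raise ValueError("axes must be > 0")
    if minor_um > major_um:
        raise ValueError("minor axis exceeds major axis")
    if spheroid == "prolate":
        return (math.pi / 6.0) * major_um * minor_um**2
    if spheroid == "oblate":
        return (math.pi / 6.0) * major_um**2 * minor_um
    raise ValueError(f"unknown spheroid convention {spheroid!r}")


def uvp_concentration(n_colonies: int, imaged_volume: float) -> float:
    """Colony concentration (colonies/L) from an in-situ imaged volume."""
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    if imaged_volume <= 0:
        raise ValueError("imaged_volume must be > 0")
    return n_colonies / imaged_volume


def biovolume_per_liter(
    detections: pd.DataFrame,
    sample: ImagingSample,
    spheroid: str = "prolate",
) -> dict[str, float]:
    """Summed object biovolume per litre of seawater, per label (µm³/L).

    Confocal detections are normalised by Vi × Cf, UVP5 detections by the
    calibrated imaged_volume.  All detections must share the sample's id
    and a single instrument; mixing instruments in one aggregation is an
    error because their normalising volumes differ.
    """
    if detections.empty:
        return {}
    if not (detections["sample_id"] == sample.sample_id).all():
        raise ValueError("detections do not all belong to the given sample")
    instruments = detections["instrument"].unique()
    if len(instruments) != 1:
        raise ValueError(f"mixed instruments in one aggregation: {sorted(instruments)}")
    instrument = instruments[0]
    if instrument == "confocal":
        denom = sample.Vi * concentration_factor(sample)
    elif instrument == "uvp5":
        if sample.imaged_volume is None:
            raise ValueError("UVP5 aggregation requires sample.imaged_volume")
        denom = sample.imaged_volume
    else:
        raise ValueError(f"unknown instrument {instrument!r}")

    out: dict[str, float] = {}
    for label, grp in detections.groupby("label"):
        vol = sum(
            ellipsoid_biovolume(maj, mino, spheroid)
            for maj, mino in zip(grp["major_um"], grp["minor_um"])
        )
        out[str(label)] = vol / denom
    return out
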