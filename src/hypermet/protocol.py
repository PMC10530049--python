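"""Acquisition protocol description for the dynamic multi-metabolite EPI scan.

The default protocol mirrors the study conditions: 20 timeframes at 3 s
temporal resolution, five 3 cm slices on a 32x32 matrix, with pyruvate
acquired at 7.5 x 7.5 mm / 20 deg flip and the low-resolution metabolite
channels (glutamate and the two J-coupled lactate doublet peaks) at
22.5 x 22.5 mm / 60 deg flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["MetaboliteChannel", "AcquisitionProtocol", "default_protocol", "CHANNELS"]

#: fixed channel order used on every channel axis in the package
CHANNELS = ("pyruvate", "glutamate", "lactate_downfield", "lactate_upfield")

#: chemical shifts (ppm) of the four excited resonances
CHEMICAL_SHIFTS_PPM = {
    "pyruvate": 206.00,
    "glutamate": 182.29,
    "lactate_downfield": 72.39,
    "lactate_upfield": 67.90,
}


@dataclass(frozen=True)
class MetaboliteChannel:
    name: str
    in_plane_resolution_mm: float
    nominal_flip_deg: float
    chemical_shift_ppm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.name not in CHANNELS:
            raise ValueError(f"unknown channel {self.name!r}")
        if not 0.0 < self.nominal_flip_deg <= 90.0:
            raise ValueError("nominal flip must lie in (0, 90] degrees")
        expected = CHEMICAL_SHIFTS_PPM[self.name]
        if self.chemical_shift_ppm is None:
            object.__setattr__(self, "chemical_shift_ppm", expected)
        elif abs(self.chemical_shift_ppm - expected) > 1e-9:
            raise ValueError(f"chemical shift of {self.name} is fixed at {expected} ppm")


@dataclass(frozen=True)
class AcquisitionProtocol:
    n_frames: int = 20
    temporal_resolution_s: float = 3.0
    matrix: tuple[int, int] = (32, 32)
    n_slices: int = 5
    slice_thickness_cm: float = 3.0
    channels: tuple[MetaboliteChannel, ...] = ()

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.temporal_resolution_s <= 0:
            raise ValueError("temporal resolution must be positive")
        if not self.channels:
            object.__setattr__(self, "channels", _default_channels())
        names = [c.name for c in self.channels]
        if names != list(CHANNELS):
            raise ValueError(f"channels must be {CHANNELS} in order, got {names}")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def coarse_factor(self) -> int:
        """Integer ratio of metabolite to pyruvate in-plane voxel size."""
        res = [c.in_plane_resolution_mm for c in self.channels]
        return max(1, int(round(max(res) / min(res))))

    def flip(self, name: str) -> float:
        for c in self.channels:
            if c.name == name:
                return c.nominal_flip_deg
        raise KeyError(name)

    def to_dict(self) -> dict:
        return asdict(self)


def _default_channels() -> tuple[MetaboliteChannel, ...]:
    return (
        MetaboliteChannel("pyruvate", 7.5, 20.0),
        MetaboliteChannel("glutamate", 22.5, 60.0),
        MetaboliteChannel("lactate_downfield", 22.5, 60.0),
        MetaboliteChannel("lactate_upfield", 22.5, 60.0),
    )


def default_protocol() -> AcquisitionProtocol:
    """The study's acquisition: 32x32, 5 slices, 20 frames at TR 3 s."""
    return AcquisitionProtocol()
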