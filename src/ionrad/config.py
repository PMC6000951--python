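"""Run configuration: beam, phantom, detector stack, acquisition, cuts.

The dataclasses mirror the experimental degrees of freedom of a five-layer
pixel-detector radiography bench: a pencil beam, a step phantom, five
300 um silicon layers (two front-tracker and two rear-tracker layers in
arrival-time mode, one energy-mode layer at the isocenter) and the
frame-based acquisition.  Everything is round-trippable through YAML so a
run is fully described by one file plus a seed.

Geometry convention: right-handed, beam along +z, x horizontal; all
positions in mm; pixel (col, row) are 0-based and map to physical
coordinates as (index + 0.5) * pitch - 7.04 mm on the 256 x 55 um sensor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .physics import IONS, MATERIALS, IonSpecies, Material

__all__ = [
    "BeamSpec", "PhantomSpec", "LayerSpec", "AcquisitionSpec",
    "ArtifactConfig", "CutConfig", "ImagingPlaneSpec", "RunConfig",
    "default_layers", "ConfigurationError",
    "SENSOR_SIDE_MM", "N_PIXELS", "PIXEL_PITCH_MM",
]

N_PIXELS = 256
PIXEL_PITCH_MM = 0.055
SENSOR_SIDE_MM = N_PIXELS * PIXEL_PITCH_MM  # 14.08 mm


class ConfigurationError(ValueError):
    """Invalid or inconsistent run configuration."""


def pixel_to_mm(index) -> float:
    """Center of a 0-based pixel index in mm (sensor centered on the axis)."""
    return (index + 0.5) * PIXEL_PITCH_MM - SENSOR_SIDE_MM / 2.0


def mm_to_pixel(pos_mm) -> float:
    """Fractional pixel coordinate of a position in mm."""
    return (pos_mm + SENSOR_SIDE_MM / 2.0) / PIXEL_PITCH_MM - 0.5


@dataclass
class BeamSpec:
    """Pencil beam along +z.

    Defaults are the head-phantom helium setting: 168.3 MeV/u, 10.6 mm
    FWHM, about 30 ions per 1 ms frame.  ``profile`` may be ``gaussian``
    (FWHM-parameterized) or ``uniform`` (flat over half_width_x/y), the
    latter being convenient for flat-field and dose-budget studies.
    """

    species: str = "helium"
    energy_per_nucleon: float = 168.3
    fwhm_mm: float = 10.6
    mean_ions_per_frame: float = 30.0
    profile: str = "gaussian"
    half_width_x_mm: float = 6.0
    half_width_y_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ConfigurationError("beam fwhm must be positive")
        if self.species not in IONS:
            raise ConfigurationError(f"unknown ion species {self.species!r}")
        if self.profile not in ("gaussian", "uniform"):
            raise ConfigurationError("profile must be 'gaussian' or 'uniform'")

    @property
    def ion(self) -> IonSpecies:
        return IONS[self.species]

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm / 2.3548200450309493


@dataclass
class PhantomSpec:
    """Homogeneous block with one thin transverse step inhomogeneity.

    The step is a slab of ``step_material`` (air by default) of
    ``step_thickness_mm`` along the beam, occupying the half-plane
    x > step_edge_x_mm, centered in depth at ``step_depth_center_mm``
    from the upstream face.  Default: 161 mm PMMA, 1 mm air step at
    mid-depth, edge at x = 0.
    """

    material: str = "pmma"
    length_mm: float = 161.0
    step_thickness_mm: float = 1.0
    step_material: str = "air"
    step_edge_x_mm: float = 0.0
    step_depth_center_mm: float = 80.5
    center_z_mm: float = 0.0  # mid-phantom z in lab coordinates

    def __post_init__(self) -> None:
        if not 0.0 <= self.step_depth_center_mm <= self.length_mm:
            raise ConfigurationError("step depth outside phantom")
        if self.step_thickness_mm < 0 or self.length_mm <= 0:
            raise ConfigurationError("non-positive phantom dimensions")

    @property
    def bulk(self) -> Material:
        return MATERIALS[self.material]

    @property
    def step(self) -> Material:
        return MATERIALS[self.step_material]

    @property
    def upstream_face_z(self) -> float:
        return self.center_z_mm - self.length_mm / 2.0

    @property
    def downstream_face_z(self) -> float:
        return self.center_z_mm + self.length_mm / 2.0


@dataclass
class LayerSpec:
    """One Timepix-style detector layer.

    ``readout_wet_mm`` is the water-equivalent budget of everything in the
    layer besides the sensor (thinned readout chip, bump bonds); the default
    0.45 mm makes the whole layer ~1 mm WET, the value quoted for a thinned
    assembly.  ``true_offset_um`` is the mechanical misalignment the
    simulator imprints and the alignment procedure must recover.
    """

    index: int
    z_position_mm: float
    mode: str  # "time" | "energy"
    sensor_thickness_um: float = 300.0
    pixel_pitch_um: float = 55.0
    n_pixels_per_side: int = 256
    readout_wet_mm: float = 0.45
    bias_voltage: float = 10.0
    threshold_kev: float = 4.0
    true_offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in ("time", "energy"):
            raise ConfigurationError("layer mode must be 'time' or 'energy'")
        if self.bias_voltage not in (10.0, 40.0):
            raise ConfigurationError("supported bias voltages: 10 V, 40 V")
        self.true_offset_um = tuple(self.true_offset_um)


def default_layers(bias_voltage: float = 10.0,
                   offsets_um: dict[int, tuple[float, float]] | None = None
                   ) -> list[LayerSpec]:
    """The five-layer stack: front tracker, energy layer at isocenter, rear
    tracker.  z positions are a design choice (the energy layer sits < 4 cm
    behind the phantom's downstream face at +95 mm)."""
    offsets_um = offsets_um or {}
    z = {1: -100.0, 2: -90.0, 3: 95.0, 4: 105.0, 5: 115.0}
    return [
        LayerSpec(index=i, z_position_mm=z[i],
                  mode="energy" if i == 3 else "time",
                  bias_voltage=bias_voltage,
                  true_offset_um=offsets_um.get(i, (0.0, 0.0)))
        for i in (1, 2, 3, 4, 5)
    ]


@dataclass
class AcquisitionSpec:
    """Frame-based readout timing.

    1 ms frames, 100 ns arrival-time ticks, 260 +- 40 us digitization per
    cluster and a 14-bit (11810-count) per-pixel counter.
    """

    frame_duration_ms: float = 1.0
    time_tick_ns: float = 100.0
    digitization_time_mean_us: float = 260.0
    digitization_time_sd_us: float = 40.0
    counter_max: int = 11810
    frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_duration_ms <= 0:
            raise ConfigurationError("frame duration must be positive")

    @property
    def frame_duration_us(self) -> float:
        return self.frame_duration_ms * 1e3

    def tick_of(self, t_us: float) -> int:
        """1-based arrival-time tick of a time within the frame."""
        return int(t_us * 1e3 / self.time_tick_ns) + 1


@dataclass
class ArtifactConfig:
    """Rates of the degradation mechanisms the cleaning stage removes.

    ``crop_window_us``: ions arriving within this window of either frame
    boundary have their energy-mode signal only partially digitized
    (expected cropped fraction ~ 2 * window / frame duration).  Overshoot
    (readout oscillation) affects clusters with a pixel above ~1 MeV true
    deposition.  ``overlap_rate_per_frame`` injects forced two-ion merged
    clusters on the energy layer in addition to naturally occurring pile-up.
    """

    background_rate_per_frame: float = 8.0
    overshoot_probability: float = 0.05
    overshoot_pixel_threshold_mev: float = 1.0
    crop_window_us: float = 65.0
    overlap_rate_per_frame: float = 0.3
    fragmentation_probability: float = 0.13

    @classmethod
    def disabled(cls) -> "ArtifactConfig":
        return cls(background_rate_per_frame=0.0, overshoot_probability=0.0,
                   crop_window_us=0.0, overlap_rate_per_frame=0.0,
                   fragmentation_probability=0.0)


@dataclass
class CutConfig:
    """Cleaning and matching cuts of the event builder.

    The 220 um energy-association radius is four 55 um pixel pitches, the
    distance within which an extrapolated rear track claims an energy
    cluster.  ``crop_guard_us`` must cover the true partial-digitization
    window at the frame boundaries; the default (100 us) brackets the
    ~12-13% loss of usable events that the cropping cut should produce.
    """

    max_tick_spread: int = 1
    crop_guard_us: float = 100.0
    energy_association_radius_um: float = 220.0
    time_match_window: int = 1
    background_volume_max_mev: float = 0.3
    background_size_max: int = 2
    overshoot_pixel_energy_mev: float = 1.0

    def __post_init__(self) -> None:
        if min(self.max_tick_spread, self.crop_guard_us,
               self.energy_association_radius_um, self.time_match_window,
               self.background_volume_max_mev,
               self.overshoot_pixel_energy_mev) <= 0:
            raise ConfigurationError("all cuts must be positive")


@dataclass
class ImagingPlaneSpec:
    """Mid-phantom imaging plane binned in 220 um pixels by default."""

    z_position_mm: float = 0.0
    pixel_pitch_um: float = 220.0
    extent_x_mm: float = 14.08
    extent_y_mm: float = 14.08

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ConfigurationError("imaging pitch must be positive")


@dataclass
class RunConfig:
    """Complete description of one simulated radiography run."""

    beam: BeamSpec = field(default_factory=BeamSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    layers: list[LayerSpec] = field(default_factory=default_layers)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    cuts: CutConfig = field(default_factory=CutConfig)
    plane: ImagingPlaneSpec = field(default_factory=ImagingPlaneSpec)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        zs = [l.z_position_mm for l in self.layers]
        if sorted(zs) != zs or len(set(zs)) != len(zs):
            raise ConfigurationError("layers must be strictly ordered in z")
        modes = {l.index: l.mode for l in self.layers}
        if len(self.layers) == 5 and modes != {1: "time", 2: "time",
                                               3: "energy", 4: "time", 5: "time"}:
            raise ConfigurationError(
                "expect layers 1,2,4,5 in time mode and layer 3 in energy mode")
        ph = self.phantom
        for l in self.layers:
            if ph.upstream_face_z < l.z_position_mm < ph.downstream_face_z:
                raise ConfigurationError(
                    f"layer {l.index} overlaps the phantom volume")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            beam=BeamSpec(**d.get("beam", {})),
            phantom=PhantomSpec(**d.get("phantom", {})),
            layers=[LayerSpec(**ld) for ld in d["layers"]] if "layers" in d
                   else default_layers(),
            acquisition=AcquisitionSpec(**d.get("acquisition", {})),
            artifacts=ArtifactConfig(**d.get("artifacts", {})),
            cuts=CutConfig(**d.get("cuts", {})),
            plane=ImagingPlaneSpec(**d.get("plane", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
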