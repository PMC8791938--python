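"""Ground-truthed synthetic macular OCT phantoms.

The generator emulates the image properties the segmentation pipeline is
designed to survive: ten alternating bright/dark reflectivity bands
between eleven boundaries, a foveal depression of the inner boundaries,
vessel-shadow columns, a faint posterior vitreous face (PVF) line above
the ILM, multiplicative speckle, and an optional AMD-like dome that
elevates the outer boundaries steeply enough to break 3-neighbourhood
path continuity (while 5-neighbourhood continuity still holds).

Every phantom returns the exact boundary rows it was built from, so all
downstream stages can be scored against a noise-free truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

from .core import (
    BOUNDARY_ORDER,
    DARK_TO_BRIGHT,
    BScan,
    ValidationError,
    Volume,
)


class VesselShadow(NamedTuple):
    """A retinal vessel shadow: attenuated columns below the ILM."""

    center: int
    width: int
    attenuation: float  # multiplicative factor in [0, 1]


class AmdDome(NamedTuple):
    """An AMD-like dome elevating the outer boundaries (drusen/edema)."""

    center: int
    height: float  # px of elevation at the apex
    width: float   # lateral extent; Gaussian sigma = width / 4


#: Mean reflectivity of the 12 axial compartments: the vitreous, the ten
#: bands between the eleven boundaries, and the sub-RPE background.
LAYER_NAMES: tuple[str, ...] = (
    "vitreous", "NFL", "GCL", "IPL", "INL", "OPL",
    "ONL", "IS", "IS/OS", "OS", "RPE", "sub-RPE",
)
DEFAULT_INTENSITIES: tuple[float, ...] = (
    0.05, 0.75, 0.35, 0.60, 0.30, 0.60, 0.10, 0.30, 0.95, 0.45, 0.95, 0.12,
)
#: Mean thickness (px) of the ten retinal bands, NFL first.
DEFAULT_THICKNESSES: tuple[float, ...] = (12, 14, 14, 12, 10, 28, 10, 8, 10, 12)

# Fractions of the foveal dip applied to each boundary (inner boundaries
# dip, outer boundaries stay put) and of the AMD dome elevation (outer
# boundaries carry the full dome; inner ones are partially lifted so the
# anatomy never self-intersects, as in edema).
FOVEA_WEIGHTS: tuple[float, ...] = (1.0, 0.85, 0.70, 0.50, 0.30, 0.15, 0, 0, 0, 0, 0)
DOME_WEIGHTS: tuple[float, ...] = (0.35, 0.45, 0.55, 0.60, 0.65, 0.70, 1, 1, 1, 1, 1)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and degradations of one synthetic B-scan.

    The defaults describe a 512 x 480 px healthy macula at 3.9 um/px
    axial pitch with gently undulating layers and a foveal dip; all
    degradations (shadows, PVF, speckle, dome) are off until configured.
    """

    width: int = 512
    height: int = 480
    pixel_size_axial: float = 3.9
    pixel_size_lateral: float = 6.0
    layer_intensities: tuple[float, ...] = DEFAULT_INTENSITIES
    layer_thicknesses: tuple[float, ...] = DEFAULT_THICKNESSES
    undulation_amplitude: float = 2.0  # px, low-frequency lateral waviness
    ilm_depth: float = 120.0           # px, mean row of the ILM
    fovea_depth: float = 25.0          # px dip of the ILM at the fovea
    fovea_width: float = 140.0         # lateral extent; sigma = width / 4
    fovea_center: Optional[float] = None  # defaults to the image centre
    vessel_shadows: tuple[VesselShadow, ...] = ()
    pvf_offset: Optional[float] = None  # rows above the ILM, None = no PVF
    pvf_contrast: float = 0.15          # fraction of the ILM step contrast
    speckle_level: float = 0.0          # multiplicative noise sigma (>= 0)
    amd_dome: Optional[AmdDome] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "layer_intensities", tuple(float(v) for v in self.layer_intensities)
        )
        object.__setattr__(
            self, "layer_thicknesses", tuple(float(v) for v in self.layer_thicknesses)
        )
        shadows = tuple(VesselShadow(*s) for s in self.vessel_shadows)
        object.__setattr__(self, "vessel_shadows", shadows)
        if self.amd_dome is not None:
            object.__setattr__(self, "amd_dome", AmdDome(*self.amd_dome))

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if self.width < 61:
            raise ValidationError("width: must be >= 61 columns")
        if self.height < 8:
            raise ValidationError("height: must be >= 8 rows")
        v = self.layer_intensities
        if len(v) != 12:
            raise ValidationError(
                "layer_intensities: expected 12 values "
                "(vitreous + 10 bands + sub-RPE background)"
            )
        if min(v) < 0 or max(v) > 1:
            raise ValidationError("layer_intensities: values must lie in [0, 1]")
        for i, name in enumerate(BOUNDARY_ORDER):
            above, below = v[i], v[i + 1]
            if name in DARK_TO_BRIGHT:
                if not above < below:
                    raise ValidationError(
                        f"layer_intensities: band above {name} must be darker "
                        f"than the band below (got {above} >= {below})"
                    )
            elif not above > below:
                raise ValidationError(
                    f"layer_intensities: band above {name} must be brighter "
                    f"than the band below (got {above} <= {below})"
                )
        t = self.layer_thicknesses
        if len(t) != 10:
            raise ValidationError("layer_thicknesses: expected 10 values")
        if min(t) < 1:
            raise ValidationError("layer_thicknesses: thicknesses must be >= 1 px")
        margin_bottom = 8
        if self.ilm_depth + self.fovea_depth + sum(t) + margin_bottom > self.height:
            raise ValidationError(
                "layer_thicknesses: mean thicknesses plus margins exceed height"
            )
        if self.fovea_depth < 0 or self.fovea_width <= 0:
            raise ValidationError("fovea_depth/fovea_width: must be non-negative")
        for s in self.vessel_shadows:
            if not 0 <= s.attenuation <= 1:
                raise ValidationError("vessel_shadows: attenuation must lie in [0, 1]")
            if s.width < 1:
                raise ValidationError("vessel_shadows: width must be >= 1 px")
        if self.pvf_offset is not None and self.pvf_offset >= self.ilm_depth:
            raise ValidationError("pvf_offset: PVF line would leave the image")
        if self.speckle_level < 0:
            raise ValidationError("speckle_level: must be >= 0")
        if self.amd_dome is not None and (
            self.amd_dome.height < 0 or self.amd_dome.width <= 0
        ):
            raise ValidationError("amd_dome: height must be >= 0 and width > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layer_intensities"] = list(self.layer_intensities)
        d["layer_thicknesses"] = list(self.layer_thicknesses)
        d["vessel_shadows"] = [list(s) for s in self.vessel_shadows]
        d["amd_dome"] = list(self.amd_dome) if self.amd_dome else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if d.get("vessel_shadows"):
            d["vessel_shadows"] = tuple(VesselShadow(*s) for s in d["vessel_shadows"])
        if d.get("amd_dome"):
            d["amd_dome"] = AmdDome(*d["amd_dome"])
        return cls(**d)


@dataclass(frozen=True)
class PhantomTruth:
    """Noise-free boundary rows and degradation metadata of a phantom."""

    boundaries: dict[str, np.ndarray]  # name -> row per column (float)
    config: PhantomConfig
    shadow_columns: frozenset[int] = frozenset()
    pvf_rows: Optional[np.ndarray] = None  # per-column PVF line row

    def rows_array(self) -> np.ndarray:
        """Boundary rows stacked in anatomical order, shape (11, width)."""
        return np.stack([self.boundaries[n] for n in BOUNDARY_ORDER])

    def validate(self) -> None:
        rows = self.rows_array()
        if np.any(np.diff(rows, axis=0) < 1 - 1e-9):
            raise ValidationError("truth boundaries are not strictly ordered")


# ---------------------------------------------------------------------------


def _boundary_curves(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Noise-free boundary rows, shape (11, width)."""
    c = np.arange(config.width, dtype=float)
    # Low-frequency lateral undulation shared by all boundaries; phases are
    # the only random element of the geometry.
    phases = rng.uniform(0.0, 2 * np.pi, size=2)
    und = config.undulation_amplitude * (
        0.6 * np.cos(2 * np.pi * c / 300.0 + phases[0])
        + 0.4 * np.cos(2 * np.pi * c / 170.0 + phases[1])
    )
    center = (
        config.fovea_center if config.fovea_center is not None else (config.width - 1) / 2
    )
    sigma_f = config.fovea_width / 4.0
    fovea = config.fovea_depth * np.exp(-0.5 * ((c - center) / sigma_f) ** 2)
    if config.amd_dome is not None:
        d = config.amd_dome
        dome = d.height * np.exp(-0.5 * ((c - d.center) / (d.width / 4.0)) ** 2)
    else:
        dome = np.zeros_like(c)

    rows = np.empty((11, config.width))
    depth = config.ilm_depth + und
    for k in range(11):
        if k > 0:
            depth = depth + config.layer_thicknesses[k - 1]
        rows[k] = depth + fovea * FOVEA_WEIGHTS[k] - dome * DOME_WEIGHTS[k]
    if np.any(np.diff(rows, axis=0) < 1 - 1e-9):
        raise ValidationError(
            "fovea_depth/amd_dome: boundary curves cross; reduce the deformation "
            "or thicken the layers"
        )
    return rows


def generate_bscan(config: PhantomConfig) -> tuple[BScan, PhantomTruth]:
    """Render one synthetic B-scan and its exact boundary truth.

    The clean image is piecewise constant along each A-scan: the band of
    pixel ``(i, j)`` is the number of boundaries whose truth row is
    ``<= i``, so a boundary at integer row ``r`` produces a step between
    rows ``r - 1`` and ``r`` (the same convention the axial gradient
    anchor uses to report its peak at ``r``). Degradations are applied
    in order: PVF line, vessel shadows, multiplicative speckle.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    rows = _boundary_curves(config, rng)
    h, w = config.height, config.width

    band = np.zeros((h, w), dtype=np.intp)
    rowgrid = np.arange(h)[:, None]
    for k in range(11):
        band += rowgrid >= rows[k][None, :]
    img = np.asarray(config.layer_intensities)[band]

    pvf_rows = None
    if config.pvf_offset is not None:
        pvf_rows = np.rint(rows[0] - config.pvf_offset).astype(int)
        if pvf_rows.min() < 0:
            raise ValidationError("pvf_offset: PVF line would leave the image")
        v = config.layer_intensities
        pvf_val = v[0] + config.pvf_contrast * (v[1] - v[0])
        img[pvf_rows, np.arange(w)] = pvf_val

    shadow_cols: set[int] = set()
    for s in config.vessel_shadows:
        half = s.width // 2
        cols = range(max(0, s.center - half), min(w, s.center + half + 1))
        for j in cols:
            start = int(np.ceil(rows[0, j]))
            img[start:, j] *= s.attenuation
            shadow_cols.add(j)

    if config.speckle_level > 0:
        shape = 1.0 / config.speckle_level**2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    truth = PhantomTruth(
        boundaries={n: rows[k] for k, n in enumerate(BOUNDARY_ORDER)},
        config=config,
        shadow_columns=frozenset(shadow_cols),
        pvf_rows=pvf_rows,
    )
    truth.validate()
    bscan = BScan(img, config.pixel_size_axial, config.pixel_size_lateral)
    return bscan, truth


def generate_volume(
    config: PhantomConfig, n_bscans: int, drift: float = 0.0
) -> tuple[Volume, list[PhantomTruth]]:
    """A stack of B-scans whose geometry varies smoothly across slices.

    The foveal dip is modulated by a Gaussian across slices (maximal at
    the central slice) and ``drift`` laterally shifts the foveal centre
    sinusoidally through the stack. A single-slice volume is identical
    to :func:`generate_bscan` for the same config.
    """
    if n_bscans < 1:
        raise ValidationError("n_bscans: must be >= 1")
    mid = (n_bscans - 1) / 2.0
    s_sigma = max(n_bscans, 2) / 4.0
    base_center = (
        config.fovea_center if config.fovea_center is not None else (config.width - 1) / 2
    )
    slices, truths = [], []
    for i in range(n_bscans):
        factor = float(np.exp(-0.5 * ((i - mid) / s_sigma) ** 2))
        shift = drift * float(np.sin(2 * np.pi * i / max(n_bscans - 1, 1)))
        cfg_i = replace(
            config,
            fovea_depth=config.fovea_depth * factor,
            fovea_center=base_center + shift,
        )
        b, t = generate_bscan(cfg_i)
        slices.append(b.pixels)
        truths.append(t)
    vol = Volume(np.stack(slices), config.pixel_size_axial, config.pixel_size_lateral)
    return vol, truths


# -- presets ----------------------------------------------------------------


def healthy_config(**overrides) -> PhantomConfig:
    """A healthy-macula phantom: undulating layers with a foveal dip."""
    return PhantomConfig(**overrides)


def amd_config(**overrides) -> PhantomConfig:
    """An AMD phantom: healthy geometry plus a steep outer-retina dome.

    The default dome (45 px tall, sigma 15 px) has a maximum boundary
    slope of ~1.8 px/column: too steep for 3-neighbourhood path
    continuity, within reach of the 5-neighbourhood search.
    """
    overrides.setdefault("amd_dome", AmdDome(256, 45.0, 60.0))
    return PhantomConfig(**overrides)
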