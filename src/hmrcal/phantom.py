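"""Digital three-layer chest calibration phantom for planar MIBG imaging.

The physical reference object is a flat PMMA slab (380 x 380 x 50 mm)
holding activity compartments that mimic the :sup:`123`I-MIBG uptake
pattern of the chest: heart, mediastinum, lungs, liver and thyroid over a
uniform background.  Its digital counterpart here is a stack of three
activity layers on a 256 x 256 grid (2.21 mm pixels, the acquisition
matrix): a basal layer carrying the background and two deeper layers
(1 and 2) carrying the organ compartments.

The phantom is *calibrated* rather than copied from drawings: the two
heart-layer activities are solved so that an ideal, degradation-free
projection reproduces the designated heart-to-mediastinum ratios of
2.6 (anterior) and 3.5 (posterior).  Because those two HMRs differ, the
heart activity must sit asymmetrically in depth; the layer stack is
oriented with the basal layer toward the anterior camera.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger("hmrcal")

__all__ = [
    "InvalidGeometryError",
    "CalibrationInfeasibleError",
    "DesignatedHMR",
    "PhantomConfig",
    "DigitalPhantom",
    "build_phantom",
    "calibrate_activities",
    "save_phantom",
    "load_phantom",
]

COMPARTMENTS = ("heart", "mediastinum", "liver", "lung_left", "lung_right", "thyroid", "background")

PMMA_DENSITY = 1.19  # g/cm^3


class InvalidGeometryError(ValueError):
    """Compartment geometry overlaps or leaves the phantom footprint."""


class CalibrationInfeasibleError(RuntimeError):
    """No nonnegative heart activity split reaches the designated HMRs."""


@dataclass(frozen=True)
class DesignatedHMR:
    """Nominal anterior/posterior HMRs fixed by the phantom's construction."""

    anterior: float = 2.6
    posterior: float = 3.5

    def __post_init__(self) -> None:
        if not (self.anterior > 1 and self.posterior > 1):
            raise ValueError("designated HMRs must exceed 1")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and activity-ratio parameters of the digital phantom.

    Lengths in mm; positions are (x, y) offsets from the footprint centre
    with y increasing downward in the anterior view.  Activity ratios are
    concentrations relative to the heart concentration; the background
    basal-layer concentration is the overall scale (1.0 by default).
    Layer thicknesses are ordered (basal, layer1, layer2) from the
    anterior-facing surface.
    """

    grid_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 2.21
    footprint: float = 380.0
    layer_thicknesses: tuple[float, float, float] = (10.0, 10.0, 30.0)

    heart_center: tuple[float, float] = (0.0, 35.0)
    heart_radius: float = 28.0
    mediastinum_center: tuple[float, float] = (0.0, -55.0)
    mediastinum_size: tuple[float, float] = (50.0, 90.0)  # width, height
    lung_center_offset: tuple[float, float] = (75.0, -30.0)
    lung_size: tuple[float, float] = (90.0, 140.0)
    liver_center: tuple[float, float] = (55.0, 107.5)
    liver_size: tuple[float, float] = (150.0, 65.0)
    thyroid_center: tuple[float, float] = (0.0, -140.0)
    thyroid_radius: float = 12.0

    background_concentration: float = 1.0  # activity per mm depth, arbitrary units
    heart_concentration: float = 2.0  # pre-calibration starting value
    liver_ratio: float = 0.9
    lung_ratio: float = 0.3
    thyroid_ratio: float = 0.5

    def __post_init__(self) -> None:
        if min(self.grid_shape) <= 0 or self.pixel_size <= 0:
            raise InvalidGeometryError("grid shape and pixel size must be positive")
        if any(t <= 0 for t in self.layer_thicknesses):
            raise InvalidGeometryError("layer thicknesses must be positive")


@dataclass
class DigitalPhantom:
    """Layered 2-D activity maps plus a density map on a physical grid.

    ``activity_layers`` is a (3, rows, cols) array of *areal* activity
    (concentration integrated over the layer thickness), ordered
    (basal, layer1, layer2) from the anterior-facing surface.  The basal
    layer holds background only; organ compartments live in layers 1-2.
    """

    grid_shape: tuple[int, int]
    pixel_size: float
    layer_thicknesses: tuple[float, float, float]
    activity_layers: np.ndarray
    density_map: np.ndarray
    compartment_masks: dict[str, np.ndarray]
    config: PhantomConfig = field(default_factory=PhantomConfig)

    def validate(self) -> None:
        if self.activity_layers.shape != (3, *self.grid_shape):
            raise InvalidGeometryError("activity_layers must be (3, rows, cols)")
        if np.any(self.activity_layers < 0):
            raise InvalidGeometryError("activity values must be nonnegative")
        organ = [m for name, m in self.compartment_masks.items() if name != "background"]
        for i, a in enumerate(organ):
            for b in organ[i + 1 :]:
                if np.any(a & b):
                    raise InvalidGeometryError("organ compartment masks overlap")

    @property
    def depth(self) -> float:
        return float(sum(self.layer_thicknesses))

    def layer_centers(self) -> np.ndarray:
        """Depth of each layer centre from the anterior-facing surface (mm)."""
        t = np.asarray(self.layer_thicknesses, dtype=float)
        return np.cumsum(t) - t / 2.0

    def scaled(self, factor: float) -> "DigitalPhantom":
        """Phantom with all activity multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, activity_layers=self.activity_layers * factor)


def _disc_mask(shape, pixel_size, footprint_center, center_mm, radius_mm):
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cx = footprint_center[1] + center_mm[0] / pixel_size
    cy = footprint_center[0] + center_mm[1] / pixel_size
    return ((xx - cx) ** 2 + (yy - cy) ** 2) <= (radius_mm / pixel_size) ** 2


def _rect_mask(shape, pixel_size, footprint_center, center_mm, size_mm):
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cx = footprint_center[1] + center_mm[0] / pixel_size
    cy = footprint_center[0] + center_mm[1] / pixel_size
    hw = size_mm[0] / (2 * pixel_size)
    hh = size_mm[1] / (2 * pixel_size)
    return (np.abs(xx - cx) <= hw) & (np.abs(yy - cy) <= hh)


def build_phantom(config: PhantomConfig | None = None) -> DigitalPhantom:
    """Construct the digital phantom from parameterized 2-D primitives.

    Raises :class:`InvalidGeometryError` if organ compartments overlap each
    other or leave the phantom footprint.
    """
    cfg = config or PhantomConfig()
    rows, cols = cfg.grid_shape
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)

    half = cfg.footprint / (2 * cfg.pixel_size)
    yy, xx = np.mgrid[0:rows, 0:cols]
    footprint = (np.abs(xx - center[1]) <= half) & (np.abs(yy - center[0]) <= half)

    masks = {
        "heart": _disc_mask(cfg.grid_shape, cfg.pixel_size, center, cfg.heart_center, cfg.heart_radius),
        "mediastinum": _rect_mask(cfg.grid_shape, cfg.pixel_size, center, cfg.mediastinum_center, cfg.mediastinum_size),
        "lung_right": _rect_mask(
            cfg.grid_shape, cfg.pixel_size, center,
            (-cfg.lung_center_offset[0], cfg.lung_center_offset[1]), cfg.lung_size,
        ),
        "lung_left": _rect_mask(
            cfg.grid_shape, cfg.pixel_size, center, cfg.lung_center_offset, cfg.lung_size,
        ),
        "liver": _rect_mask(cfg.grid_shape, cfg.pixel_size, center, cfg.liver_center, cfg.liver_size),
        "thyroid": _disc_mask(cfg.grid_shape, cfg.pixel_size, center, cfg.thyroid_center, cfg.thyroid_radius),
    }
    for name, m in masks.items():
        if not m.any():
            raise InvalidGeometryError(f"compartment {name!r} has empty mask")
        if np.any(m & ~footprint):
            raise InvalidGeometryError(f"compartment {name!r} extends outside the footprint")
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise InvalidGeometryError(f"compartments {a!r} and {b!r} overlap")
    masks["background"] = footprint

    t_b, t_1, t_2 = cfg.layer_thicknesses
    basal = np.where(footprint, cfg.background_concentration * t_b, 0.0)

    heart_conc = cfg.heart_concentration
    organ_conc = {
        "heart": heart_conc,
        "liver": cfg.liver_ratio * heart_conc,
        "lung_left": cfg.lung_ratio * heart_conc,
        "lung_right": cfg.lung_ratio * heart_conc,
        "thyroid": cfg.thyroid_ratio * heart_conc,
    }
    organ_image = np.zeros(cfg.grid_shape)
    for name, conc in organ_conc.items():
        organ_image[masks[name]] = conc
    layers = np.stack([basal, organ_image * t_1, organ_image * t_2])

    density = np.where(footprint, PMMA_DENSITY, 0.0)

    ph = DigitalPhantom(
        grid_shape=cfg.grid_shape,
        pixel_size=cfg.pixel_size,
        layer_thicknesses=cfg.layer_thicknesses,
        activity_layers=layers,
        density_map=density,
        compartment_masks=masks,
        config=cfg,
    )
    ph.validate()
    return ph


def _ideal_roi_response(ph: DigitalPhantom, ideal_projector, rois):
    """Heart/mediastinum ROI means of the ideal projection for both views."""
    from .analysis import roi_means  # local import to avoid a module cycle

    out = {}
    for view in ("anterior", "posterior"):
        img = ideal_projector(ph, view)
        r = rois if view == "anterior" else rois.mirrored(ph.grid_shape[1])
        out[view] = roi_means(img, r)
    return out


def calibrate_activities(
    ph: DigitalPhantom,
    target: DesignatedHMR | None = None,
    ideal_projector=None,
) -> DigitalPhantom:
    """Solve the heart activity split so ideal-view HMRs hit the targets.

    The ideal projector (attenuation only: no collimator blur, no septal
    penetration, no noise) makes the heart and mediastinum ROI means
    linear in the two heart-layer activities, so the designated
    (anterior, posterior) HMR pair reduces to a 2 x 2 linear system.  The
    other organ compartments keep their configured concentration ratios
    relative to the recalibrated heart.

    Raises :class:`CalibrationInfeasibleError`, reporting the attainable
    posterior-vs-anterior contrast ratio range, when the solution would
    need a negative activity.
    """
    from .analysis import place_rois
    from .projector import ideal_projection

    target = target or DesignatedHMR()
    projector = ideal_projector or ideal_projection
    if not ph.compartment_masks["heart"].any() or not ph.compartment_masks["background"].any():
        raise CalibrationInfeasibleError("phantom needs nonzero heart and background regions")

    rois = place_rois(ph)
    heart = ph.compartment_masks["heart"]

    # Basis phantoms: background-plus-organs with heart zeroed, and a unit
    # areal heart activity in layer 1 / layer 2 alone.
    base_layers = ph.activity_layers.copy()
    base_layers[1][heart] = 0.0
    base_layers[2][heart] = 0.0
    base = replace(ph, activity_layers=base_layers)

    def unit_heart(layer_index):
        layers = np.zeros_like(ph.activity_layers)
        layers[layer_index][heart] = 1.0
        return replace(ph, activity_layers=layers)

    resp_base = _ideal_roi_response(base, projector, rois)
    resp_h1 = _ideal_roi_response(unit_heart(1), projector, rois)
    resp_h2 = _ideal_roi_response(unit_heart(2), projector, rois)

    targets = {"anterior": target.anterior, "posterior": target.posterior}
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for i, view in enumerate(("anterior", "posterior")):
        h_base, m_base = resp_base[view]
        A[i, 0] = resp_h1[view][0]
        A[i, 1] = resp_h2[view][0]
        b[i] = targets[view] * m_base - h_base

    x = np.linalg.solve(A, b)
    if np.any(x < 0):
        ratios = []
        for j in range(2):
            c_ant = A[0, j] / resp_base["anterior"][1]
            c_post = A[1, j] / resp_base["posterior"][1]
            ratios.append(c_post / c_ant)
        required = (target.posterior - 1.0) / (target.anterior - 1.0)
        raise CalibrationInfeasibleError(
            "no nonnegative heart split reaches the designated HMRs: required "
            f"posterior/anterior contrast ratio {required:.3f}, attainable range "
            f"[{min(ratios):.3f}, {max(ratios):.3f}]; adjust layer thicknesses"
        )

    new_layers = ph.activity_layers.copy()
    new_layers[1][heart] = x[0]
    new_layers[2][heart] = x[1]

    # Re-anchor the other organs to the calibrated heart: each organ keeps
    # its configured concentration ratio and the heart's depth profile.
    cfg = ph.config
    ratios = {
        "liver": cfg.liver_ratio,
        "lung_left": cfg.lung_ratio,
        "lung_right": cfg.lung_ratio,
        "thyroid": cfg.thyroid_ratio,
    }
    for name, ratio in ratios.items():
        m = ph.compartment_masks[name]
        new_layers[1][m] = ratio * x[0]
        new_layers[2][m] = ratio * x[1]

    calibrated = replace(ph, activity_layers=new_layers)
    calibrated.validate()
    logger.info(
        "calibrated heart areal activities: layer1=%.4f, layer2=%.4f", x[0], x[1]
    )
    return calibrated


def save_phantom(ph: DigitalPhantom, directory: str | Path) -> None:
    """Write per-layer activity CSV matrices plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(("basal", "layer1", "layer2")):
        np.savetxt(directory / f"activity_{name}.csv", ph.activity_layers[i], delimiter=",")
    np.savetxt(directory / "density.csv", ph.density_map, delimiter=",")
    labels = np.zeros(ph.grid_shape, dtype=int)
    order = [n for n in COMPARTMENTS if n != "background"]
    for code, name in enumerate(order, start=1):
        labels[ph.compartment_masks[name]] = code
    np.savetxt(directory / "compartments.csv", labels, fmt="%d", delimiter=",")
    meta = {
        "grid_shape": list(ph.grid_shape),
        "pixel_size_mm": ph.pixel_size,
        "layer_thicknesses_mm": list(ph.layer_thicknesses),
        "compartment_codes": {name: i for i, name in enumerate(order, start=1)},
    }
    (directory / "phantom.json").write_text(json.dumps(meta, indent=2))


def load_phantom(directory: str | Path) -> DigitalPhantom:
    """Inverse of :func:`save_phantom`."""
    directory = Path(directory)
    meta = json.loads((directory / "phantom.json").read_text())
    layers = np.stack(
        [
            np.loadtxt(directory / f"activity_{name}.csv", delimiter=",")
            for name in ("basal", "layer1", "layer2")
        ]
    )
    density = np.loadtxt(directory / "density.csv", delimiter=",")
    labels = np.loadtxt(directory / "compartments.csv", dtype=int, delimiter=",")
    masks = {
        name: labels == code for name, code in meta["compartment_codes"].items()
    }
    masks["background"] = density > 0
    return DigitalPhantom(
        grid_shape=tuple(meta["grid_shape"]),
        pixel_size=float(meta["pixel_size_mm"]),
        layer_thicknesses=tuple(meta["layer_thicknesses_mm"]),
        activity_layers=layers,
        density_map=density,
        compartment_masks=masks,
    )
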