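"""ROI placement, HMR computation, conversion coefficients and filtering.

The heart-to-mediastinum ratio (HMR) is the mean count in a circular
cardiac ROI divided by the mean count in a rectangular mediastinal ROI.
A camera/collimator system is mapped onto the standard HMR scale through
the conversion coefficient

    CC = ((HMR_ant + HMR_post)/2 - 1) / ((2.6 + 3.5)/2 - 1)

where 2.6 and 3.5 are the phantom's designated anterior and posterior
HMRs: an ideal system scores 1, a contrast-free system 0.  Simulated
coefficients are mapped onto the experimental scale with the published
compensation line Y = 1.27 X - 0.15, and designs whose 159 keV septal
penetration exceeds 1.0% are excluded from regression datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .collimator import CollimatorSpec, penetration_fraction
from .phantom import DesignatedHMR, DigitalPhantom
from .projector import (
    AcquisitionSpec,
    DetectorSpec,
    ModelConstants,
    DEFAULT_CONSTANTS,
    PlanarImage,
    ProjectionCache,
    simulate_planar,
)

logger = logging.getLogger("hmrcal")

__all__ = [
    "ROIPlacementError",
    "ROISet",
    "HMRPair",
    "CompensationLine",
    "PUBLISHED_COMPENSATION",
    "ConversionRecord",
    "place_rois",
    "roi_means",
    "compute_hmr",
    "conversion_coefficient",
    "compensate",
    "fit_compensation",
    "penetration_filter",
    "simulate_record",
    "records_to_frame",
]

MIN_HEART_ROI_RADIUS_PX = 3.0
MEDIASTINUM_ROI_SIZE_PX = (10, 30)  # width, height


class ROIPlacementError(ValueError):
    """An ROI would leave its compartment mask."""


@dataclass(frozen=True)
class ROISet:
    """Heart circle plus mediastinum rectangle, in pixel coordinates.

    ``heart_center`` is (row, col); the mediastinum rectangle is given by
    its top-left (row, col) corner, width (cols) and height (rows).
    """

    heart_center: tuple[float, float]
    heart_radius: float
    med_topleft: tuple[int, int]
    med_width: int
    med_height: int

    def heart_mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        r, c = self.heart_center
        return ((yy - r) ** 2 + (xx - c) ** 2) <= self.heart_radius**2

    def med_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        r0, c0 = self.med_topleft
        m[r0 : r0 + self.med_height, c0 : c0 + self.med_width] = True
        return m

    def mirrored(self, ncols: int) -> "ROISet":
        """ROI set for the left-right mirrored (posterior) image."""
        r, c = self.heart_center
        r0, c0 = self.med_topleft
        return ROISet(
            heart_center=(r, (ncols - 1) - c),
            heart_radius=self.heart_radius,
            med_topleft=(r0, ncols - c0 - self.med_width),
            med_width=self.med_width,
            med_height=self.med_height,
        )


@dataclass(frozen=True)
class HMRPair:
    """Anterior and posterior heart-to-mediastinum ratios."""

    hmr_ant: float
    hmr_post: float

    def __post_init__(self) -> None:
        if not (self.hmr_ant > 0 and self.hmr_post > 0):
            raise ValueError("HMRs must be positive")


@dataclass(frozen=True)
class CompensationLine:
    """Linear map from simulated onto experimental conversion coefficients."""

    slope: float = 1.27
    intercept: float = -0.15
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("compensation slope must be positive")


#: Published line regressing experimental on simulated coefficients.
PUBLISHED_COMPENSATION = CompensationLine(slope=1.27, intercept=-0.15, r_squared=0.96)


@dataclass
class ConversionRecord:
    """One collimator's coefficients, penetration and replicate statistics."""

    collimator: CollimatorSpec
    raw_coefficient: float
    compensated_coefficient: float
    penetration_159: float
    hmr_ant: float
    hmr_post: float
    n_replicates: int
    raw_sd: float = 0.0
    compensated_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.raw_coefficient, self.compensated_coefficient]).all():
            raise ValueError("coefficients must be finite")
        if not (0.0 < self.penetration_159 <= 1.0):
            raise ValueError("penetration fraction must be in (0, 1]")


def place_rois(ph: DigitalPhantom, acq: AcquisitionSpec | None = None) -> ROISet:
    """Standardized ROIs anchored to the phantom compartment centroids.

    Heart: circle at the heart-mask centroid with radius 0.8 x the
    inscribed radius there.  Mediastinum: 10 x 30 pixel rectangle centred
    on the mediastinum-mask centroid.  Raises if either ROI would leave
    its compartment.
    """
    heart = ph.compartment_masks["heart"]
    med = ph.compartment_masks["mediastinum"]
    if not heart.any() or not med.any():
        raise ROIPlacementError("phantom lacks heart or mediastinum masks")

    hr, hc = ndimage.center_of_mass(heart)
    inscribed = ndimage.distance_transform_edt(heart)[int(round(hr)), int(round(hc))]
    radius = 0.8 * inscribed
    if radius < MIN_HEART_ROI_RADIUS_PX:
        raise ROIPlacementError(
            f"heart compartment too small: ROI radius {radius:.2f} px "
            f"< {MIN_HEART_ROI_RADIUS_PX} px"
        )

    mr, mc = ndimage.center_of_mass(med)
    width, height = MEDIASTINUM_ROI_SIZE_PX
    r0 = int(round(mr - height / 2))
    c0 = int(round(mc - width / 2))
    rois = ROISet((hr, hc), radius, (r0, c0), width, height)

    if np.any(rois.heart_mask(ph.grid_shape) & ~heart):
        raise ROIPlacementError("heart ROI exits the heart compartment")
    if np.any(rois.med_mask(ph.grid_shape) & ~med):
        raise ROIPlacementError("mediastinum ROI exits the mediastinum compartment")
    return rois


def roi_means(image: np.ndarray | PlanarImage, rois: ROISet) -> tuple[float, float]:
    """(heart mean, mediastinum mean) counts."""
    arr = image.counts if isinstance(image, PlanarImage) else image
    return (
        float(arr[rois.heart_mask(arr.shape)].mean()),
        float(arr[rois.med_mask(arr.shape)].mean()),
    )


def compute_hmr(img: PlanarImage | np.ndarray, rois: ROISet) -> float:
    """Mean heart-ROI counts over mean mediastinum-ROI counts."""
    heart, med = roi_means(img, rois)
    if med <= 0:
        raise ZeroDivisionError(
            f"mediastinal ROI mean is {med}; image too sparse for an HMR "
            "(raise the photon budget)"
        )
    return heart / med


def conversion_coefficient(
    pair: HMRPair, designated: DesignatedHMR | None = None
) -> float:
    """((HMR_ant + HMR_post)/2 - 1) / ((2.6 + 3.5)/2 - 1)."""
    designated = designated or DesignatedHMR()
    denom = (designated.anterior + designated.posterior) / 2.0 - 1.0
    return ((pair.hmr_ant + pair.hmr_post) / 2.0 - 1.0) / denom


def compensate(raw: float, line: CompensationLine = PUBLISHED_COMPENSATION) -> float:
    """Map a simulated coefficient onto the experimental scale."""
    return line.slope * raw + line.intercept


def fit_compensation(
    pairs: list[tuple[float, float]] | np.ndarray
) -> CompensationLine:
    """OLS of experimental on simulated coefficients over (sim, exp) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (simulated, experimental) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: simulated coefficients have no variance")
    res = stats.linregress(x, y)
    return CompensationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def penetration_filter(
    records: list[ConversionRecord], threshold: float = 0.01
) -> list[ConversionRecord]:
    """Retain records whose 159 keV penetration is <= threshold (strict >)."""
    return [r for r in records if not (r.penetration_159 > threshold)]


def simulate_record(
    ph: DigitalPhantom,
    c: CollimatorSpec,
    det: DetectorSpec,
    acq: AcquisitionSpec,
    n_replicates: int = 3,
    seed: int | None = None,
    line: CompensationLine = PUBLISHED_COMPENSATION,
    noise: bool = True,
    consts: ModelConstants = DEFAULT_CONSTANTS,
    cache: ProjectionCache | None = None,
) -> ConversionRecord:
    """Simulate both views ``n_replicates`` times and summarize.

    Replicate seeds are spawned deterministically from ``seed`` (falling
    back to ``acq.seed``), so a fixed seed reproduces the record exactly.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base_seed = acq.seed if seed is None else seed
    rois_ant = place_rois(ph, acq)
    rois_post = rois_ant.mirrored(ph.grid_shape[1])
    if cache is None:
        cache = ProjectionCache(ph)

    raws, ants, posts = [], [], []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((base_seed, rep)))
        hmrs = {}
        for view, rois in (("anterior", rois_ant), ("posterior", rois_post)):
            img = simulate_planar(
                ph, c, det, acq, view, noise=noise, rng=rng, consts=consts, cache=cache
            )
            hmrs[view] = compute_hmr(img, rois)
        pair = HMRPair(hmrs["anterior"], hmrs["posterior"])
        raws.append(conversion_coefficient(pair))
        ants.append(pair.hmr_ant)
        posts.append(pair.hmr_post)
        if not noise:
            # expectation images are deterministic; replicates are identical
            raws = raws * n_replicates
            ants = ants * n_replicates
            posts = posts * n_replicates
            break

    raws = np.asarray(raws)
    comp = line.slope * raws + line.intercept
    return ConversionRecord(
        collimator=c,
        raw_coefficient=float(raws.mean()),
        compensated_coefficient=float(comp.mean()),
        penetration_159=penetration_fraction(c, 159.0),
        hmr_ant=float(np.mean(ants)),
        hmr_post=float(np.mean(posts)),
        n_replicates=n_replicates,
        raw_sd=float(raws.std(ddof=1)) if n_replicates > 1 else 0.0,
        compensated_sd=float(comp.std(ddof=1)) if n_replicates > 1 else 0.0,
    )


def records_to_frame(records: list[ConversionRecord]) -> pd.DataFrame:
    """Tabulate records with the documented CSV columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "label": r.collimator.label,
                "d_mm": r.collimator.hole_diameter,
                "t_mm": r.collimator.septal_thickness,
                "L_mm": r.collimator.length,
                "hmr_ant": r.hmr_ant,
                "hmr_post": r.hmr_post,
                "raw_cc": r.raw_coefficient,
                "compensated_cc": r.compensated_coefficient,
                "penetration_159": r.penetration_159,
                "n_replicates": r.n_replicates,
                "cc_sd": r.compensated_sd,
            }
        )
    return pd.DataFrame(rows)
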