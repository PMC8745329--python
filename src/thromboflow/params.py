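"""Extraction of the seven thrombus parameters P1-P7 from channel masks.

Coverage parameters are surface-area coverages of the binary masks:
P1 platelet adhesion (DiOC6), P2 thrombus coverage (brightfield),
P6 phosphatidylserine exposure (AF568-annexin A5), P7 fibrin deposition
(thresholded AF647).  P3-P5 are ordinal scores that a human assigns
visually in the assay; here they are automated proxies computed from the
masks and intensity images:

* P3 thrombus morphology (0-5): connected-component area classes — single
  platelets, small, medium and big aggregates — with the 0/1/2 range of the
  scale (none / multiple singles / widespread singles) decided by total
  coverage;
* P4 thrombus contraction (0-3): mean component solidity combined with the
  dark-core fraction of the brightfield image (contracted thrombi are
  compact and dense);
* P5 thrombus multilayering (0-3): fraction of thrombus pixels whose DiOC6
  intensity exceeds a high level (stacked platelets image brighter).

Area cut points are defined at the native 0.108 µm/px raster and rescaled
by pixel area for down-sampled renders.  The proxies are explicit,
reproducible rules — not replicas of human judgement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .render import FULL_PIXEL_UM

PARAM_NAMES = ("P1", "P2", "P3", "P4", "P5", "P6", "P7")

# component-area classes at the native raster (px^2 at 0.108 µm/px)
AREA_SINGLE = 200.0     # below: a single platelet
AREA_MEDIUM = 2000.0    # below: a small aggregate
AREA_BIG = 10000.0      # at or above: a big aggregate / thrombus

# SAC cut points for the 0/1/2 range of the morphology scale (percent)
SAC_WIDESPREAD = 5.0
SAC_SPARSE = 0.2

# contraction proxy bins: (solidity, dark-core fraction) descending; the
# dark-core cuts sit at the midpoints of the renderer's ~0.25/level mapping
CONTRACTION_BINS = ((0.85, 0.44), (0.75, 0.25), (0.65, 0.08))
DARK_LEVEL = 70.0       # brightfield intensity below which a pixel is "dense"
CONTRACTION_SAC_FLOOR = 8.0

# multilayer proxy bins: bright fraction of thrombus pixels, descending
MULTILAYER_BINS = (0.50, 0.25, 0.08)
BRIGHT_LEVEL = 200.0    # DiOC6 intensity above which platelets are stacked


class IncompleteImageSetError(KeyError):
    """A required channel is missing from an image/mask set."""

    def __init__(self, channel: str):
        super().__init__(channel)
        self.channel = channel

    def __str__(self) -> str:
        return f"missing channel {self.channel!r} in image/mask set"


@dataclass(frozen=True)
class ParameterRecord:
    """The seven parameters for one microspot, time point and run."""

    donor: str
    replicate: str
    surface: str
    preset: str
    switch_time: str        # "0", "2" or "none"
    timepoint: float
    p1_platelet_sac: float
    p2_thrombus_sac: float
    p3_morphology: int
    p4_contraction: int
    p5_multilayer: int
    p6_ps_sac: float
    p7_fibrin_sac: float

    def __post_init__(self) -> None:
        for attr in ("p1_platelet_sac", "p2_thrombus_sac", "p6_ps_sac",
                     "p7_fibrin_sac"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{attr}={v} outside [0, 100]")
        if self.p3_morphology not in range(6):
            raise ValueError("P3 must be an integer in 0..5")
        if self.p4_contraction not in range(4) or self.p5_multilayer not in range(4):
            raise ValueError("P4 and P5 must be integers in 0..3")

    def values(self) -> tuple:
        return (self.p1_platelet_sac, self.p2_thrombus_sac,
                float(self.p3_morphology), float(self.p4_contraction),
                float(self.p5_multilayer), self.p6_ps_sac, self.p7_fibrin_sac)


def _area_scale(pixel_size_um: float) -> float:
    return (FULL_PIXEL_UM / pixel_size_um) ** 2


def _sac(mask: np.ndarray) -> float:
    return 100.0 * np.count_nonzero(mask) / mask.size


def score_morphology(mask: np.ndarray,
                     pixel_size_um: float = FULL_PIXEL_UM) -> int:
    """Thrombus morphology score 0-5 from the brightfield mask.

    The largest connected component (8-connectivity) sets the score once
    aggregates exist: small (3), medium (4) or big (5) by area class.  With
    only single-platelet-sized components the score is 0 (bare or nearly
    bare field), 1 (multiple attached single platelets) or 2 (widespread
    coverage of single platelets) by total coverage.  Using coverage rather
    than a component count for the 0/1/2 range keeps the score monotone
    under dilation (components may merge, coverage can only grow).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return 0
    scale = _area_scale(pixel_size_um)
    labels = label(m, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]
    largest = float(areas.max())
    if largest >= AREA_BIG * scale:
        return 5
    if largest >= AREA_MEDIUM * scale:
        return 4
    if largest >= AREA_SINGLE * scale:
        return 3
    sac = _sac(m)
    if sac >= SAC_WIDESPREAD:
        return 2
    if sac >= SAC_SPARSE:
        return 1
    return 0


def score_contraction(bf_image: np.ndarray, thrombus_mask: np.ndarray,
                      pixel_size_um: float = FULL_PIXEL_UM) -> int:
    """Thrombus contraction score 0-3 from compactness and density.

    Mean solidity (area / convex area) of the aggregate components is
    combined with the fraction of thrombus pixels darker than
    ``DARK_LEVEL`` in brightfield; both rise as thrombi contract.
    """
    m = np.asarray(thrombus_mask).astype(bool)
    img = np.asarray(bf_image, dtype=float)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        return 0
    scale = _area_scale(pixel_size_um)
    labels = label(m, connectivity=2)
    min_area = AREA_SINGLE * scale  # solidity of specks is meaningless
    sols = [p.solidity for p in regionprops(labels) if p.area >= min_area]
    solidity = float(np.mean(sols)) if sols else 0.0
    dark_frac = float(np.count_nonzero(img[m] < DARK_LEVEL)) / np.count_nonzero(m)
    for score, (sol_cut, dark_cut) in zip((3, 2, 1), CONTRACTION_BINS):
        if solidity >= sol_cut and dark_frac >= dark_cut:
            return score
    return 1 if _sac(m) >= CONTRACTION_SAC_FLOOR else 0


def score_multilayering(dioc6_image: np.ndarray, thrombus_mask: np.ndarray,
                        pixel_size_um: float = FULL_PIXEL_UM) -> int:
    """Thrombus multilayering score 0-3: bright-core fraction of the mask."""
    m = np.asarray(thrombus_mask).astype(bool)
    img = np.asarray(dioc6_image, dtype=float)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        return 0
    bright_frac = float(np.count_nonzero(img[m] > BRIGHT_LEVEL)) \
        / np.count_nonzero(m)
    for score, cut in zip((3, 2, 1), MULTILAYER_BINS):
        if bright_frac >= cut:
            return score
    return 0


def extract_parameters(masks: dict, images: dict, *,
                       donor: str = "D01", replicate: str = "r1",
                       surface: str = "collagen_TF", preset: str = "vehicle",
                       switch_time: str = "none", timepoint: float = 0.0,
                       pixel_size_um: float = FULL_PIXEL_UM) -> ParameterRecord:
    """Compute P1-P7 for one microspot/time point.

    ``masks`` and ``images`` map channel names (bf, dioc6, af568, af647) to
    binary masks and 8-bit intensity images.  Raises
    :class:`IncompleteImageSetError` naming the first missing channel.
    """
    for ch in ("bf", "dioc6", "af568", "af647"):
        if ch not in masks:
            raise IncompleteImageSetError(ch)
    for ch in ("bf", "dioc6"):
        if ch not in images:
            raise IncompleteImageSetError(ch)

    def raster(m):
        return m.raster if hasattr(m, "raster") else np.asarray(m)

    bf_mask = raster(masks["bf"])
    return ParameterRecord(
        donor=donor, replicate=replicate, surface=surface, preset=preset,
        switch_time=switch_time, timepoint=timepoint,
        p1_platelet_sac=_sac(raster(masks["dioc6"])),
        p2_thrombus_sac=_sac(bf_mask),
        p3_morphology=score_morphology(bf_mask, pixel_size_um),
        p4_contraction=score_contraction(images["bf"], bf_mask, pixel_size_um),
        p5_multilayer=score_multilayering(images["dioc6"], bf_mask,
                                          pixel_size_um),
        p6_ps_sac=_sac(raster(masks["af568"])),
        p7_fibrin_sac=_sac(raster(masks["af647"])),
    )
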