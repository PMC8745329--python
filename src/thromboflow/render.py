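"""Synthetic four-channel microscopy rendering with stored ground truth.

Emulates the imaging geometry of the assay — 8-bit monochrome frames of
1360 x 1024 pixels at 0.108 µm/pixel, one frame per channel (brightfield,
DiOC6, AF568-annexin A5, AF647-fibrin(ogen)) per microspot per time point —
driven by the kinetic ground truth of :mod:`thromboflow.kinetics`.

Thrombi are rendered as clusters of platelet-sized disks around fixed
cluster centres; the cluster layout is drawn once per run so thrombi grow
(or dismantle) in place across time points.  Contraction tightens the
radial scatter of a cluster and darkens its core in brightfield;
multilayering brightens a central core in the DiOC6 channel.  The AF647
channel carries high-intensity fibrin fibres over a low-intensity soluble
fibrinogen haze so that threshold discrimination has something to do.
Every channel receives a low-frequency illumination gradient (for the FFT
background filter to remove) and Gaussian noise before 8-bit quantisation.

Greedy placement guarantees that each stored ground-truth mask covers the
kinetic state's coverage to well within half a percentage point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .kinetics import FlowRunConfig, KineticState, _stable_hash

CHANNELS = ("bf", "dioc6", "af568", "af647")

#: native raster of the acquisition camera
FULL_WIDTH = 1360
FULL_HEIGHT = 1024
FULL_PIXEL_UM = 0.108

PLATELET_RADIUS_UM = 1.5  # spread platelet footprint radius


class PlacementError(RuntimeError):
    """Requested coverage could not be reached on the given raster."""


@dataclass(frozen=True)
class RenderConfig:
    """Raster geometry and nuisance-signal levels for the renderer."""

    width: int = FULL_WIDTH
    height: int = FULL_HEIGHT
    pixel_size_um: float = FULL_PIXEL_UM
    noise_sigma: float = 4.0
    gradient_amplitude: float = 20.0
    n_clusters: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("raster must be at least 32 x 32 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @classmethod
    def quarter_scale(cls, **kw) -> "RenderConfig":
        """1/4-scale raster (340 x 256); SAC statistics are scale-free."""
        kw.setdefault("width", FULL_WIDTH // 4)
        kw.setdefault("height", FULL_HEIGHT // 4)
        kw.setdefault("pixel_size_um", FULL_PIXEL_UM * 4)
        return cls(**kw)

    @property
    def linear_scale(self) -> float:
        """Length scale relative to the native raster (1.0 = full size)."""
        return FULL_PIXEL_UM / self.pixel_size_um

    def with_seed(self, seed: int) -> "RenderConfig":
        return replace(self, seed=seed)


# intensity model (mean 8-bit levels before gradient/noise)
_LEVELS = {
    "bf_background": 210.0,
    "bf_thrombus": 110.0,
    "bf_dark_core": 35.0,
    "dioc6_background": 15.0,
    "dioc6_platelet": 150.0,
    "dioc6_thrombus": 160.0,
    "dioc6_core": 235.0,
    "af568_background": 12.0,
    "af568_ps": 170.0,
    "af647_background": 10.0,
    "af647_haze": 55.0,
    "af647_fibrin": 205.0,
}

#: fraction of a cluster's nominal area rendered as bright core per
#: multilayer level (the realised fraction is smaller once satellite jitter
#: spreads the cluster footprint)
_MUL_CORE_FRAC = 0.25
#: fraction of a cluster's area rendered as dark core per contraction level
_CON_CORE_FRAC = 0.25


@dataclass(frozen=True)
class ChannelImageSet:
    """The four rendered 8-bit images for one microspot at one time point."""

    timepoint: float
    images: dict  # channel -> uint8 array (H, W)
    pixel_size_um: float

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.images)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-timepoint binary masks and the true kinetic states behind them."""

    timepoints: tuple
    masks: tuple          # one dict channel -> bool array per timepoint
    states: tuple         # KineticState per timepoint
    pixel_size_um: float

    def true_sac(self, channel: str, index: int) -> float:
        m = self.masks[index][channel]
        return 100.0 * np.count_nonzero(m) / m.size


def _run_entropy(config: FlowRunConfig, render_cfg: RenderConfig) -> list[int]:
    sw = -1 if config.switch_time is None else int(config.switch_time)
    return [
        render_cfg.seed, config.seed,
        _stable_hash(config.donor_id), _stable_hash(config.replicate_id),
        _stable_hash(config.surface), _stable_hash(config.preset_obj.name),
        sw & 0xFFFF,
    ]


class _Layout:
    """Pre-drawn random geometry for one run, shared across time points."""

    def __init__(self, config: FlowRunConfig, cfg: RenderConfig):
        rng = np.random.default_rng(
            np.random.SeedSequence(_run_entropy(config, cfg)))
        h, w = cfg.height, cfg.width
        area = h * w
        self.r_plt = max(2, int(round(PLATELET_RADIUS_UM / cfg.pixel_size_um)))
        disk_area = np.pi * self.r_plt ** 2
        n_c = cfg.n_clusters
        margin = int(0.08 * min(h, w))
        self.centers = np.column_stack([
            rng.uniform(margin, h - margin, n_c),
            rng.uniform(margin, w - margin, n_c),
        ])
        # enough satellites per cluster to tile ~90% of the field
        self.sat_per_cluster = int(np.ceil(2.0 * area / disk_area / n_c)) + 4
        m = self.sat_per_cluster
        self.sat_angle = rng.uniform(0, 2 * np.pi, (n_c, m))
        self.sat_jitter = rng.exponential(1.0, (n_c, m))
        # independent uniform positions for single platelets and PS disks
        n_singles = int(np.ceil(2.5 * area / disk_area)) + 8
        self.single_pos = np.column_stack([
            rng.uniform(0, h, n_singles), rng.uniform(0, w, n_singles)])
        self.ps_pick = rng.random(n_singles)          # cluster vs field
        self.ps_cluster = rng.integers(0, n_c, n_singles)
        self.ps_radial = rng.uniform(0, 1, n_singles)
        self.ps_angle = rng.uniform(0, 2 * np.pi, n_singles)
        self.ps_pos = np.column_stack([
            rng.uniform(0, h, n_singles), rng.uniform(0, w, n_singles)])
        # fibrin fibre anchors/angles/lengths; budget sized for dense,
        # heavily overlapping networks (~4x the naive pixel budget)
        fib_w = max(2, int(round(0.35 / cfg.pixel_size_um)))
        mean_fib_px = 0.07 * min(h, w) * fib_w
        n_fib = int(np.ceil(4.0 * area / mean_fib_px)) + 8
        self.fib_cluster = rng.integers(0, n_c, n_fib)
        self.fib_offset = rng.normal(0, 0.18 * min(h, w), (n_fib, 2))
        self.fib_angle = rng.uniform(0, np.pi, n_fib)
        self.fib_len = rng.uniform(0.04, 0.10, n_fib) * min(h, w)
        # illumination gradient direction per channel (fixed for the run)
        self.grad_theta = {ch: rng.uniform(0, 2 * np.pi) for ch in CHANNELS}
        self.noise_seed = {ch: int(rng.integers(0, 2 ** 31)) for ch in CHANNELS}


def _paint_disk(mask: np.ndarray, count: int, r: float, c: float,
                radius: int) -> int:
    rr, cc = draw_disk((r, c), radius, shape=mask.shape)
    if rr.size:
        count += int(np.count_nonzero(~mask[rr, cc]))
        mask[rr, cc] = True
    return count


def _fill_clusters(shape: tuple, layout: _Layout, target_px: int,
                   raggedness: float) -> tuple:
    """Grow disk clusters round-robin until ``target_px`` pixels are set.

    Returns (mask, per-cluster satellite counts).  Raises
    :class:`PlacementError` if the pre-drawn satellite budget is exhausted.
    """
    mask = np.zeros(shape, dtype=bool)
    n_c = layout.centers.shape[0]
    used = np.zeros(n_c, dtype=int)
    count = 0
    r_sat = layout.r_plt
    k = 0
    while count < target_px:
        ci = k % n_c
        si = used[ci]
        if si >= layout.sat_per_cluster:
            raise PlacementError(
                f"coverage target {target_px} px unreachable: satellite "
                f"budget exhausted after {k} placements")
        rho = 0.9 * r_sat * np.sqrt(si) * (1.0 + raggedness * layout.sat_jitter[ci, si])
        ang = layout.sat_angle[ci, si]
        r = layout.centers[ci, 0] + rho * np.sin(ang)
        c = layout.centers[ci, 1] + rho * np.cos(ang)
        count = _paint_disk(mask, count, r, c, r_sat)
        used[ci] += 1
        k += 1
    return mask, used


def _cluster_core_mask(shape: tuple, layout: _Layout, used: np.ndarray,
                       area_frac: float) -> np.ndarray:
    """Central core disks covering ``area_frac`` of each cluster's footprint."""
    core = np.zeros(shape, dtype=bool)
    if area_frac <= 0:
        return core
    for ci, n_sat in enumerate(used):
        if n_sat == 0:
            continue
        r_cluster = 0.9 * layout.r_plt * np.sqrt(n_sat)
        r_core = r_cluster * np.sqrt(min(area_frac, 1.0))
        rr, cc = draw_disk((layout.centers[ci, 0], layout.centers[ci, 1]),
                           max(r_core, 1.0), shape=shape)
        core[rr, cc] = True
    return core


def _fill_singles(mask: np.ndarray, layout: _Layout, target_px: int) -> np.ndarray:
    """Add single-platelet disks at pre-drawn positions until the combined
    mask reaches ``target_px`` set pixels."""
    count = int(np.count_nonzero(mask))
    i = 0
    n = layout.single_pos.shape[0]
    while count < target_px:
        if i >= n:
            raise PlacementError("single-platelet position budget exhausted")
        r, c = layout.single_pos[i]
        count = _paint_disk(mask, count, r, c, layout.r_plt)
        i += 1
    return mask


def _fill_ps(shape: tuple, layout: _Layout, used: np.ndarray,
             target_px: int) -> np.ndarray:
    """PS-positive platelet disks, preferentially inside thrombus clusters."""
    mask = np.zeros(shape, dtype=bool)
    count = 0
    i = 0
    n = layout.ps_pos.shape[0]
    any_cluster = used.sum() > 0
    while count < target_px:
        if i >= n:
            raise PlacementError("PS position budget exhausted")
        if any_cluster and layout.ps_pick[i] < 0.7:
            ci = layout.ps_cluster[i] % len(used)
            r_cluster = 0.9 * layout.r_plt * np.sqrt(max(used[ci], 1))
            rho = r_cluster * np.sqrt(layout.ps_radial[i])
            r = layout.centers[ci, 0] + rho * np.sin(layout.ps_angle[i])
            c = layout.centers[ci, 1] + rho * np.cos(layout.ps_angle[i])
        else:
            r, c = layout.ps_pos[i]
        count = _paint_disk(mask, count, r, c, layout.r_plt)
        i += 1
    return mask


def _fill_fibres(shape: tuple, layout: _Layout, target_px: int,
                 width_px: int) -> np.ndarray:
    """Fibrin fibre segments anchored near cluster centres."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    count = 0
    i = 0
    n = layout.fib_cluster.shape[0]
    while count < target_px:
        if i >= n:
            raise PlacementError("fibre budget exhausted")
        ci = layout.fib_cluster[i]
        r0 = layout.centers[ci, 0] + layout.fib_offset[i, 0]
        c0 = layout.centers[ci, 1] + layout.fib_offset[i, 1]
        length = layout.fib_len[i]
        dr = length * np.sin(layout.fib_angle[i])
        dc = length * np.cos(layout.fib_angle[i])
        p0 = (int(np.clip(r0, 0, h - 1)), int(np.clip(c0, 0, w - 1)))
        p1 = (int(np.clip(r0 + dr, 0, h - 1)), int(np.clip(c0 + dc, 0, w - 1)))
        rr, cc = draw_line(*p0, *p1)
        for off_r in range(width_px):
            for off_c in range(width_px):
                r2 = np.clip(rr + off_r, 0, h - 1)
                c2 = np.clip(cc + off_c, 0, w - 1)
                count += int(np.count_nonzero(~mask[r2, c2]))
                mask[r2, c2] = True
        i += 1
    return mask


def _illumination(shape: tuple, amplitude: float, theta: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (xx / max(w - 1, 1) - 0.5) * np.cos(theta) \
        + (yy / max(h - 1, 1) - 0.5) * np.sin(theta)
    return amplitude * 2.0 * ramp  # peak-to-peak ~ 2*amplitude


def _finish(base: np.ndarray, layout: _Layout, channel: str,
            cfg: RenderConfig) -> np.ndarray:
    img = base + _illumination(base.shape, cfg.gradient_amplitude,
                               layout.grad_theta[channel])
    rng = np.random.default_rng(layout.noise_seed[channel])
    img = img + rng.normal(0.0, cfg.noise_sigma, base.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_images(states: "list[KineticState]", config: FlowRunConfig,
                  render_cfg: "RenderConfig | None" = None
                  ) -> tuple:
    """Render the four-channel stack for one flow run.

    Parameters
    ----------
    states : list of KineticState
        Ground-truth kinetics, one state per time point (ordered).
    config : FlowRunConfig
        Run identity; combined with ``render_cfg.seed`` it fully determines
        the output (same inputs give bit-identical images).
    render_cfg : RenderConfig, optional
        Raster geometry and nuisance levels (native full-size by default).

    Returns
    -------
    (images, truth) : (list of ChannelImageSet, GroundTruth)
    """
    cfg = render_cfg or RenderConfig()
    layout = _Layout(config, cfg)
    shape = (cfg.height, cfg.width)
    area = cfg.height * cfg.width
    fib_width = max(2, int(round(0.35 / cfg.pixel_size_um)))

    image_sets = []
    mask_sets = []
    for st in states:
        raggedness = 0.9 * (1.0 - st.contraction_level / 3.0)
        t_target = int(round(st.thrombus_coverage * area))
        thrombus, used = _fill_clusters(shape, layout, t_target, raggedness)
        p_target = int(round(st.platelet_coverage * area))
        platelet = _fill_singles(thrombus.copy(), layout, max(p_target, t_target))
        ps = _fill_ps(shape, layout, used,
                      int(round(st.ps_coverage * area)))
        fibrin = _fill_fibres(shape, layout,
                              int(round(st.fibrin_coverage * area)), fib_width)

        mul_core = _cluster_core_mask(
            shape, layout, used, _MUL_CORE_FRAC * st.multilayer_level)
        con_core = _cluster_core_mask(
            shape, layout, used, _CON_CORE_FRAC * st.contraction_level)

        bf = np.full(shape, _LEVELS["bf_background"])
        bf[thrombus] = _LEVELS["bf_thrombus"]
        bf[thrombus & con_core] = _LEVELS["bf_dark_core"]

        dioc6 = np.full(shape, _LEVELS["dioc6_background"])
        dioc6[platelet] = _LEVELS["dioc6_platelet"]
        dioc6[thrombus] = _LEVELS["dioc6_thrombus"]
        dioc6[thrombus & mul_core] = _LEVELS["dioc6_core"]

        af568 = np.full(shape, _LEVELS["af568_background"])
        af568[ps] = _LEVELS["af568_ps"]

        af647 = np.full(shape, _LEVELS["af647_background"])
        af647[thrombus | platelet] = _LEVELS["af647_haze"]
        af647[fibrin] = _LEVELS["af647_fibrin"]

        images = {
            "bf": _finish(bf, layout, "bf", cfg),
            "dioc6": _finish(dioc6, layout, "dioc6", cfg),
            "af568": _finish(af568, layout, "af568", cfg),
            "af647": _finish(af647, layout, "af647", cfg),
        }
        image_sets.append(ChannelImageSet(
            timepoint=st.time, images=images, pixel_size_um=cfg.pixel_size_um))
        mask_sets.append({
            "bf": thrombus, "dioc6": platelet, "af568": ps, "af647": fibrin,
        })

        achieved = 100.0 * np.count_nonzero(thrombus) / area
        wanted = 100.0 * st.thrombus_coverage
        if abs(achieved - wanted) > 0.5:  # placement guarantee
            warnings.warn(
                f"thrombus mask SAC {achieved:.2f}% deviates from target "
                f"{wanted:.2f}%", stacklevel=2)

    truth = GroundTruth(
        timepoints=tuple(st.time for st in states),
        masks=tuple(mask_sets),
        states=tuple(states),
        pixel_size_um=cfg.pixel_size_um,
    )
    return image_sets, truth
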