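"""Synthetic cohort generation and on-disk dataset handling.

A cohort is a set of donors, each perfused in duplicate or triplicate over
both microspot surfaces under a set of intervention conditions — the paired
design of the assay, in which every donor contributes all conditions and
donor-level noise is shared across them.  The generator writes one 8-bit
grayscale TIFF per channel per microspot per time point, ground-truth masks
alongside, and a manifest CSV tying every file to its run configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import DEFAULT_TIMEPOINTS, FlowRunConfig, KineticRates, \
    DEFAULT_RATES, simulate_kinetics
from .render import CHANNELS, RenderConfig, render_images
from .segment import SegmentationConfig, segment_image_set

MANIFEST_NAME = "manifest.csv"


@dataclass(frozen=True)
class Condition:
    """One intervention arm: surface, preset and switch time."""

    surface: str
    preset: str
    switch_time: "float | None" = None

    @property
    def switch_label(self) -> str:
        return "none" if self.switch_time is None else str(int(self.switch_time))


def _switch_label(switch_time) -> str:
    return "none" if switch_time is None else str(int(switch_time))


def image_filename(donor: str, replicate: str, surface: str, preset: str,
                   switch_time, timepoint: float, channel: str,
                   suffix: str = "") -> str:
    t = int(timepoint) if float(timepoint).is_integer() else timepoint
    return (f"{donor}_{replicate}_{surface}_{preset}_"
            f"{_switch_label(switch_time)}_t{t}_{channel}{suffix}.tif")


def config_hash(config: FlowRunConfig, render_cfg: RenderConfig) -> str:
    payload = json.dumps({
        "surface": config.surface, "preset": config.preset_obj.name,
        "switch": _switch_label(config.switch_time),
        "donor": config.donor_id, "replicate": config.replicate_id,
        "seed": config.seed, "timepoints": list(config.timepoints),
        "render": [render_cfg.width, render_cfg.height,
                   render_cfg.pixel_size_um, render_cfg.noise_sigma,
                   render_cfg.gradient_amplitude, render_cfg.seed],
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_run(out_dir: Path, config: FlowRunConfig, render_cfg: RenderConfig,
              rates: KineticRates = DEFAULT_RATES) -> list[dict]:
    """Simulate, render and write one flow run; returns manifest rows."""
    states = simulate_kinetics(config, rates)
    image_sets, truth = render_images(states, config, render_cfg)
    chash = config_hash(config, render_cfg)
    rows = []
    for j, img_set in enumerate(image_sets):
        row = {
            "donor": config.donor_id, "replicate": config.replicate_id,
            "surface": config.surface, "preset": config.preset_obj.name,
            "switch_time": _switch_label(config.switch_time),
            "timepoint": img_set.timepoint, "seed": config.seed,
            "pixel_size_um": img_set.pixel_size_um, "config_hash": chash,
        }
        st = truth.states[j]
        row.update({
            "true_p1": 100 * st.platelet_coverage,
            "true_p2": 100 * st.thrombus_coverage,
            "true_p6": 100 * st.ps_coverage,
            "true_p7": 100 * st.fibrin_coverage,
            "true_contraction": st.contraction_level,
            "true_multilayer": st.multilayer_level,
        })
        for ch in CHANNELS:
            fname = image_filename(config.donor_id, config.replicate_id,
                                   config.surface, config.preset_obj.name,
                                   config.switch_time, img_set.timepoint, ch)
            tifffile.imwrite(out_dir / fname, img_set.images[ch])
            row[f"file_{ch}"] = fname
            mname = image_filename(config.donor_id, config.replicate_id,
                                   config.surface, config.preset_obj.name,
                                   config.switch_time, img_set.timepoint, ch,
                                   suffix="_truth")
            tifffile.imwrite(out_dir / mname,
                             truth.masks[j][ch].astype(np.uint8) * 255)
            row[f"truth_{ch}"] = mname
        rows.append(row)
    return rows


def generate_cohort(out_dir: "str | Path", n_donors: int,
                    conditions: "list[Condition]", replicates: int = 2,
                    seed: int = 0,
                    render_cfg: "RenderConfig | None" = None,
                    timepoints=DEFAULT_TIMEPOINTS,
                    rates: KineticRates = DEFAULT_RATES,
                    overwrite: bool = False) -> pd.DataFrame:
    """Write a full synthetic cohort to ``out_dir``; returns the manifest.

    Every donor is run under every condition with ``replicates`` runs each;
    donor noise is shared across that donor's conditions (paired design).
    Refuses to write into a non-empty directory unless ``overwrite``.
    """
    if n_donors < 2:
        raise ValueError("a cohort needs at least 2 donors")
    if replicates not in (2, 3):
        raise ValueError("replicates must be 2 (duplicate) or 3 (triplicate)")
    if not conditions:
        raise ValueError("no conditions given")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} is not empty; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    rcfg = render_cfg or RenderConfig.quarter_scale(seed=seed)

    rows = []
    for d in range(n_donors):
        donor = f"D{d + 1:02d}"
        for cond in conditions:
            for r in range(replicates):
                config = FlowRunConfig(
                    surface=cond.surface, preset=cond.preset,
                    switch_time=cond.switch_time, donor_id=donor,
                    replicate_id=f"r{r + 1}", seed=seed,
                    timepoints=tuple(timepoints))
                rows.extend(write_run(out, config, rcfg, rates))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / MANIFEST_NAME, index=False)
    return manifest


def load_manifest(directory: "str | Path") -> pd.DataFrame:
    path = Path(directory) / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    return pd.read_csv(path, dtype={"switch_time": str})


def segment_dataset(image_dir: "str | Path", out_dir: "str | Path",
                    config: "SegmentationConfig | None" = None,
                    qc: bool = False) -> pd.DataFrame:
    """Segment every image set listed in a dataset's manifest.

    Writes one ``*_mask.tif`` ({0, 255}) per channel, optional QC overlay
    PNGs, and returns the manifest extended with mask paths.  A manifest
    row whose image file is missing raises ``FileNotFoundError`` naming it.
    """
    from .segment import overlay_qc

    image_dir = Path(image_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg = config or SegmentationConfig()
    manifest = load_manifest(image_dir)
    mask_cols = {f"mask_{ch}": [] for ch in CHANNELS}
    for _, row in manifest.iterrows():
        images = {}
        for ch in CHANNELS:
            path = image_dir / row[f"file_{ch}"]
            if not path.exists():
                raise FileNotFoundError(
                    f"channel image missing for "
                    f"{row['donor']}/{row['replicate']}/{row['surface']}/"
                    f"{row['preset']} t={row['timepoint']}: {path.name}")
            images[ch] = tifffile.imread(path)
        masks = segment_image_set(images, seg, float(row["pixel_size_um"]))
        for ch in CHANNELS:
            mname = Path(row[f"file_{ch}"]).stem + "_mask.tif"
            tifffile.imwrite(out / mname,
                             masks[ch].raster.astype(np.uint8) * 255)
            mask_cols[f"mask_{ch}"].append(mname)
            if qc:
                overlay_qc(images[ch], masks[ch].raster,
                           out / (Path(row[f"file_{ch}"]).stem + "_qc.png"))
    seg_manifest = manifest.assign(**mask_cols)
    seg_manifest.to_csv(out / MANIFEST_NAME, index=False)
    return seg_manifest


def quantify_dataset(image_dir: "str | Path", mask_dir: "str | Path",
                     out_csv: "str | Path | None" = None) -> pd.DataFrame:
    """Extract P1-P7 for every image set; returns (and writes) a tidy table."""
    from .params import extract_parameters
    from .stats import records_to_frame

    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir)
    manifest = load_manifest(mask_dir)
    records = []
    for _, row in manifest.iterrows():
        images = {ch: tifffile.imread(image_dir / row[f"file_{ch}"])
                  for ch in CHANNELS}
        masks = {ch: tifffile.imread(mask_dir / row[f"mask_{ch}"]) > 0
                 for ch in CHANNELS}
        records.append(extract_parameters(
            masks, images, donor=row["donor"], replicate=row["replicate"],
            surface=row["surface"], preset=row["preset"],
            switch_time=str(row["switch_time"]),
            timepoint=float(row["timepoint"]),
            pixel_size_um=float(row["pixel_size_um"])))
    frame = records_to_frame(records)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame


def paired_design_check(n_donors: int = 100, seed: int = 0) -> "tuple[float, float]":
    """Variance of paired vs donor-shuffled vehicle-treated differences.

    Because donor noise is shared within a donor, pairing should reduce the
    variance of treated-minus-vehicle differences relative to shuffling the
    donor assignment.  Returns (paired variance, shuffled variance) of the
    end-point thrombus coverage difference across ``n_donors`` donors.
    """
    from .kinetics import simulate_batch

    configs = []
    for d in range(n_donors):
        for preset, switch in (("vehicle", None), ("PAR1_4", 0)):
            configs.append(FlowRunConfig(
                surface="collagen_TF", preset=preset, switch_time=switch,
                donor_id=f"D{d}", replicate_id="r1", seed=seed))
    res = simulate_batch(configs)
    final_t = res["thrombus"][:, -1].reshape(n_donors, 2)
    vehicle, treated = final_t[:, 0], final_t[:, 1]
    paired_var = float(np.var(treated - vehicle, ddof=1))
    rng = np.random.default_rng(seed)
    shuffled = vehicle[rng.permutation(n_donors)]
    shuffled_var = float(np.var(treated - shuffled, ddof=1))
    return paired_var, shuffled_var
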