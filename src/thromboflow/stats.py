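"""Replicate averaging, 0-10 univariate scaling, paired testing, and
significance-filtered subtraction heatmaps.

The analysis follows the assay's statistics: thrombus parameters of
duplicate/triplicate flow runs are averaged per blood donor; each parameter
is then univariate-normalised to 0-10 across every condition, surface and
time point of the experiment set (one affine map per parameter, so scaled
means equal means of scaled values); treated and reference conditions are
compared per heatmap cell with a paired two-sided Student's t-test across
donors; and subtraction heatmaps show scaled treated-minus-reference
differences, with cells at p >= alpha set to zero when the significance
filter is on.  Raw per-cell p-values are used without multiple-testing
correction, matching the assay's convention; a Benjamini-Hochberg option
is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

KEY_COLS = ["donor", "surface", "preset", "switch_time", "timepoint"]
PARAM_COLS = ["P1", "P2", "P3", "P4", "P5", "P6", "P7"]
PARAM_LABELS = {
    "P1": "P1 platelet adhesion",
    "P2": "P2 thrombus coverage",
    "P3": "P3 thrombus morphology",
    "P4": "P4 thrombus contraction",
    "P5": "P5 thrombus multilayering",
    "P6": "P6 PS exposure",
    "P7": "P7 fibrin deposition",
}


class MissingCellError(ValueError):
    """A required (donor, condition, surface, timepoint) cell has no data."""


class AlignmentError(ValueError):
    """Treated and reference grids do not share identical keys."""


def records_to_frame(records) -> pd.DataFrame:
    """Tidy frame from :class:`~thromboflow.params.ParameterRecord` objects."""
    rows = []
    for r in records:
        p1, p2, p3, p4, p5, p6, p7 = r.values()
        rows.append({
            "donor": r.donor, "replicate": r.replicate, "surface": r.surface,
            "preset": r.preset, "switch_time": str(r.switch_time),
            "timepoint": float(r.timepoint),
            "P1": p1, "P2": p2, "P3": p3, "P4": p4, "P5": p5,
            "P6": p6, "P7": p7,
        })
    return pd.DataFrame(rows)


def average_replicates(df: pd.DataFrame,
                       required_cells: "pd.DataFrame | None" = None
                       ) -> pd.DataFrame:
    """Mean of P1-P7 across replicate runs, one row per donor-cell.

    ``required_cells`` (a frame of KEY_COLS rows) makes missing cells an
    error; by default whatever cells are present are averaged.
    """
    if df.empty:
        raise ValueError("no parameter records to average")
    out = (df.groupby(KEY_COLS, as_index=False, sort=True)[PARAM_COLS]
             .mean())
    if required_cells is not None:
        have = set(map(tuple, out[KEY_COLS].itertuples(index=False)))
        missing = [tuple(row) for row in
                   required_cells[KEY_COLS].itertuples(index=False)
                   if tuple(row) not in have]
        if missing:
            raise MissingCellError(
                f"{len(missing)} required cells have no replicates, e.g. "
                f"{missing[:3]}")
    return out


def univariate_scale(values: np.ndarray) -> np.ndarray:
    """Affine map of a series onto [0, 10]: x -> 10 (x - min) / (max - min).

    A constant series maps to all zeros with a warning (no dynamic range
    to normalise).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot scale an empty series")
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        warnings.warn("constant series: univariate scale maps to all zeros",
                      stacklevel=2)
        return np.zeros_like(x)
    # ratio first: (hi-lo)/(hi-lo) is exactly 1, so the endpoints land on
    # exactly 0 and 10
    return 10.0 * ((x - lo) / (hi - lo))


def scale_parameters(df: pd.DataFrame, scope: str = "all"
                     ) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Univariate-scale each parameter column of donor-averaged records.

    ``scope='all'`` (default) uses one (min, max) per parameter across all
    conditions, surfaces and timepoints — cross-panel comparable heatmaps;
    ``scope='surface'`` scales per parameter within each surface.  Returns
    the scaled frame and a bounds frame recording the (min, max) used.
    """
    if scope not in ("all", "surface"):
        raise ValueError("scope must be 'all' or 'surface'")
    scaled = df.copy()
    bounds = []
    groups = [(None, df)] if scope == "all" else df.groupby("surface")
    for gkey, g in groups:
        for p in PARAM_COLS:
            x = g[p].to_numpy(dtype=float)
            lo, hi = float(np.min(x)), float(np.max(x))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaled.loc[g.index, p] = univariate_scale(x)
            bounds.append({"parameter": p, "surface": gkey or "all",
                           "min": lo, "max": hi})
    return scaled, pd.DataFrame(bounds)


def paired_t_test(control, treated, axis: int = -1):
    """Two-sided paired Student's t-test.

    d = treated - control; t = mean(d) / (sd(d)/sqrt(n)) with the sample
    standard deviation (n-1 denominator); df = n-1; p from the
    t-distribution.  Degenerate cases: zero-variance differences give
    p = 0 (with a warning) when the mean difference is non-zero, and
    t = 0, p = 1 when it is zero too.

    Arrays broadcast along ``axis`` (the pairing axis), so whole heatmaps
    of cells can be tested in one call.  Returns (t, df, p).
    """
    c = np.asarray(control, dtype=float)
    tr = np.asarray(treated, dtype=float)
    if c.shape != tr.shape:
        raise ValueError(f"paired samples differ in shape: {c.shape} vs {tr.shape}")
    n = c.shape[axis]
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2 pairs, got n={n}")
    d = tr - c
    mean = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    if np.any(zero_sd & (mean != 0)):
        warnings.warn("zero-variance differences with non-zero mean: p set "
                      "to 0", stacklevel=2)
    with np.errstate(invalid="ignore"):
        degenerate_t = np.where(mean != 0, np.inf * np.sign(mean + 0.0), 0.0)
    t = np.where(zero_sd, degenerate_t, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(zero_sd, np.where(mean != 0, 0.0, 1.0), p)
    if np.ndim(t) == 0:
        return float(t), df, float(p)
    return t, df, p


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default pipeline uses raw p)."""
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat)
    ranked = flat[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(flat)
    out[order] = np.minimum(adj, 1.0)
    return out.reshape(p.shape)


@dataclass(frozen=True)
class ScaledMatrix:
    """Mean scaled parameter values per cell, with scaling provenance."""

    values: pd.DataFrame        # rows P1..P7, columns (surface, preset, switch, time)
    scale_bounds: pd.DataFrame
    n_donors: int


@dataclass(frozen=True)
class SubtractionHeatmap:
    """Scaled treated-minus-reference differences with per-cell p-values."""

    preset: str
    switch_time: str
    delta: pd.DataFrame         # rows P1..P7, cols (surface, timepoint)
    p_values: pd.DataFrame
    alpha: float = 0.05
    filtered: bool = True

    def __post_init__(self) -> None:
        if not self.delta.index.equals(self.p_values.index) or \
                not self.delta.columns.equals(self.p_values.columns):
            raise AlignmentError("delta and p-value grids are not aligned")

    @property
    def display(self) -> pd.DataFrame:
        """Delta with non-significant cells zeroed when filtered."""
        if not self.filtered:
            return self.delta
        return self.delta.where(self.p_values < self.alpha, other=0.0)


def subtraction_heatmap(scaled_treated: pd.DataFrame,
                        scaled_reference: pd.DataFrame,
                        p_values: pd.DataFrame,
                        alpha: float = 0.05, filtered: bool = True,
                        preset: str = "", switch_time: str = ""
                        ) -> SubtractionHeatmap:
    """Cell-wise scaled difference grid with the p < alpha filter."""
    if not scaled_treated.index.equals(scaled_reference.index) or \
            not scaled_treated.columns.equals(scaled_reference.columns):
        raise AlignmentError("treated and reference grids are not aligned")
    delta = scaled_treated - scaled_reference
    return SubtractionHeatmap(preset=preset, switch_time=switch_time,
                              delta=delta, p_values=p_values, alpha=alpha,
                              filtered=filtered)


def _pivot(donor_frame: pd.DataFrame, preset: str, switch: str) -> pd.DataFrame:
    """(donor x cell) values for one condition; cells = (surface, time, param)."""
    sub = donor_frame[(donor_frame["preset"] == preset)
                      & (donor_frame["switch_time"] == switch)]
    long = sub.melt(id_vars=["donor", "surface", "timepoint"],
                    value_vars=PARAM_COLS, var_name="parameter")
    return long.pivot_table(index="donor",
                            columns=["parameter", "surface", "timepoint"],
                            values="value", sort=True)


def _cell_grid(donor_cells: pd.DataFrame) -> pd.DataFrame:
    """Mean across donors, reshaped to rows P1..P7 x (surface, timepoint)."""
    mean = donor_cells.mean(axis=0)
    grid = mean.unstack(level=["surface", "timepoint"])
    return grid.reindex(PARAM_COLS)


@dataclass
class Report:
    """Everything :func:`assemble_report` produced."""

    scaled: ScaledMatrix
    heatmaps: list = field(default_factory=list)
    csv_paths: dict = field(default_factory=dict)
    figure_paths: dict = field(default_factory=dict)


def assemble_report(df: pd.DataFrame, out_dir: "str | Path | None" = None,
                    reference: "tuple[str, str]" = ("vehicle", "none"),
                    alpha: float = 0.05, filtered: bool = True,
                    scale_scope: str = "all", correction: "str | None" = None,
                    make_figures: bool = True) -> Report:
    """Full statistics pass over a tidy parameter table.

    Averages replicates per donor, scales each parameter to 0-10, builds
    the scaled heatmap, and — for every (preset, switch_time) condition
    other than the reference — a subtraction heatmap versus the reference
    condition on the same surface, with paired t-tests across donors.
    Writes ``scaled.csv``, ``scale_bounds.csv``, ``delta_{preset}_{switch}.csv``
    and PNG figures when ``out_dir`` is given.
    """
    donor_avg = average_replicates(df)
    scaled_df, bounds = scale_parameters(donor_avg, scope=scale_scope)

    conditions = sorted(set(zip(scaled_df["preset"], scaled_df["switch_time"])))
    ref_preset, ref_switch = reference
    if (ref_preset, ref_switch) not in conditions:
        raise AlignmentError(
            f"reference condition {reference} absent; have {conditions}")

    ref_cells = _pivot(scaled_df, ref_preset, ref_switch)
    n_donors = ref_cells.shape[0]
    scaled_grids = {}
    for preset, switch in conditions:
        cells = _pivot(scaled_df, preset, switch)
        scaled_grids[(preset, switch)] = _cell_grid(cells)

    heatmaps = []
    for preset, switch in conditions:
        if (preset, switch) == (ref_preset, ref_switch):
            continue
        cells = _pivot(scaled_df, preset, switch)
        if not cells.index.equals(ref_cells.index):
            raise AlignmentError(
                f"donors of {preset}@{switch} do not match the reference: "
                f"{list(cells.index)} vs {list(ref_cells.index)}")
        common = cells.columns.intersection(ref_cells.columns)
        tvals, dof, pvals = paired_t_test(
            ref_cells[common].to_numpy(), cells[common].to_numpy(), axis=0)
        p_series = pd.Series(pvals, index=common)
        if correction == "bh":
            p_series[:] = benjamini_hochberg(p_series.to_numpy())
        p_grid = p_series.unstack(level=["surface", "timepoint"]).reindex(PARAM_COLS)
        delta = scaled_grids[(preset, switch)] - scaled_grids[(ref_preset, ref_switch)]
        heatmaps.append(SubtractionHeatmap(
            preset=preset, switch_time=switch, delta=delta,
            p_values=p_grid, alpha=alpha, filtered=filtered))

    scaled_matrix = ScaledMatrix(
        values=pd.concat(
            {cond: grid for cond, grid in scaled_grids.items()},
            axis=1, names=["preset", "switch_time"]),
        scale_bounds=bounds, n_donors=n_donors)
    report = Report(scaled=scaled_matrix, heatmaps=heatmaps)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = out / "scaled.csv"
        scaled_matrix.values.to_csv(p)
        report.csv_paths["scaled"] = p
        p = out / "scale_bounds.csv"
        bounds.to_csv(p, index=False)
        report.csv_paths["scale_bounds"] = p
        for hm in heatmaps:
            name = f"delta_{hm.preset}_{hm.switch_time}"
            p = out / f"{name}.csv"
            combined = pd.concat({"delta": hm.delta, "p": hm.p_values,
                                  "display": hm.display}, axis=1)
            combined.to_csv(p)
            report.csv_paths[name] = p
        if make_figures:
            report.figure_paths.update(
                _write_figures(scaled_matrix, heatmaps, out))
    return report


def _write_figures(scaled: ScaledMatrix, heatmaps, out: Path) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    paths = {}
    fig, ax = plt.subplots(
        figsize=(max(6, 0.35 * scaled.values.shape[1]), 4))
    sns.heatmap(scaled.values, vmin=0, vmax=10, cmap="viridis", ax=ax,
                cbar_kws={"label": "scaled value (0-10)"})
    ax.set_ylabel("parameter")
    ax.set_title(f"Univariate-scaled parameters (n={scaled.n_donors} donors)")
    fig.tight_layout()
    p = out / "scaled_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["scaled"] = p

    for hm in heatmaps:
        fig, ax = plt.subplots(figsize=(max(5, 0.5 * hm.delta.shape[1]), 4))
        sns.heatmap(hm.display, vmin=-10, vmax=10, cmap="RdBu_r", ax=ax,
                    cbar_kws={"label": "scaled difference"})
        flt = f", filtered p<{hm.alpha:g}" if hm.filtered else ""
        ax.set_title(f"{hm.preset} @ switch {hm.switch_time} - reference{flt}")
        ax.set_ylabel("parameter")
        fig.tight_layout()
        p = out / f"delta_{hm.preset}_{hm.switch_time}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"delta_{hm.preset}_{hm.switch_time}"] = p
    return paths


def null_type_i_fraction(n_cohorts: int = 2000, n_donors: int = 5,
                         replicates: int = 2, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """Fraction of heatmap cells called significant under the null.

    Simulates cohorts in which both arms are vehicle runs of the same
    donors — two disjoint groups of physical replicate runs, sharing donor
    noise but with independent run noise — averages replicates, and applies
    the paired t-test per cell (parameter x timepoint).  With the test
    calibrated, about ``alpha`` of testable cells come out significant.
    Cells with no variance at all (e.g. fibrin before its onset) count as
    non-significant.
    """
    from .kinetics import FlowRunConfig, simulate_batch

    configs = []
    for c in range(n_cohorts):
        for d in range(n_donors):
            for arm in ("a", "b"):
                for r in range(replicates):
                    configs.append(FlowRunConfig(
                        surface="collagen_TF", preset="vehicle",
                        donor_id=f"c{c}_d{d}", replicate_id=f"{arm}{r}",
                        seed=seed))
    res = simulate_batch(configs)
    n_t = res["time"].size
    quantities = ("platelet", "thrombus", "ps", "fibrin",
                  "contraction", "multilayer")
    # (cohort, donor, arm, replicate, time, quantity)
    stack = np.stack([res[q] for q in quantities], axis=-1).reshape(
        n_cohorts, n_donors, 2, replicates, n_t, len(quantities))
    per_donor = stack.mean(axis=3)          # average replicates
    control = per_donor[:, :, 0]            # (cohort, donor, time, qty)
    treated = per_donor[:, :, 1]
    _, _, p = paired_t_test(control, treated, axis=1)
    return float(np.mean(p < alpha))
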