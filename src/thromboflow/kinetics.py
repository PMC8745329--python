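"""Thrombus-formation kinetics under flow with time-switchable inhibition.

The model tracks, per microspot, six state variables over the 10-minute
perfusion: platelet surface coverage (-> P1), thrombus coverage (-> P2),
phosphatidylserine-positive coverage (-> P6), fibrin coverage (-> P7), and
continuous contraction and multilayering levels on a 0-3 scale (-> P4, P5).

Coverages grow logistically, dC/dt = r * a(t) * (C + c0) * (1 - C/K), where
the activity a(t) combines two receptor pathways whose drives are
time-dependent:

* a GPVI (collagen-receptor) drive that decays as the collagen surface is
  occupied, exp(-t/tau_gpvi) — the early pathway;
* a thrombin (PAR1/4) drive that switches on after the extrinsic
  TF/FVIIa initiation event (t_ext ~ 1 min, collagen/TF surfaces only) or,
  weakly and late, through the intrinsic route on collagen alone.

Fibrin deposition starts after a delay past the extrinsic trigger (onset
around 4 min on collagen/TF, matching the vehicle time course) and never
starts within 10 min on collagen-only spots.  An inhibitor preset rescales
pathway activities from its switch time onward; blocking FVIIa instead
removes the initiation event itself, which is why late FVIIa inhibition
(after the event has fired) has no effect at all.  The integrin antagonist
adds a first-order detachment term that dismantles thrombi unless fibrin
has already stabilised them.

Inter-donor and inter-run variability are multiplicative log-normal factors
on the process rates, seeded from (seed, donor, replicate) only, so the same
blood sample perfused under two conditions shares its noise — the paired
design of the assay.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .presets import InterventionPreset, get_preset

DEFAULT_TIMEPOINTS = (2.0, 4.0, 6.0, 8.0, 10.0)
SURFACES = ("collagen", "collagen_TF")

#: kinetic processes that receive donor/replicate noise factors
NOISE_PROCESSES = ("adhesion", "aggregation", "ps_exposure", "fibrin")


@dataclass(frozen=True)
class KineticRates:
    """Rate constants of the logistic/delay model (all times in minutes).

    Values are model configuration, chosen so the vehicle time courses and
    the directional early/late inhibition effects come out right; see the
    methods note for the reasoning behind each.
    """

    # platelet adhesion (P1)
    r_adh: float = 1.2
    k_adh: float = 0.50
    seed_adh: float = 0.02
    adh_base: float = 0.40  # activation-independent (GPIb/VWF) share
    # thrombus growth / aggregation (P2)
    r_agg: float = 0.85
    k_agg: float = 0.35
    seed_agg: float = 0.012
    w_base: float = 0.05
    w_gpvi: float = 0.50
    w_thr: float = 1.20
    # phosphatidylserine exposure (P6)
    r_ps: float = 0.06
    k_ps: float = 0.30
    # fibrin deposition (P7)
    r_fib: float = 1.30
    k_fib: float = 0.40
    seed_fib: float = 0.01
    fib_floor: float = 0.30  # thrombus-independent share of fibrin growth
    fib_t_ref: float = 0.25  # thrombus coverage giving full fibrin support
    # contraction / multilayering (P4, P5)
    r_con: float = 0.40
    r_mul: float = 0.55
    # pathway timing
    tau_gpvi: float = 4.0   # decay time of the collagen-receptor drive
    t_ext: float = 1.0      # extrinsic initiation event on collagen/TF
    thr_ramp: float = 1.0   # thrombin-drive rise time after initiation
    int_amp: float = 0.15   # intrinsic thrombin drive (collagen-only), weak
    int_onset: float = 6.0
    int_ramp: float = 2.0
    fib_delay: float = 2.5  # fibrin onset = t_ext + fib_delay (~3.5 min)
    # noise
    sigma_donor: float = 0.15
    sigma_replicate: float = 0.10
    dt: float = 0.01


DEFAULT_RATES = KineticRates()


@dataclass(frozen=True)
class KineticState:
    """Ground-truth state of one microspot at one time point."""

    time: float
    platelet_coverage: float
    thrombus_coverage: float
    ps_coverage: float
    fibrin_coverage: float
    contraction_level: float
    multilayer_level: float

    def __post_init__(self) -> None:
        for attr in ("platelet_coverage", "thrombus_coverage", "ps_coverage",
                     "fibrin_coverage"):
            v = getattr(self, attr)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{attr}={v} outside [0, 1]")
        for attr in ("contraction_level", "multilayer_level"):
            v = getattr(self, attr)
            if not -1e-9 <= v <= 3.0 + 1e-9:
                raise ValueError(f"{attr}={v} outside [0, 3]")


@dataclass(frozen=True)
class FlowRunConfig:
    """One flow run: surface, intervention, switch time, identity, seed."""

    surface: str = "collagen_TF"
    preset: "str | InterventionPreset" = "vehicle"
    switch_time: "float | None" = None
    donor_id: str = "D01"
    replicate_id: str = "r1"
    seed: int = 0
    timepoints: tuple = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ValueError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        get_preset(self.preset)  # raises on unknown name
        if self.switch_time is not None and self.switch_time not in (0, 2):
            raise ValueError(
                f"switch_time must be 0, 2 or None, got {self.switch_time!r}"
            )
        tp = tuple(float(t) for t in self.timepoints)
        if not tp or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        if any(t <= 0 for t in tp):
            raise ValueError("timepoints must be positive")
        object.__setattr__(self, "timepoints", tp)

    @property
    def preset_obj(self) -> InterventionPreset:
        return get_preset(self.preset)

    @property
    def effective_switch(self) -> float:
        """Time from which the preset's factors apply (inf = never)."""
        if self.preset_obj.name == "vehicle" or self.switch_time is None:
            return np.inf
        return float(self.switch_time)

    def with_(self, **kw) -> "FlowRunConfig":
        return replace(self, **kw)


def _stable_hash(text: str) -> int:
    """Platform-stable 32-bit hash for seeding."""
    return zlib.crc32(str(text).encode("utf-8"))


def noise_factors(config: FlowRunConfig, rates: KineticRates = DEFAULT_RATES
                  ) -> dict[str, float]:
    """Multiplicative log-normal noise per kinetic process for one run.

    Donor factors (sigma 0.15) depend on (seed, donor) only, so they are
    shared across every run of that donor — the paired design.  Replicate
    factors (sigma 0.10) depend on (seed, donor, replicate): two conditions
    perfused from the same blood sample share them, two physical runs do not.
    """
    d = _stable_hash(config.donor_id)
    r = _stable_hash(config.replicate_id)
    rng_d = np.random.default_rng(np.random.SeedSequence([config.seed, d, 11]))
    rng_r = np.random.default_rng(np.random.SeedSequence([config.seed, d, r, 13]))
    donor = np.exp(rng_d.normal(0.0, rates.sigma_donor, len(NOISE_PROCESSES)))
    rep = np.exp(rng_r.normal(0.0, rates.sigma_replicate, len(NOISE_PROCESSES)))
    return dict(zip(NOISE_PROCESSES, donor * rep))


def _batch_arrays(configs: "list[FlowRunConfig]", rates: KineticRates
                  ) -> dict[str, np.ndarray]:
    n = len(configs)
    out = {
        "is_tf": np.array([c.surface == "collagen_TF" for c in configs]),
        "switch": np.array([c.effective_switch for c in configs]),
        "f_gpvi": np.empty(n), "f_par": np.empty(n), "f_itg": np.empty(n),
        "f_ps": np.empty(n), "detach": np.empty(n),
        "blocks_ext": np.empty(n, dtype=bool),
        "n_adh": np.empty(n), "n_agg": np.empty(n),
        "n_ps": np.empty(n), "n_fib": np.empty(n),
    }
    for i, c in enumerate(configs):
        p = c.preset_obj
        out["f_gpvi"][i] = p.gpvi_factor
        out["f_par"][i] = p.par_factor
        out["f_itg"][i] = p.integrin_factor
        out["f_ps"][i] = p.ps_factor
        out["detach"][i] = p.detachment_per_min
        out["blocks_ext"][i] = p.blocks_extrinsic
        nf = noise_factors(c, rates)
        out["n_adh"][i] = nf["adhesion"]
        out["n_agg"][i] = nf["aggregation"]
        out["n_ps"][i] = nf["ps_exposure"]
        out["n_fib"][i] = nf["fibrin"]
    return out


def simulate_batch(configs: "list[FlowRunConfig]",
                   rates: KineticRates = DEFAULT_RATES) -> dict[str, np.ndarray]:
    """Integrate the kinetic model for many runs at once.

    All runs must share the same timepoints.  Returns arrays of shape
    (n_runs, n_timepoints) under keys ``platelet``, ``thrombus``, ``ps``,
    ``fibrin``, ``contraction``, ``multilayer``, plus ``time`` (n_timepoints,).
    """
    if not configs:
        raise ValueError("no run configurations given")
    timepoints = configs[0].timepoints
    if any(c.timepoints != timepoints for c in configs):
        raise ValueError("all runs in a batch must share timepoints")

    a = _batch_arrays(configs, rates)
    n = len(configs)
    dt = rates.dt
    t_end = timepoints[-1]
    n_steps = int(round(t_end / dt))
    rec_steps = {int(round(t / dt)): j for j, t in enumerate(timepoints)}

    # the extrinsic initiation event fires on TF spots unless FVIIa is
    # inhibited at the time of the event
    triggered = a["is_tf"] & ~(a["blocks_ext"] & (a["switch"] <= rates.t_ext))
    fib_onset = np.where(triggered, rates.t_ext + rates.fib_delay, np.inf)

    P = np.zeros(n); T = np.zeros(n); S = np.zeros(n); F = np.zeros(n)
    CON = np.zeros(n); MUL = np.zeros(n)
    out = {k: np.empty((n, len(timepoints)))
           for k in ("platelet", "thrombus", "ps", "fibrin",
                     "contraction", "multilayer")}

    for step in range(1, n_steps + 1):
        t = step * dt
        active = t >= a["switch"]
        fg = np.where(active, a["f_gpvi"], 1.0)
        fp = np.where(active, a["f_par"], 1.0)
        fi = np.where(active, a["f_itg"], 1.0)
        fps = np.where(active, a["f_ps"], 1.0)
        stabilised = triggered & (t >= rates.t_ext)
        det = np.where(active & ~stabilised, a["detach"], 0.0)

        gpvi_drive = np.exp(-t / rates.tau_gpvi)
        thr_ext = np.where(triggered & (t > rates.t_ext),
                           1.0 - np.exp(-(t - rates.t_ext) / rates.thr_ramp), 0.0)
        thr_int = rates.int_amp * np.clip(
            (t - rates.int_onset) / rates.int_ramp, 0.0, 1.0)
        thr = thr_ext + thr_int

        act_adh = fg * gpvi_drive + 0.5 * fp * thr
        act_agg = rates.w_base + rates.w_gpvi * fg * gpvi_drive \
            + rates.w_thr * fp * thr

        dP = rates.r_adh * a["n_adh"] \
            * (rates.adh_base + (1 - rates.adh_base) * np.minimum(act_adh, 1.0)) \
            * (P + rates.seed_adh) * (1 - P / rates.k_adh)
        dT = rates.r_agg * a["n_agg"] * fi * act_agg \
            * (T + rates.seed_agg) * (1 - T / rates.k_agg) - det * T
        dS = rates.r_ps * a["n_ps"] * fps * P * (1 - S / rates.k_ps)
        supp = rates.fib_floor + (1 - rates.fib_floor) \
            * np.minimum(T / rates.fib_t_ref, 1.0)
        dF = np.where(t >= fib_onset,
                      rates.r_fib * a["n_fib"] * supp
                      * (F + rates.seed_fib) * (1 - F / rates.k_fib), 0.0)
        # contraction/multilayering share the aggregation pathway's
        # platelet-reactivity noise
        con_drive = np.minimum(0.3 * fg * gpvi_drive + fp * thr + 0.1, 1.0)
        dCON = rates.r_con * a["n_agg"] * fi * con_drive * (1 - CON / 3.0) - det * CON
        mul_drive = np.minimum(act_agg / 1.5, 1.0)
        dMUL = rates.r_mul * a["n_agg"] * fi * mul_drive * (1 - MUL / 3.0) - det * MUL

        P = np.clip(P + dt * dP, 0.0, 1.0)
        T = np.clip(T + dt * dT, 0.0, 1.0)
        T = np.minimum(T, P)  # thrombi are a subset of the platelet deposit
        S = np.clip(S + dt * dS, 0.0, 1.0)
        F = np.clip(F + dt * dF, 0.0, 1.0)
        CON = np.clip(CON + dt * dCON, 0.0, 3.0)
        MUL = np.clip(MUL + dt * dMUL, 0.0, 3.0)

        j = rec_steps.get(step)
        if j is not None:
            out["platelet"][:, j] = P
            out["thrombus"][:, j] = T
            out["ps"][:, j] = S
            out["fibrin"][:, j] = F
            out["contraction"][:, j] = CON
            out["multilayer"][:, j] = MUL

    out["time"] = np.asarray(timepoints, dtype=float)
    return out


def simulate_kinetics(config: FlowRunConfig,
                      rates: KineticRates = DEFAULT_RATES) -> list[KineticState]:
    """Simulate one flow run; returns one :class:`KineticState` per timepoint."""
    res = simulate_batch([config], rates)
    return [
        KineticState(
            time=float(res["time"][j]),
            platelet_coverage=float(res["platelet"][0, j]),
            thrombus_coverage=float(res["thrombus"][0, j]),
            ps_coverage=float(res["ps"][0, j]),
            fibrin_coverage=float(res["fibrin"][0, j]),
            contraction_level=float(res["contraction"][0, j]),
            multilayer_level=float(res["multilayer"][0, j]),
        )
        for j in range(len(res["time"]))
    ]


def true_morphology_class(thrombus_coverage: float, multilayer_level: float) -> int:
    """Ground-truth morphology score (0-5) implied by the kinetic state.

    Mirrors the ordinal scale: bare field, single platelets, widespread
    singles, then small / medium / big aggregates as coverage and
    multilayering build up.  Used as the renderer's target class and as the
    test oracle; the measured P3 comes from the segmented mask.
    """
    t = thrombus_coverage
    if t < 0.001:
        return 0
    if t < 0.01:
        return 1
    if t < 0.03:
        return 2 if multilayer_level < 0.5 else 3
    if t < 0.08:
        return 3 if multilayer_level < 1.0 else 4
    if t < 0.15:
        return 4
    return 5


@dataclass(frozen=True)
class TrueRecord:
    """Ground-truth P1-P7 for one run/timepoint (percent SAC and scores)."""

    config: FlowRunConfig = field(repr=False)
    timepoint: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    p3: int = 0
    p4: float = 0.0
    p5: float = 0.0
    p6: float = 0.0
    p7: float = 0.0


def true_records(configs: "list[FlowRunConfig]",
                 rates: KineticRates = DEFAULT_RATES) -> list[TrueRecord]:
    """Ground-truth parameter records for a batch of runs (no rendering)."""
    res = simulate_batch(configs, rates)
    recs = []
    for i, c in enumerate(configs):
        for j, t in enumerate(res["time"]):
            recs.append(TrueRecord(
                config=c, timepoint=float(t),
                p1=100.0 * res["platelet"][i, j],
                p2=100.0 * res["thrombus"][i, j],
                p3=true_morphology_class(res["thrombus"][i, j],
                                         res["multilayer"][i, j]),
                p4=res["contraction"][i, j],
                p5=res["multilayer"][i, j],
                p6=100.0 * res["ps"][i, j],
                p7=100.0 * res["fibrin"][i, j],
            ))
    return recs
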