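"""Pharmacological intervention presets.

Each preset encodes, as multiplicative activity factors in [0, 1], how an
inhibitor acts on the kinetic processes of thrombus formation once the
inhibited blood reaches the chamber:

``gpvi_factor``
    Residual GPVI->Syk collagen-receptor signalling (drives early adhesion,
    aggregation and, through ``ps_factor``, phosphatidylserine exposure).
``par_factor``
    Residual PAR1/PAR4 thrombin-receptor signalling (drives sustained
    aggregation and contraction once thrombin is being generated).
``integrin_factor``
    Residual integrin aIIbb3 aggregation capacity; zero means platelets can
    still adhere as a monolayer but cannot build multilayered thrombi.
``ps_factor``
    Residual GPVI-gated phosphatidylserine exposure.
``detachment_per_min``
    First-order dismantlement rate of existing thrombus mass; only the
    integrin antagonist has one, and it is suppressed once fibrin has
    stabilised the thrombi (collagen/TF surfaces after coagulation onset).
``blocks_extrinsic``
    Whether the inhibitor prevents the TF/FVIIa extrinsic initiation event.
    This event fires within the first minute of flow, so blocking it only
    matters when the inhibitor is present from the start.

Factor values are tunable model configuration chosen to reproduce the
directional early/late inhibition effects; they are not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class InterventionPreset:
    name: str
    gpvi_factor: float = 1.0
    par_factor: float = 1.0
    integrin_factor: float = 1.0
    ps_factor: float = 1.0
    detachment_per_min: float = 0.0
    blocks_extrinsic: bool = False
    acts_on: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for attr in ("gpvi_factor", "par_factor", "integrin_factor", "ps_factor"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.detachment_per_min < 0:
            raise ValueError(f"{self.name}: detachment rate must be >= 0")


PRESETS: dict[str, InterventionPreset] = {
    "vehicle": InterventionPreset(name="vehicle"),
    # active-site-inhibited factor VIIa: kills the extrinsic (TF-driven)
    # initiation of coagulation, nothing else
    "iFVIIa": InterventionPreset(
        name="iFVIIa",
        blocks_extrinsic=True,
        acts_on=frozenset({"thrombin_fibrin"}),
    ),
    # atopaxar + BMS-986120: PAR1 and PAR4 blockade
    "PAR1_4": InterventionPreset(
        name="PAR1_4",
        par_factor=0.15,
        acts_on=frozenset({"adhesion", "aggregation", "stability"}),
    ),
    # anti-GPVI Fab (EMF-1)
    "GPVI_Fab": InterventionPreset(
        name="GPVI_Fab",
        gpvi_factor=0.10,
        ps_factor=0.02,
        acts_on=frozenset({"adhesion", "aggregation", "ps_exposure"}),
    ),
    # Syk kinase inhibitor PRT-060318; slightly stronger than the Fab since
    # it also silences non-GPVI receptors that signal through Syk
    "Syk_IN": InterventionPreset(
        name="Syk_IN",
        gpvi_factor=0.05,
        ps_factor=0.015,
        acts_on=frozenset({"adhesion", "aggregation", "ps_exposure"}),
    ),
    # tirofiban: integrin aIIbb3 antagonist; blocks aggregation outright and
    # dismantles unstabilised thrombi
    "tirofiban": InterventionPreset(
        name="tirofiban",
        integrin_factor=0.0,
        detachment_per_min=0.3,
        acts_on=frozenset({"aggregation", "stability"}),
    ),
}

PRESET_NAMES = tuple(PRESETS)


def get_preset(preset: "str | InterventionPreset") -> InterventionPreset:
    if isinstance(preset, InterventionPreset):
        return preset
    try:
        return PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; known presets: {', '.join(PRESETS)}"
        ) from None
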