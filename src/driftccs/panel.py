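"""Reference panel: seven bioactive compounds of *Dendrobium officinale*.

Published drift-tube measurements for the seven-compound panel
(scoparone, dendrobine, apigenin, naringenin, dendrophenol, luteolin,
erianin, as their [M+H]+ ions) that the worked examples, the synthetic
study generator and the self-consistency checks use as ground truth:
apex drift time at the 1700 V fixed field, single- and stepped-field CCS,
their pairwise agreement, and the stepped-field regression parameters
(t0, K0).

Also included: the reported per-compound quantification results on a real
stem sample — extract concentration (µg/mL) and the derived per-gram
content for a 30 mg sample eluted in 200 µL.
"""

from __future__ import annotations

from dataclasses import dataclass

from .physics import IonSpecies


@dataclass(frozen=True)
class PanelCompound:
    """One reference compound with its published drift-tube values."""

    name: str
    mz: float                 # [M+H]+ m/z, Th
    drift_time_ms: float      # apex drift time at the 1700 V fixed field
    ccs_single: float         # Å², single-field calibration route
    ccs_multi: float          # Å², stepped-field (Mason-Schamp) route
    agreement_pct: float      # reported single/multi relative spread, %
    t0_ms: float              # stepped-field intercept
    k0: float                 # reduced mobility, cm²/(V·s)

    @property
    def ion(self) -> IonSpecies:
        return IonSpecies(self.name, self.mz, 1)


#: The published seven-compound reference table.
REFERENCE_PANEL: tuple[PanelCompound, ...] = (
    PanelCompound("Scoparone",    207.065, 17.06, 137.5, 139.3, 0.65, 4.05, 1.539),
    PanelCompound("Dendrobine",   264.196, 19.76, 157.1, 158.3, 0.38, 4.79, 1.336),
    PanelCompound("Apigenin",     271.060, 19.70, 156.4, 158.7, 0.73, 4.69, 1.331),
    PanelCompound("Naringenin",   273.076, 20.27, 160.8, 165.4, 1.41, 4.64, 1.275),
    PanelCompound("Dendrophenol", 275.128, 20.13, 159.6, 162.4, 0.87, 4.75, 1.301),
    PanelCompound("Luteolin",     287.055, 20.29, 160.6, 163.0, 0.74, 4.81, 1.290),
    PanelCompound("Erianin",      319.154, 21.32, 167.9, 170.3, 0.71, 5.06, 1.230),
)

#: Drift-voltage ladder of the stepped-field measurement (V).
STEPPED_FIELD_VOLTAGES: tuple[float, ...] = (
    1000.0, 1100.0, 1200.0, 1300.0, 1400.0, 1500.0, 1600.0, 1700.0,
)

#: Fixed drift voltage of the single-field measurement (V).
SINGLE_FIELD_VOLTAGE: float = 1700.0

#: Reported real-sample quantification: extract concentration (µg/mL) and
#: per-gram content on the printed scale (30 mg sample, 200 µL elution).
REFERENCE_CONTENTS: dict[str, tuple[float, float]] = {
    "Scoparone":    (0.029, 0.19),
    "Dendrobine":   (0.091, 0.61),
    "Apigenin":     (0.797, 5.32),
    "Naringenin":   (1.884, 12.56),
    "Dendrophenol": (0.019, 0.13),
    "Luteolin":     (0.988, 6.59),
    "Erianin":      (9.026, 60.18),
}

#: Reported average spike recoveries (%) at the two spike levels (µg/mL).
REFERENCE_RECOVERIES: dict[str, dict[float, float]] = {
    "Scoparone":    {0.05: 103.0, 1.0: 127.0},
    "Dendrobine":   {0.05: 86.5, 1.0: 46.4},
    "Apigenin":     {0.05: 101.0, 1.0: 68.2},
    "Naringenin":   {0.05: 95.0, 1.0: 42.3},
    "Dendrophenol": {0.05: 60.7, 1.0: 41.2},
    "Luteolin":     {0.05: 97.1, 1.0: 23.8},
    "Erianin":      {0.05: 89.8, 1.0: 52.4},
}
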