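"""Synthetic study generator.

Emulates the full data-generating process of a drift-tube IM-QTOF assay
with a micro-extraction front end, so that every pipeline stage can be
exercised end-to-end with known ground truth:

* arrival-time spectra across a ladder of drift voltages — one Gaussian
  drift peak per (compound, voltage) at the kinematically exact drift
  time, plus additive counting noise;
* a calibration series per analyte — linear response in concentration
  with multiplicative (per-cent-scale) noise, reflecting the
  heteroscedastic areas real calibrations show;
* unspiked and spiked sample areas whose back-calculated recoveries
  embed chosen true recovery factors;
* matrix/solvent area pairs embedding chosen matrix-effect factors.

The default compound panel is the published seven-compound Dendrobium
reference set with its reported reduced mobilities and transit times, so
the shipped demo reproduces a report of the familiar shape. Randomness
is counter-based: one global seed plus stable per-output stream keys, so
adding a compound never perturbs another file's noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import REFERENCE_PANEL, REFERENCE_RECOVERIES, STEPPED_FIELD_VOLTAGES
from .physics import InstrumentConfig, IonSpecies, drift_time
from .spectra import DriftSpectrum

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class CompoundTruth:
    """Ground truth for one simulated compound."""

    name: str
    mz: float
    z: int = 1
    k0: float = 1.3            # reduced mobility, cm²/(V·s)
    t0_ms: float = 4.5         # transit time outside the drift region
    base_conc_ug_ml: float = 0.5   # concentration in the unspiked extract
    cal_slope: float = 1.0e6       # area per (µg/mL)
    cal_intercept: float = 0.0
    matrix_factor: float = 0.90
    recoveries: dict = field(default_factory=dict)  # spike level -> fraction

    @property
    def ion(self) -> IonSpecies:
        return IonSpecies(self.name, self.mz, self.z)


#: Base extract concentrations (µg/mL) for the default panel — the
#: reported real-sample values, so the demo report has familiar numbers.
_DEFAULT_BASE_CONC = {
    "Scoparone": 0.029, "Dendrobine": 0.091, "Apigenin": 0.797,
    "Naringenin": 1.884, "Dendrophenol": 0.019, "Luteolin": 0.988,
    "Erianin": 9.026,
}

#: Matrix-effect factors for the default panel, spanning the mild
#: ion-suppression range (85–96%) typical of this matrix.
_DEFAULT_MATRIX = {
    "Scoparone": 0.85, "Dendrobine": 0.87, "Apigenin": 0.89,
    "Naringenin": 0.91, "Dendrophenol": 0.93, "Luteolin": 0.95,
    "Erianin": 0.96,
}


def default_compounds() -> tuple[CompoundTruth, ...]:
    """The seven-compound reference panel as simulation ground truth."""
    out = []
    for i, row in enumerate(REFERENCE_PANEL):
        out.append(CompoundTruth(
            name=row.name,
            mz=row.mz,
            k0=row.k0,
            t0_ms=row.t0_ms,
            base_conc_ug_ml=_DEFAULT_BASE_CONC[row.name],
            cal_slope=1.0e6 * (1.0 + 0.5 * i),
            cal_intercept=0.0,
            matrix_factor=_DEFAULT_MATRIX[row.name],
            recoveries={lvl: pct / 100.0
                        for lvl, pct in REFERENCE_RECOVERIES[row.name].items()},
        ))
    return tuple(out)


@dataclass(frozen=True)
class SimulationScenario:
    """Everything that defines one synthetic study.

    Spectral defaults: 0.35 ms FWHM drift peaks (plausible for a
    ~20 ms drift regime on a uniform tube), peak height 1000 counts over
    a 20-count detector baseline, additive noise sigma 5 counts, 0.01 ms
    grid. Quantification
    defaults: six calibration levels spanning 0.05–5 µg/mL, three
    replicates, 2% multiplicative area noise, spike levels 0.05 and
    1 µg/mL with two replicates each.
    """

    compounds: tuple[CompoundTruth, ...] = field(default_factory=default_compounds)
    cfg: InstrumentConfig = field(default_factory=InstrumentConfig)
    voltages: tuple[float, ...] = STEPPED_FIELD_VOLTAGES
    peak_fwhm_ms: float = 0.35
    peak_height: float = 1000.0
    baseline: float = 20.0           # detector baseline, counts
    noise_sd: float = 5.0            # counts, additive, per time sample
    grid_dt_ms: float = 0.01
    grid_pad_ms: float = 3.0
    cal_levels: tuple[float, ...] = (0.05, 0.1, 0.5, 1.0, 2.0, 5.0)
    cal_replicates: int = 3
    cal_cv: float = 0.02             # multiplicative area noise
    spike_levels: tuple[float, ...] = (0.05, 1.0)
    sample_replicates: int = 2
    seed: int = 0

    def truth(self) -> dict:
        """Ground-truth manifest (JSON-serialisable)."""
        return {
            "seed": self.seed,
            "instrument": self.cfg.to_dict(),
            "voltages": list(self.voltages),
            "compounds": [asdict(c) for c in self.compounds],
            "cal_levels": list(self.cal_levels),
            "cal_cv": self.cal_cv,
            "spike_levels": list(self.spike_levels),
        }


def _stream(seed: int, *tokens) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed by (seed, tokens)."""
    keys = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *keys]))


def simulate_stepped_spectra(scn: SimulationScenario) -> list[DriftSpectrum]:
    """One arrival-time spectrum per (compound, voltage).

    The Gaussian apex sits at the kinematic drift time of the compound's
    true reduced mobility under the scenario's instrument state; noise is
    additive Gaussian, clipped at zero counts.
    """
    sigma_peak = scn.peak_fwhm_ms / _FWHM_PER_SIGMA
    out: list[DriftSpectrum] = []
    for comp in scn.compounds:
        for v in scn.voltages:
            td = drift_time(comp.k0, v, scn.cfg, comp.t0_ms)
            t_lo = td - scn.grid_pad_ms
            n = int(round(2 * scn.grid_pad_ms / scn.grid_dt_ms)) + 1
            times = t_lo + scn.grid_dt_ms * np.arange(n)
            signal = scn.baseline + scn.peak_height * np.exp(
                -0.5 * ((times - td) / sigma_peak) ** 2
            )
            if scn.noise_sd > 0:
                rng = _stream(scn.seed, "spectrum", comp.name, int(v))
                signal = signal + rng.normal(0.0, scn.noise_sd, size=n)
            out.append(DriftSpectrum(
                times=times,
                intensities=np.clip(signal, 0.0, None),
                compound=comp.name,
                drift_voltage=float(v),
            ))
    return out


def simulate_quant_study(scn: SimulationScenario) -> dict[str, pd.DataFrame]:
    """Calibration, sample and matrix-pair tables for the scenario.

    Returns ``{"calibration": ..., "samples": ..., "matrix": ...}`` in
    the long CSV schemas the validation readers expect. Spiked-sample
    areas are built so that back-calculating through the true calibration
    line recovers each compound's true recovery fraction (before noise).
    """
    cal_rows, sample_rows, matrix_rows = [], [], []
    for comp in scn.compounds:
        line = lambda c: comp.cal_slope * c + comp.cal_intercept
        rng = _stream(scn.seed, "calibration", comp.name)
        for conc in scn.cal_levels:
            for rep in range(1, scn.cal_replicates + 1):
                noise = 1.0 + scn.cal_cv * rng.normal() if scn.cal_cv > 0 else 1.0
                cal_rows.append({
                    "analyte": comp.name,
                    "concentration_ug_ml": conc,
                    "replicate": rep,
                    "peak_area": line(conc) * noise,
                })
        rng = _stream(scn.seed, "samples", comp.name)
        for rep in range(1, scn.sample_replicates + 1):
            noise = 1.0 + scn.cal_cv * rng.normal() if scn.cal_cv > 0 else 1.0
            sample_rows.append({
                "analyte": comp.name,
                "sample_id": f"unspiked-{rep}",
                "spiked_level_ug_ml": 0.0,
                "peak_area": line(comp.base_conc_ug_ml) * noise,
            })
        for lvl in scn.spike_levels:
            rec = comp.recoveries.get(lvl, 1.0)
            total = comp.base_conc_ug_ml + rec * lvl
            for rep in range(1, scn.sample_replicates + 1):
                noise = 1.0 + scn.cal_cv * rng.normal() if scn.cal_cv > 0 else 1.0
                sample_rows.append({
                    "analyte": comp.name,
                    "sample_id": f"spike-{lvl}-{rep}",
                    "spiked_level_ug_ml": lvl,
                    "peak_area": line(total) * noise,
                })
        rng = _stream(scn.seed, "matrix", comp.name)
        mid_conc = scn.cal_levels[len(scn.cal_levels) // 2]
        noise_m = 1.0 + scn.cal_cv * rng.normal() if scn.cal_cv > 0 else 1.0
        noise_s = 1.0 + scn.cal_cv * rng.normal() if scn.cal_cv > 0 else 1.0
        area_solvent = line(mid_conc) * noise_s
        matrix_rows.append({
            "analyte": comp.name,
            "concentration_ug_ml": mid_conc,
            "peak_area_matrix": comp.matrix_factor * line(mid_conc) * noise_m,
            "peak_area_solvent": area_solvent,
        })
    return {
        "calibration": pd.DataFrame(cal_rows),
        "samples": pd.DataFrame(sample_rows),
        "matrix": pd.DataFrame(matrix_rows),
    }


def spectra_to_frame(spectra: list[DriftSpectrum]) -> pd.DataFrame:
    """Long-format table (compound, drift_voltage_v, time_ms, intensity)."""
    frames = []
    for s in spectra:
        frames.append(pd.DataFrame({
            "compound": s.compound,
            "drift_voltage_v": s.drift_voltage,
            "time_ms": s.times,
            "intensity": s.intensities,
        }))
    return pd.concat(frames, ignore_index=True)


def write_study(scn: SimulationScenario, outdir: str | Path) -> dict[str, Path]:
    """Materialise a full synthetic study as a directory tree.

    Writes ``spectra/<compound>_<voltage>V.csv``, ``calibration.csv``,
    ``samples.csv``, ``matrix.csv`` and the ground-truth manifest
    ``scenario.json``; returns the paths. Byte-identical for the same
    scenario.
    """
    outdir = Path(outdir)
    specdir = outdir / "spectra"
    specdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for s in simulate_stepped_spectra(scn):
        p = specdir / f"{s.compound}_{int(s.drift_voltage)}V.csv"
        pd.DataFrame({"time_ms": s.times, "intensity": s.intensities}).to_csv(
            p, index=False, float_format="%.6f"
        )
    paths["spectra"] = specdir
    ions = pd.DataFrame(
        [{"compound": c.name, "mz": c.mz, "z": c.z} for c in scn.compounds]
    )
    ions_path = outdir / "ions.csv"
    ions.to_csv(ions_path, index=False)
    paths["ions"] = ions_path
    tables = simulate_quant_study(scn)
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p
    manifest = outdir / "scenario.json"
    manifest.write_text(json.dumps(scn.truth(), indent=2, sort_keys=True))
    paths["scenario"] = manifest
    return paths
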