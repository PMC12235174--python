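"""Synthetic plates of bioluminescence traces and qPCR Ct tables.

The generator emulates the experimental design the analysis assumes: ~6-day
recordings of luciferase-reporter nematode populations in a 96-well plate,
first under a dual 12:12 light-dark / cold-warm cycle (entrainment), then
under constant dark and warm temperature (free run). Each well's signal is an
additive model

    y(t) = env(t) * (mesor + amplitude * cos(theta(t))) + noise(t)

where ``env`` is a saturating luciferase-accumulation ramp followed by
exponential damping, and the instantaneous phase ``theta`` advances with the
entrained period while the zeitgeber cycles and with the genotype's
free-running period after release, continuously at the transition. Arrhythmic
wells (a configurable fraction) keep the same envelope and noise but have zero
oscillation amplitude. Every well carries a ground-truth record so downstream
stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import PlateRecording, TraceSeries

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ProtocolSchedule:
    """Recording protocol: cadence, entrained/free-run days, zeitgeber frame.

    Defaults mirror the standard protocol: one 10-s integration per well every 30 min,
    3 days of dual LD/CW cycling (12 h photoperiod, 15.5/17.0 degC) then
    3 days of DD/WW free run, recording started at ZT12.
    """

    sampling_interval: float = 0.5
    n_days_entrained: int = 3
    n_days_freerun: int = 3
    record_start_zt: float = 12.0
    photoperiod: float = 12.0
    temp_cold: float = 15.5
    temp_warm: float = 17.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.n_days_entrained < 0 or self.n_days_freerun < 0:
            raise ValueError("day counts must be non-negative")

    @property
    def temp_delta(self) -> float:
        return self.temp_warm - self.temp_cold

    @property
    def total_hours(self) -> float:
        return 24.0 * (self.n_days_entrained + self.n_days_freerun)

    @property
    def release_hour(self) -> float:
        """Hours from recording start at which free run begins."""
        return 24.0 * self.n_days_entrained

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.total_hours, self.sampling_interval)


@dataclass(frozen=True)
class GenotypeSpec:
    """Ground-truth rhythm parameters for one strain.

    ``period_freerun`` is the endogenous period tau revealed under constant
    conditions (e.g. ~24.2 h for the control reporter strain, ~27.1 h for the
    clock-gene mutant). ``acrophase_zt`` is the entrained peak time; control
    traces peak in the nocturnal/warm phase (~ZT18). ``transient_hours`` is
    the initial luciferase-accumulation ramp; ``damping_rate`` the exponential
    signal decay; ``fraction_rhythmic`` the probability a well oscillates at
    all.
    """

    label: str = "control"
    period_entrained: float = 24.0
    period_freerun: float = 24.2
    acrophase_zt: float = 18.0
    amplitude: float = 2.0
    mesor: float = 5.0
    damping_rate: float = 0.01
    transient_hours: float = 12.0
    noise_sd: float = 0.3
    fraction_rhythmic: float = 0.5
    phase_offset_at_release: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.damping_rate < 0:
            raise ValueError("damping_rate must be >= 0")
        if not 0.0 <= self.fraction_rhythmic <= 1.0:
            raise ValueError("fraction_rhythmic must be in [0, 1]")
        if self.period_entrained <= 0 or self.period_freerun <= 0:
            raise ValueError("periods must be positive")


@dataclass
class SynthPlate:
    """A generated plate plus its per-well ground truth."""

    recording: PlateRecording
    truth: pd.DataFrame  # well, strain, rhythmic, period_freerun_h, acrophase_zt
    seed: int

    def truth_for(self, well_id: str) -> pd.Series:
        row = self.truth.loc[self.truth["well"] == well_id]
        if row.empty:
            raise KeyError(well_id)
        return row.iloc[0]


def _envelope(t: np.ndarray, transient_hours: float, damping_rate: float) -> np.ndarray:
    ramp = np.ones_like(t) if transient_hours <= 0 else np.minimum(t / transient_hours, 1.0)
    return ramp * np.exp(-damping_rate * t)


def _phase(t: np.ndarray, genotype: GenotypeSpec, protocol: ProtocolSchedule) -> np.ndarray:
    """Instantaneous cosine phase, continuous at the entrained->free-run switch."""
    # Entrained: peak when ZT == acrophase_zt, i.e. t + record_start_zt == acrophase (mod tau_ent)
    t_rel = t + protocol.record_start_zt - genotype.acrophase_zt
    phase_ent = TWO_PI * t_rel / genotype.period_entrained
    t_release = protocol.release_hour
    phase_at_release = (
        TWO_PI
        * (t_release + protocol.record_start_zt - genotype.acrophase_zt)
        / genotype.period_entrained
    )
    phase_fr = (
        phase_at_release
        + TWO_PI * (t - t_release + genotype.phase_offset_at_release) / genotype.period_freerun
    )
    return np.where(t < t_release, phase_ent, phase_fr)


def generate_trace(
    genotype: GenotypeSpec,
    protocol: ProtocolSchedule,
    seed: int | np.random.SeedSequence,
    well_id: str = "A1",
    rhythmic: bool | None = None,
) -> tuple[TraceSeries, bool]:
    """Generate one well's trace; returns (trace, is_rhythmic).

    ``rhythmic=None`` draws the well's rhythmicity as a Bernoulli trial with
    probability ``fraction_rhythmic`` from the same seeded stream as the
    noise, so a (genotype, protocol, seed) triple is fully reproducible.
    """
    rng = np.random.default_rng(seed)
    t = protocol.time_grid()
    if rhythmic is None:
        rhythmic = bool(rng.random() < genotype.fraction_rhythmic)
    amplitude = genotype.amplitude if rhythmic else 0.0
    env = _envelope(t, genotype.transient_hours, genotype.damping_rate)
    signal = env * (genotype.mesor + amplitude * np.cos(_phase(t, genotype, protocol)))
    noise = rng.normal(0.0, genotype.noise_sd, size=t.size) if genotype.noise_sd > 0 else 0.0
    trace = TraceSeries(
        well_id=well_id,
        strain=genotype.label,
        times=t,
        values=signal + noise,
        zt_offset=protocol.record_start_zt,
        entrained_until=protocol.release_hour,
    )
    return trace, rhythmic


def generate_plate(
    genotypes: list[tuple[GenotypeSpec, int]],
    protocol: ProtocolSchedule | None = None,
    seed: int = 0,
) -> SynthPlate:
    """Generate a plate: ``genotypes`` is a list of (spec, n_wells) pairs.

    Per-well random streams are spawned deterministically from the plate seed
    (numpy SeedSequence spawn keys = well index), so wells are independent yet
    the whole plate is reproducible from one integer.
    """
    if not genotypes or all(n <= 0 for _, n in genotypes):
        raise ValueError("at least one well must be requested")
    protocol = protocol or ProtocolSchedule()
    root = np.random.SeedSequence(seed)
    traces: list[TraceSeries] = []
    truth_rows = []
    well_index = 0
    for genotype, n_wells in genotypes:
        for _ in range(int(n_wells)):
            well_id = f"{genotype.label}-W{well_index:03d}"
            child = np.random.SeedSequence(entropy=seed, spawn_key=(well_index,))
            trace, rhythmic = generate_trace(genotype, protocol, child, well_id=well_id)
            traces.append(trace)
            truth_rows.append(
                {
                    "well": well_id,
                    "strain": genotype.label,
                    "rhythmic": rhythmic,
                    "period_freerun_h": genotype.period_freerun if rhythmic else np.nan,
                    "acrophase_zt": genotype.acrophase_zt if rhythmic else np.nan,
                }
            )
            well_index += 1
    recording = PlateRecording(
        traces=traces, meta={"seed": seed, "protocol": protocol, "synthetic": True}
    )
    return SynthPlate(recording=recording, truth=pd.DataFrame(truth_rows), seed=seed)


def qpcr_timepoints(
    start_zt: float = 1.0,
    interval: float = 4.0,
    n_days_entrained: int = 1,
    n_days_freerun: int = 2,
) -> np.ndarray:
    """Sampling grid for the qPCR time course: every 4 h from ZT1 over one
    entrained day plus two free-running days."""
    total = 24.0 * (n_days_entrained + n_days_freerun)
    return np.arange(start_zt, start_zt + total, interval)


def generate_ct_table(
    true_profile: np.ndarray,
    timepoints: np.ndarray | None = None,
    reference_ct: float = 20.0,
    target_offset_ct: float = 8.0,
    replicates: int = 4,
    noise_sd: float = 0.25,
    seed: int = 0,
    target_gene: str = "aha-1",
    reference_gene: str = "Y45F10D.4",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table under the perfect-doubling model.

    ``true_profile`` is the relative expression of the target at each
    timepoint (>0, arbitrary scale). Target Ct = reference_ct +
    target_offset_ct - log2(relative expression) + noise; reference-gene Ct =
    reference_ct + noise. Returns a long table with columns
    sample, timepoint_h, gene, ct.
    """
    true_profile = np.asarray(true_profile, dtype=float)
    if np.any(true_profile <= 0):
        raise ValueError("relative expression must be > 0 at every timepoint")
    if timepoints is None:
        timepoints = qpcr_timepoints()
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size != true_profile.size:
        raise ValueError("true_profile and timepoints must align")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for tp, rel in zip(timepoints, true_profile):
        for rep in range(int(replicates)):
            eps_t = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            eps_r = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": f"rep{rep + 1}",
                    "timepoint_h": tp,
                    "gene": target_gene,
                    "ct": reference_ct + target_offset_ct - np.log2(rel) + eps_t,
                }
            )
            rows.append(
                {
                    "sample": f"rep{rep + 1}",
                    "timepoint_h": tp,
                    "gene": reference_gene,
                    "ct": reference_ct + eps_r,
                }
            )
    return pd.DataFrame(rows)
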