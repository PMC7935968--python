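"""Synthetic closed-batch methanogenesis data: simulator and fixtures.

Every pipeline stage can be exercised without external data.  The simulator
integrates a minimal gas-limited growth model in a sealed headspace:

    dxi/dt = 0                                          (t < t_lag)
    dxi/dt = q_max * X * V_liquid * p_H2 / (K_p + p_H2) (t >= t_lag)
    dX/dt  = Y_x * (dxi/dt) / V_liquid

with xi the CH4 extent (mol), X the biomass concentration (g CDW / L),
q_max the specific methanogenesis rate, and a Monod dependence on the H2
partial pressure (a deliberate simplification: no gas-liquid transfer
resistance).  Headspace pressure follows the species balance and ideal gas
law — 4 moles of gas vanish per mole of CH4 — so the trace decays from p0
toward the CO2-limited residual (p0/5 for the 4:1 mixture), which is the
model's fixed point.  Recorded pressures carry i.i.d. Gaussian sensor
noise; all randomness flows from the seed.

Alongside the simulator live generators for cluster-structured screening
matrices (with missing-at-random masks and ground-truth labels) and gapped
MCR-alpha-like alignments with Y/F substitutions at reference positions
444/446, both fully label-annotated for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gas_model import (
    BAR_PER_PA,
    R_GAS,
    GasComposition,
    VesselSpec,
    max_extent_per_mole,
    moles_from_pressure,
    residual_pressure_full_conversion,
)
from .io_formats import ODSeries, PressureSeries
from .motif import GAP, MOTIF_POSITIONS, Alignment
from .screening import ScreeningMatrix

__all__ = [
    "SimParams",
    "SimTruth",
    "CycleTruth",
    "simulate_closed_batch",
    "simulate_rcb",
    "make_screening_matrix",
    "make_lowrank_matrix",
    "make_alignment",
]


def _default_vessel() -> VesselSpec:
    # 160 mL pressure vessel with 60 mL liquid at 65 degC
    return VesselSpec(v_total=0.160, v_liquid=0.060, t_incubation=338.15)


@dataclass(frozen=True)
class SimParams:
    """Closed-batch simulation parameters (defaults emulate a thermophilic
    hydrogenotroph converting 10 bar of 4:1 H2:CO2 in a 160 mL vessel).

    q_max      mmol CH4 (g CDW)^-1 h^-1 : specific methanogenesis rate
    k_p        bar  : Monod half-saturation on the H2 partial pressure
    x0         g CDW L^-1 : inoculum biomass concentration
    y_x        g CDW per mol CH4 : biomass yield on methane formed
    t_lag      h    : lag phase before conversion starts
    sigma_noise bar : sd of i.i.d. Gaussian sensor noise on recorded pressure
    dt_sim     h    : fixed RK4 integration step
    dt_record  h    : sampling interval of the recorded trace (5-min logs)
    od_per_gcdw     : OD578 units per g CDW L^-1
    """

    vessel: VesselSpec = field(default_factory=_default_vessel)
    composition: GasComposition = field(default_factory=GasComposition)
    p0: float = 10.0
    q_max: float = 60.0
    k_p: float = 0.5
    x0: float = 0.02
    y_x: float = 2.5
    t_lag: float = 5.0
    sigma_noise: float = 0.02
    dt_sim: float = 0.01
    dt_record: float = 1.0 / 12.0
    seed: int = 1
    od_per_gcdw: float = 2.5

    def __post_init__(self) -> None:
        for name in ("p0", "q_max", "k_p", "y_x", "dt_sim", "dt_record", "od_per_gcdw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("x0", "t_lag", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt_sim > self.dt_record:
            raise ValueError("dt_sim must not exceed dt_record")


@dataclass
class SimTruth:
    """Noise-free ground truth of one simulated conversion run."""

    times: np.ndarray  # recording grid, h
    pressure_true: np.ndarray  # bar, noise-free
    xi: np.ndarray  # mol CH4
    biomass: np.ndarray  # g CDW L^-1
    mer_true: np.ndarray  # mmol L^-1 h^-1
    mer_max: float
    t_mer_max: float
    k_min: float  # bar h^-1
    t_k_min: float
    time_to_full_conversion: float | None
    xi_final: float


@dataclass
class CycleTruth:
    index: int
    start: float
    end: float
    start_sample: int
    mer_max: float
    xi_formed: float


def _derivatives(
    xi: float, x_conc: float, t: float, params: SimParams, n0: float
) -> tuple[float, float]:
    if t < params.t_lag:
        return 0.0, 0.0
    v_gas_m3 = params.vessel.v_gas * 1e-3
    n_h2 = max(n0 * params.composition.x_h2 - 4.0 * xi, 0.0)
    p_h2 = n_h2 * R_GAS * params.vessel.t_incubation / v_gas_m3 * BAR_PER_PA
    dxi = params.q_max * 1e-3 * x_conc * params.vessel.v_liquid * p_h2 / (params.k_p + p_h2)
    dx = params.y_x * dxi / params.vessel.v_liquid
    return dxi, dx


def _rk4_step(
    xi: float, x_conc: float, t: float, dt: float, params: SimParams, n0: float
) -> tuple[float, float]:
    k1 = _derivatives(xi, x_conc, t, params, n0)
    k2 = _derivatives(xi + 0.5 * dt * k1[0], x_conc + 0.5 * dt * k1[1], t + 0.5 * dt, params, n0)
    k3 = _derivatives(xi + 0.5 * dt * k2[0], x_conc + 0.5 * dt * k2[1], t + 0.5 * dt, params, n0)
    k4 = _derivatives(xi + dt * k3[0], x_conc + dt * k3[1], t + dt, params, n0)
    xi_new = xi + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    x_new = x_conc + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return xi_new, x_new


def _pressure_of(xi: float, params: SimParams, n0: float) -> float:
    v_gas_m3 = params.vessel.v_gas * 1e-3
    n = n0 - 4.0 * xi
    return n * R_GAS * params.vessel.t_incubation / v_gas_m3 * BAR_PER_PA


def _integrate(
    params: SimParams,
    duration: float,
    xi0: float,
    x0: float,
    t0: float,
    n0: float,
    error_check: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4 over [t0, t0+duration]; returns fine-grid t, xi, X."""
    n_steps = int(round(duration / params.dt_sim))
    t = t0 + params.dt_sim * np.arange(n_steps + 1)
    xi = np.empty(n_steps + 1)
    x = np.empty(n_steps + 1)
    xi[0], x[0] = xi0, x0
    xi_max = max_extent_per_mole(params.composition) * n0
    v_gas_m3 = params.vessel.v_gas * 1e-3
    p_per_mol = R_GAS * params.vessel.t_incubation / v_gas_m3 * BAR_PER_PA
    for i in range(n_steps):
        xi[i + 1], x[i + 1] = _rk4_step(xi[i], x[i], t[i], params.dt_sim, params, n0)
        if error_check and i % 100 == 0:
            # step-doubling local error estimate, expressed in pressure units
            h1, hx1 = _rk4_step(xi[i], x[i], t[i], 0.5 * params.dt_sim, params, n0)
            h2, _ = _rk4_step(h1, hx1, t[i] + 0.5 * params.dt_sim, 0.5 * params.dt_sim, params, n0)
            err_bar = abs(xi[i + 1] - h2) * 4.0 * p_per_mol
            if err_bar > 1e-6:
                raise RuntimeError(
                    f"RK4 step error {err_bar:.2e} bar exceeds 1e-6 at dt_sim="
                    f"{params.dt_sim}; reduce dt_sim"
                )
        xi[i + 1] = min(xi[i + 1], xi_max)
    return t, xi, x


def _truth_from_fine(
    params: SimParams,
    t_fine: np.ndarray,
    xi_fine: np.ndarray,
    x_fine: np.ndarray,
    n0: float,
    full_conversion_tol: float = 0.02,
) -> SimTruth:
    stride = max(int(round(params.dt_record / params.dt_sim)), 1)
    t = t_fine[::stride]
    xi = xi_fine[::stride]
    x = x_fine[::stride]
    p_true = np.array([_pressure_of(v, params, n0) for v in xi])
    dxi_dt = np.array(
        [_derivatives(v, xc, tt, params, n0)[0] for v, xc, tt in zip(xi, x, t)]
    )
    mer_true = dxi_dt / params.vessel.v_liquid * 1e3
    i_peak = int(np.argmax(mer_true))
    v_gas_m3 = params.vessel.v_gas * 1e-3
    dpdt_true = -4.0 * dxi_dt * R_GAS * params.vessel.t_incubation / v_gas_m3 * BAR_PER_PA
    i_kmin = int(np.argmin(dpdt_true))
    p_res = residual_pressure_full_conversion(p_true[0], params.composition)
    reached = p_true <= p_res * (1.0 + full_conversion_tol)
    ttfc = float(t[int(np.argmax(reached))] - t[0]) if reached.any() else None
    return SimTruth(
        times=t,
        pressure_true=p_true,
        xi=xi,
        biomass=x,
        mer_true=mer_true,
        mer_max=float(mer_true[i_peak]),
        t_mer_max=float(t[i_peak]),
        k_min=float(dpdt_true[i_kmin]),
        t_k_min=float(t[i_kmin]),
        time_to_full_conversion=ttfc,
        xi_final=float(xi[-1]),
    )


def simulate_closed_batch(
    params: SimParams, duration: float = 48.0, vessel_id: str = "R1"
) -> tuple[PressureSeries, ODSeries, SimTruth]:
    """Simulate one closed-batch conversion and its recorded traces.

    Returns the noisy recorded pressure trace, the OD trace and the
    noise-free truth record (true MER curve, extrema, conversion time).
    """
    rng = np.random.default_rng(params.seed)
    n0 = moles_from_pressure(params.p0, params.vessel, params.vessel.t_incubation)
    t_fine, xi_fine, x_fine = _integrate(params, duration, 0.0, params.x0, 0.0, n0)
    truth = _truth_from_fine(params, t_fine, xi_fine, x_fine, n0)
    noise = rng.normal(0.0, params.sigma_noise, size=truth.times.size)
    pressures = truth.pressure_true + noise
    series = PressureSeries(vessel_id, truth.times, pressures, vessel=params.vessel)
    od = ODSeries(vessel_id, truth.times, truth.biomass * params.od_per_gcdw)
    return series, od, truth


def simulate_rcb(
    params: SimParams,
    n_cycles: int = 4,
    full_conversion_tol: float = 0.005,
    max_cycle_duration: float = 200.0,
    vessel_id: str = "R1",
) -> tuple[PressureSeries, list[CycleTruth]]:
    """Simulate a repetitive-closed-batch run with biomass carried over.

    Each cycle integrates until the pressure reaches the full-conversion
    residual within ``full_conversion_tol``, then the headspace is released
    and repressurized to p0 while the culture keeps its biomass.  The
    trigger is deliberately tighter than the 2% analysis tolerance —
    repressurization happens only once conversion is essentially complete,
    so downstream verdicts are not decided by sensor noise.  Returns the
    concatenated recorded trace and per-cycle ground truth (boundaries,
    peak MER, CH4 formed).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(params.seed)
    n0 = moles_from_pressure(params.p0, params.vessel, params.vessel.t_incubation)
    p_res = residual_pressure_full_conversion(params.p0, params.composition)

    all_t: list[np.ndarray] = []
    all_p: list[np.ndarray] = []
    truths: list[CycleTruth] = []
    x_now = params.x0
    t_now = 0.0
    sample_count = 0
    for c in range(1, n_cycles + 1):
        cycle_params = params if c == 1 else replace(params, t_lag=0.0)
        t_fine, xi_fine, x_fine = _integrate(
            cycle_params, max_cycle_duration, 0.0, x_now, t_now, n0
        )
        p_fine = np.array([_pressure_of(v, cycle_params, n0) for v in xi_fine])
        done = p_fine <= p_res * (1.0 + full_conversion_tol)
        i_stop = int(np.argmax(done)) if done.any() else len(t_fine) - 1
        stride = max(int(round(params.dt_record / params.dt_sim)), 1)
        keep = np.arange(0, i_stop + 1, stride)
        if keep[-1] != i_stop:  # always record the conversion endpoint
            keep = np.append(keep, i_stop)
        t_rec = t_fine[keep]
        xi_rec = xi_fine[keep]
        x_rec = x_fine[keep]
        p_rec = p_fine[keep]
        dxi = np.array(
            [_derivatives(v, xc, tt, cycle_params, n0)[0] for v, xc, tt in zip(xi_rec, x_rec, t_rec)]
        )
        mer = dxi / params.vessel.v_liquid * 1e3
        truths.append(
            CycleTruth(
                index=c,
                start=float(t_rec[0]),
                end=float(t_rec[-1]),
                start_sample=sample_count,
                mer_max=float(mer.max()),
                xi_formed=float(xi_rec[-1]),
            )
        )
        all_t.append(t_rec)
        all_p.append(p_rec)
        sample_count += t_rec.size
        x_now = float(x_fine[i_stop])
        t_now = float(t_fine[i_stop]) + params.dt_record

    times = np.concatenate(all_t)
    p_true = np.concatenate(all_p)
    pressures = p_true + rng.normal(0.0, params.sigma_noise, size=times.size)
    series = PressureSeries(vessel_id, times, pressures, vessel=params.vessel)
    return series, truths


def make_screening_matrix(
    n_per_cluster: int = 20,
    k: int = 2,
    n_variables: int = 9,
    separation: float = 5.0,
    noise_sd: float = 1.0,
    missing_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[ScreeningMatrix, np.ndarray]:
    """Cluster-structured strains x variables matrix with a MAR missing mask.

    ``separation`` is the per-variable centroid spacing in noise-sd units:
    cluster centroids lie on a line through variable space (a random sign
    pattern), with the two extreme clusters ``separation`` noise-sd apart
    in every variable — emulating screening responses that co-vary along a
    dominant nutrient axis.  Returns the matrix (NaN-masked) and the true
    labels.
    """
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pattern = rng.choice([-1.0, 1.0], size=n_variables)
    spacing = np.linspace(-0.5, 0.5, k) if k > 1 else np.zeros(1)
    centroids = np.outer(spacing, pattern) * separation * noise_sd
    labels = np.repeat(np.arange(k), n_per_cluster)
    x = centroids[labels] + rng.normal(0.0, noise_sd, size=(k * n_per_cluster, n_variables))
    mask = rng.random(x.shape) < missing_fraction
    # keep at least one observed value per row and column
    for i in range(x.shape[0]):
        if mask[i].all():
            mask[i, rng.integers(x.shape[1])] = False
    for j in range(x.shape[1]):
        if mask[:, j].all():
            mask[rng.integers(x.shape[0]), j] = False
    x_masked = x.copy()
    x_masked[mask] = np.nan
    names = [
        "od_max", "turnover_max", "mer_max", "salt", "sulfate",
        "sulfur", "ammonium", "phosphate", "cysteine",
    ][:n_variables]
    names += [f"var_{j}" for j in range(len(names), n_variables)]
    data = pd.DataFrame(x_masked, columns=names)
    meta = pd.DataFrame(
        {
            "taxonomy": [f"clade_{lab}" for lab in labels],
            "temperature_group": rng.choice(
                ["mesophile", "thermophile", "hyperthermophile"], size=labels.size
            ),
        }
    )
    return ScreeningMatrix(data, meta), labels


def make_lowrank_matrix(
    n_rows: int = 30,
    n_cols: int = 8,
    rank: int = 2,
    missing_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[ScreeningMatrix, np.ndarray]:
    """Exact rank-``rank`` matrix with missing entries; returns (matrix, truth)."""
    rng = np.random.default_rng(seed)
    full = rng.normal(size=(n_rows, rank)) @ rng.normal(size=(rank, n_cols))
    mask = rng.random(full.shape) < missing_fraction
    for j in range(n_cols):
        if mask[:, j].all():
            mask[rng.integers(n_rows), j] = False
    x = full.copy()
    x[mask] = np.nan
    data = pd.DataFrame(x, columns=[f"v{j}" for j in range(n_cols)])
    return ScreeningMatrix(data), full


_MOTIF_BY_LABEL = {
    "YGY": "YGY",
    "FGY": "FGY",
    "YGF": "YGF",
    "FGF": "FGF",
    "other/gapped": "Y-Y",  # gap at the glycine position
}


def make_alignment(
    label_counts: dict[str, int] | None = None,
    length: int = 520,
    gap_rate: float = 0.02,
    n_insert_columns: int = 5,
    reference_id: str = "ref_mcrA_alpha",
    seed: int = 0,
) -> tuple[Alignment, dict[str, str]]:
    """Gapped MCR-alpha-like alignment with known motif labels per sequence.

    The reference carries Tyr-Gly-Tyr at residues 444-446; each variant gets
    the motif dictated by its label, random deletions (gaps) elsewhere at
    ``gap_rate``, and ``n_insert_columns`` alignment columns that are gaps
    in the reference.  Returns the alignment and {seq_id: true label}.
    """
    if label_counts is None:
        label_counts = {"YGY": 6, "FGY": 3, "YGF": 2, "FGF": 1, "other/gapped": 2}
    unknown = set(label_counts) - set(_MOTIF_BY_LABEL)
    if unknown:
        raise ValueError(f"unknown motif labels {unknown}")
    if length < MOTIF_POSITIONS[-1] + 10:
        raise ValueError(f"length must exceed {MOTIF_POSITIONS[-1] + 10}")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVW"))  # no Y: motif sites set explicitly
    ref = rng.choice(alphabet, size=length)
    motif_cols0 = [p - 1 for p in MOTIF_POSITIONS]
    ref[motif_cols0] = list("YGY")
    ref_seq = "".join(ref)

    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    i = 0
    for label, count in sorted(label_counts.items()):
        for _ in range(count):
            i += 1
            seq = list(ref_seq)
            for col, ch in zip(motif_cols0, _MOTIF_BY_LABEL[label]):
                seq[col] = ch
            for col in range(length):
                if col not in motif_cols0 and rng.random() < gap_rate:
                    seq[col] = GAP
            seq_id = f"seq_{i:03d}_{label.replace('/', '_')}"
            records.append((seq_id, "".join(seq)))
            truth[seq_id] = label

    # insertion columns: gap in the reference, residues in some variants
    ref_list = list(ref_seq)
    insert_at = sorted(rng.integers(0, length, size=n_insert_columns).tolist(), reverse=True)
    for pos in insert_at:
        ref_list.insert(pos, GAP)
        for idx, (seq_id, seq) in enumerate(records):
            chars = list(seq)
            fill = str(rng.choice(alphabet)) if rng.random() < 0.5 else GAP
            chars.insert(pos, fill)
            records[idx] = (seq_id, "".join(chars))
    records.insert(0, (reference_id, "".join(ref_list)))
    truth[reference_id] = "YGY"
    return Alignment(records, reference_id), truth

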