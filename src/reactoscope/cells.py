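"""Ground-truth cell biology for the virtual microscope.

Light-driven gene expression with a deterministic maturation delay, exact
stochastic (birth-death) and deterministic ("average cell") variants, simple
monolayer population dynamics (exponential growth, division with binomial
protein partitioning, centroid jitter with overlap relaxation), exponential
membrane-dye decay, and light-driven Cre-lox style recombination with a
slow-growth phenotype.

The expression model is a one-stage birth-death process with delayed input:

    production rate  b0 + k * u(t - tau)
    degradation rate gamma * n

where ``u`` is the binary light activation per measurement interval and
``tau`` is the fluorophore maturation delay (minutes). A 1000 ms pulse within
a 6 min interval is mapped to full activation (u = 1) for that interval,
reflecting the fast photo-switching of the EL222 transcription factor
relative to the imaging cadence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeneExpressionParams",
    "LightProfile",
    "CellTruth",
    "RecombinationParams",
    "PopulationParams",
    "simulate_deterministic",
    "simulate_ssa",
    "step_population",
    "apply_recombination",
]


@dataclass(frozen=True)
class GeneExpressionParams:
    """Parameters of the delayed birth-death expression model.

    Attributes
    ----------
    k : float
        Maximal light-induced production rate (molecules/min).
    b0 : float
        Basal production rate (molecules/min).
    gamma : float
        Degradation + dilution rate (1/min). Default ln(2)/90, matching a
        90 min effective half-life set by dilution at the cell generation
        time.
    tau : float
        Deterministic delay between light application and effective protein
        production (min); dominated by fluorophore maturation. Default 36.
    alpha : float
        Fluorescence units per molecule.
    sigma_meas : float
        Gaussian measurement noise SD (fluorescence units).
    """

    k: float = 20.0
    b0: float = 0.5
    gamma: float = math.log(2) / 90.0
    tau: float = 36.0
    alpha: float = 1.0
    sigma_meas: float = 50.0

    def __post_init__(self) -> None:
        if self.k < 0 or self.b0 < 0:
            raise ValueError("production rates must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class LightProfile:
    """Binary light stimulation plan on the fluorescence-frame cadence.

    ``pulses[i]`` says whether a pulse of ``pulse_ms`` is applied in interval
    ``[i*step_min, (i+1)*step_min)``. Activation is binary per interval.
    """

    pulses: tuple
    step_min: float = 6.0
    pulse_ms: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(bool(p) for p in self.pulses))
        if self.step_min <= 0:
            raise ValueError("step_min must be > 0")

    def activation(self, t_min: float) -> float:
        """Binary activation u(t): 1 while the interval containing t is pulsed."""
        if t_min < 0:
            return 0.0
        i = int(t_min // self.step_min)
        if i >= len(self.pulses):
            return 0.0
        return 1.0 if self.pulses[i] else 0.0

    @property
    def horizon_min(self) -> float:
        return len(self.pulses) * self.step_min


@dataclass
class CellTruth:
    """Ground-truth simulated cell (geometry, molecular state, lineage)."""

    id: int
    centroid: tuple  # (row, col) px
    semi_axes: tuple  # (a, b) px
    orientation: float = 0.0  # rad
    parent_id: int | None = None
    protein_count: float = 0.0
    dye_level: float = 0.0
    reporter_level: float = 0.0  # recombination reporter fluorescence signal
    light_history: list = field(default_factory=list)  # (time_min, dose)
    recombined: bool = False
    recombination_time: float | None = None
    growth_rate: float = math.log(2) / 90.0  # 1/min

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass(frozen=True)
class RecombinationParams:
    """Light-driven recombination and its growth-arrest phenotype."""

    p_rec: float = 0.9  # per-stimulation recombination prob. at dose >= threshold
    p_spont: float = 0.0  # spontaneous recombination prob. per frame
    dose_threshold: float = 100.0  # ms-equivalent dose
    reporter_delay: float = 36.0  # min between recombination and reporter rise
    reporter_plateau: float = 100.0  # reporter signal at full expression
    reporter_ramp_min: float = 60.0  # min to ramp from 0 to plateau
    growth_factor_post: float = 0.3  # growth-rate multiplier after recombination

    def __post_init__(self) -> None:
        for p in (self.p_rec, self.p_spont):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationParams:
    """Monolayer population dynamics knobs (growth, division, motion)."""

    division_area: float = 220.0  # px^2 threshold for division
    jitter_px: float = 0.3  # SD of per-step centroid jitter
    dye_decay_rate: float = math.log(2) / 180.0  # 1/min; ~3 h half-life
    relax_iters: int = 12  # overlap-relaxation sweeps per step
    deterministic_partition: bool = False  # halve protein instead of binomial


def _interval_rate(params: GeneExpressionParams, light: LightProfile, t: float) -> float:
    """Birth propensity at time t, honoring the input delay."""
    u = light.activation(t - params.tau) if t >= params.tau else 0.0
    return params.b0 + params.k * u


def simulate_deterministic(
    params: GeneExpressionParams,
    light: LightProfile,
    horizon_min: float,
    dt_min: float = 1.0,
    p0: float = 0.0,
):
    """Integrate dP/dt = b0 + k*u(t - tau) - gamma*P exactly per dt step.

    ``u`` is piecewise constant on the light-profile grid, so each dt step
    (dt must divide step_min) has constant input and the linear ODE is
    advanced with its exact exponential solution.

    Returns (times, P) with times = 0, dt, ..., horizon_min.
    """
    if p0 < 0:
        raise ValueError("p0 must be >= 0")
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    n_sub = light.step_min / dt_min
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError("dt_min must divide the light profile step")
    n_steps = int(round(horizon_min / dt_min))
    times = np.arange(n_steps + 1) * dt_min
    out = np.empty(n_steps + 1)
    out[0] = p0
    g = params.gamma
    decay = math.exp(-g * dt_min)
    p = p0
    for i in range(n_steps):
        rate = _interval_rate(params, light, times[i])
        p = p * decay + (rate / g) * (1.0 - decay)
        out[i + 1] = p
    return times, out


def simulate_ssa(
    params: GeneExpressionParams,
    light: LightProfile,
    horizon_min: float,
    rng: np.random.Generator,
    n0: int = 0,
    sample_times: np.ndarray | None = None,
):
    """Exact stochastic simulation of the delayed birth-death process.

    Propensities are piecewise constant between light-grid boundaries, so a
    plain Gillespie algorithm is run within each constant-rate segment.

    Returns the protein count sampled at ``sample_times`` (default: every
    light step, including t=0 and horizon).
    """
    if n0 < 0 or int(n0) != n0:
        raise ValueError("initial count must be a nonnegative integer")
    if sample_times is None:
        sample_times = np.arange(0.0, horizon_min + 1e-9, light.step_min)
    sample_times = np.asarray(sample_times, dtype=float)
    counts = np.empty(len(sample_times), dtype=np.int64)
    n = int(n0)
    t = 0.0
    si = 0
    # segment boundaries where the birth propensity may change
    step = light.step_min
    while si < len(sample_times) and sample_times[si] <= t + 1e-12:
        counts[si] = n
        si += 1
    while t < horizon_min and si < len(sample_times):
        seg_end = min(horizon_min, (math.floor(t / step + 1e-12) + 1) * step)
        birth = _interval_rate(params, light, t)
        while True:
            total = birth + params.gamma * n
            if total <= 0:
                t = seg_end
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= seg_end:
                t = seg_end
                break
            t += dt
            if rng.random() < birth / total:
                n += 1
            else:
                n -= 1
            while si < len(sample_times) and sample_times[si] <= t:
                counts[si] = n
                si += 1
        while si < len(sample_times) and sample_times[si] <= t + 1e-9:
            counts[si] = n
            si += 1
    counts[si:] = n
    return sample_times, counts


def _split_cell(cell: CellTruth, next_id: int, rng: np.random.Generator,
                pop: PopulationParams) -> tuple[CellTruth, CellTruth]:
    """Divide a cell along its major axis; protein partitioned binomially."""
    a, b = cell.semi_axes
    theta = cell.orientation
    offset = a * 0.6
    dr = offset * math.sin(theta), offset * math.cos(theta)
    # daughters: each exactly half the area (shape preserved)
    geom = (a / math.sqrt(2.0), b / math.sqrt(2.0))
    n = cell.protein_count
    if pop.deterministic_partition:
        n1 = n / 2.0
    else:
        n1 = float(rng.binomial(int(round(n)), 0.5))
    n2 = n - n1
    d1 = replace_cell(cell, centroid=(cell.centroid[0] - dr[0], cell.centroid[1] - dr[1]),
                      semi_axes=geom, protein_count=n1)
    d2 = replace_cell(cell, centroid=(cell.centroid[0] + dr[0], cell.centroid[1] + dr[1]),
                      semi_axes=geom, protein_count=n2)
    d2.id = next_id
    d2.parent_id = cell.id
    d2.orientation = float(cell.orientation + rng.normal(0.0, 0.3))
    d2.light_history = []
    return d1, d2


def replace_cell(cell: CellTruth, **kw) -> CellTruth:
    """Shallow-copy a cell with selected fields replaced."""
    out = CellTruth(
        id=cell.id, parent_id=cell.parent_id, centroid=cell.centroid,
        semi_axes=cell.semi_axes, orientation=cell.orientation,
        protein_count=cell.protein_count, dye_level=cell.dye_level,
        reporter_level=cell.reporter_level,
        light_history=list(cell.light_history), recombined=cell.recombined,
        recombination_time=cell.recombination_time, growth_rate=cell.growth_rate,
    )
    for key, val in kw.items():
        setattr(out, key, val)
    return out


def _relax_overlaps(cells: list[CellTruth], iters: int) -> None:
    """Push overlapping cells apart (circle approximation on mean radius)."""
    for _ in range(iters):
        moved = False
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                ci, cj = cells[i], cells[j]
                ri = math.sqrt(ci.semi_axes[0] * ci.semi_axes[1])
                rj = math.sqrt(cj.semi_axes[0] * cj.semi_axes[1])
                dy = cj.centroid[0] - ci.centroid[0]
                dx = cj.centroid[1] - ci.centroid[1]
                d = math.hypot(dy, dx)
                target = 0.9 * (ri + rj)
                if d < target:
                    moved = True
                    if d < 1e-6:
                        dy, dx, d = 1.0, 0.0, 1.0
                    push = 0.5 * (target - d)
                    uy, ux = dy / d, dx / d
                    cells[i].centroid = (ci.centroid[0] - uy * push,
                                         ci.centroid[1] - ux * push)
                    cells[j].centroid = (cj.centroid[0] + uy * push,
                                         cj.centroid[1] + ux * push)
        if not moved:
            break


def step_population(
    population: list[CellTruth],
    dt_min: float,
    rng: np.random.Generator,
    pop_params: PopulationParams = PopulationParams(),
) -> list[CellTruth]:
    """Advance population geometry by one step.

    Areas grow exponentially at each cell's growth rate; cells above the
    division threshold split with protein conserved; centroids jitter and
    overlaps are relaxed; dye decays exponentially.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    out: list[CellTruth] = []
    next_id = max((c.id for c in population), default=-1) + 1
    dye_f = math.exp(-pop_params.dye_decay_rate * dt_min)
    for cell in population:
        growth = math.exp(cell.growth_rate * dt_min)
        scale = math.sqrt(growth)  # area grows by `growth`
        c = replace_cell(cell, semi_axes=(cell.semi_axes[0] * scale,
                                          cell.semi_axes[1] * scale),
                         dye_level=cell.dye_level * dye_f)
        if pop_params.jitter_px > 0:
            jr, jc = rng.normal(0.0, pop_params.jitter_px, size=2)
            c.centroid = (c.centroid[0] + jr, c.centroid[1] + jc)
        if c.area >= pop_params.division_area:
            d1, d2 = _split_cell(c, next_id, rng, pop_params)
            next_id += 1
            out.extend([d1, d2])
        else:
            out.append(c)
    if pop_params.jitter_px > 0 or len(out) > len(population):
        _relax_overlaps(out, pop_params.relax_iters)
    return out


def apply_recombination(
    cell: CellTruth,
    dose: float,
    params: RecombinationParams,
    rng: np.random.Generator,
    t_min: float,
) -> CellTruth:
    """Stochastic recombination decision for one cell at one stimulation tick.

    A stimulated cell (dose >= dose_threshold) recombines with probability
    ``p_rec``; an unstimulated cell recombines spontaneously with ``p_spont``.
    Recombination is irreversible; the growth-arrest phenotype and reporter
    ramp are applied by :func:`update_phenotype` as time advances.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if cell.recombined:
        return cell
    if dose >= params.dose_threshold:
        p = params.p_rec
    else:
        p = params.p_spont
    if p > 0 and rng.random() < p:
        cell = replace_cell(cell, recombined=True, recombination_time=t_min)
    return cell


def update_phenotype(cell: CellTruth, t_min: float,
                     params: RecombinationParams) -> CellTruth:
    """Express the recombined phenotype: reporter ramp and slowed growth.

    After ``recombination_time + reporter_delay`` the reporter signal ramps
    linearly to its plateau over ``reporter_ramp_min`` and the growth rate is
    multiplied by ``growth_factor_post``.
    """
    if not cell.recombined or cell.recombination_time is None:
        return cell
    t_on = cell.recombination_time + params.reporter_delay
    base_growth = cell.growth_rate
    if t_min >= t_on:
        frac = min(1.0, (t_min - t_on) / max(params.reporter_ramp_min, 1e-9))
        reporter = frac * params.reporter_plateau
        # apply growth arrest once
        if cell.reporter_level == 0.0 and reporter > 0.0:
            base_growth = cell.growth_rate * params.growth_factor_post
        return replace_cell(cell, reporter_level=reporter, growth_rate=base_growth)
    return cell
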