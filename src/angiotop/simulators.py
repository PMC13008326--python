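"""Snail-trail angiogenesis simulators: Anderson--Chaplain (AC),
Stokes--Lauffenburger (SL) and Plank--Sleeman (PS).

All three models track tip endothelial cells (ECs) migrating in the square
domain of :class:`~angiotop.domain.DomainConfig`, leaving a contiguous trail
of stalk ECs behind them (the snail-trail assumption).  VEGF increases
towards the tumour at the top; tips are seeded evenly along the bottom edge.

Movement rules differ per model:

* **AC** — biased random walk on the lattice.  Each step a tip makes one of
  five moves (stay, +-x, +-y) with probabilities proportional to
  non-negative weights ``D + chi(c) * dc/h + rho * df/h`` (clamped at zero
  and renormalized), so chemotaxis ``chi`` biases moves up the VEGF gradient
  and haptotaxis ``rho`` up the fibronectin gradient.  Fibronectin is
  produced and degraded by the ECs themselves (toggleable to static).
* **SL** — off-lattice Ornstein--Uhlenbeck velocity:
  ``dw = (-beta w + kappa grad c) dt + sigma dW`` (Euler--Maruyama), position
  advanced by ``w dt``.
* **PS** — constant speed, discrete headings ``k * phi_hat`` measured from
  the vertical.  Per step the heading turns by ``+-phi_hat`` with rates
  ``tau+- = (Dr dt / 2) exp(-dc * (a(theta') - a(theta)) / phi_hat)`` where
  ``a`` is the angular distance to the local VEGF-gradient direction, so
  ``dc > 0`` favours the turn that re-orients the tip towards the tumour and
  ``Dr`` sets the overall turning rate.

Shared rules: a tip branches (spawning an independent daughter, both ages
reset) when its age exceeds ``abr`` *and* local VEGF exceeds ``cbr``, with a
configurable per-step firing probability; a tip fuses and deactivates
(anastomosis) when its trail enters a lattice cell already laid by a
different tip lineage; side and bottom walls reflect, the top edge absorbs
(the tip has reached the tumour).

All randomness is drawn from a single seeded ``numpy`` generator in a fixed
per-step order (movement draws, then branching draws), which makes
simulations bit-reproducible from ``(model_id, params, config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .domain import DomainConfig, EnvironmentFields, make_environment
from .grid import supercover_cells
from .models import ModelParams

__all__ = [
    "SimulatorSettings",
    "TipCell",
    "SimulationResult",
    "SimulationError",
    "simulate",
    "ac_move_probabilities",
    "sl_velocity_step",
    "ps_turn_step",
    "branch_check",
    "anastomosis_check",
]


class SimulationError(RuntimeError):
    """Raised when a simulation produces invalid state (e.g. non-finite
    velocities); the message names the seed and timestep."""


@dataclass(frozen=True)
class SimulatorSettings:
    """Nuisance coefficients of the three models (not inferred).

    Every coefficient of the published model forms that is not one of the
    four inferred parameters is surfaced here.
    """

    vegf_profile: str = "linear"
    vegf_decay: float = 3.0              # exponential profile only
    fibronectin_slope: float = 0.4       # initial fibronectin drop bottom->top
    fibronectin_dynamic: bool = True     # ECs produce/degrade fibronectin (AC)
    fibro_production: float = 0.05       # per unit time at occupied sites
    fibro_degradation: float = 0.1
    ac_diffusion: float = 1.0            # baseline (unbiased) move weight D
    ac_stay_weight: float = 1.0          # weight of the stay move
    ac_alpha: float = 0.0                # chi(c) = chi / (1 + alpha c); 0 = constant
    sl_drag: float = 1.0                 # OU relaxation rate beta
    sl_init_speed: float = 0.1           # initial upward speed of SL tips
    ps_half_turns: int = 6               # phi_hat = pi / ps_half_turns
    ps_speed: Optional[float] = None     # constant PS speed; None -> 1.25 L / T
    branch_probability: float = 1.0      # Bernoulli rate once the gate is open
    max_tips: int = 512                  # hard cap on simultaneous tips

    @property
    def phi_hat(self) -> float:
        return math.pi / self.ps_half_turns

    def ps_speed_for(self, config: DomainConfig) -> float:
        if self.ps_speed is not None:
            return self.ps_speed
        return 1.25 * config.side_length / (config.n_timesteps * config.dt)


@dataclass
class TipCell:
    """State of a single tip EC (used by the single-tip step operations)."""

    position: np.ndarray                 # (2,) domain coordinates / lattice ij
    velocity: Optional[np.ndarray] = None  # SL only
    heading: int = 0                     # PS only: heading index k (angle k*phi_hat)
    age: float = 0.0
    active: bool = True
    lineage: int = 0


@dataclass
class SimulationResult:
    """Final-timestep record of one simulation."""

    model_id: str
    params: ModelParams
    config: DomainConfig
    settings: SimulatorSettings
    seed: int
    trail_sites: Optional[np.ndarray]           # AC: (m, 2) lattice site indices
    polylines: Optional[List[np.ndarray]]       # SL/PS: per-tip (k, 2) paths
    trail_cells: np.ndarray = field(repr=False)  # (m, 3) ix, iy, lineage at lattice res
    tip_start: List[int] = field(default_factory=list, repr=False)
    n_tips_final: int = 0
    n_tips_total: int = 0
    n_anastomoses: int = 0
    n_branches: int = 0

    def trail_frame(self) -> pd.DataFrame:
        """Trail points as a table (x, y, tip_lineage_id, t_laid)."""
        rows = []
        if self.polylines is not None:
            for lin, (line, t0) in enumerate(zip(self.polylines, self.tip_start)):
                for k, (x, y) in enumerate(np.asarray(line)):
                    rows.append((x, y, lin, (t0 + k) * self.config.dt))
        else:
            h = self.config.h
            for ix, iy, lin in self.trail_cells:
                rows.append((ix * h, iy * h, lin, np.nan))
        return pd.DataFrame(rows, columns=["x", "y", "tip_lineage_id", "t_laid"])


# ---------------------------------------------------------------------------
# movement kernels


def _ac_weights(
    sites: np.ndarray,
    env: EnvironmentFields,
    chi: float,
    rho: float,
    settings: SimulatorSettings,
) -> np.ndarray:
    """Unnormalized AC move weights, shape (n, 5): stay, +x, -x, +y, -y."""
    c, f = env.vegf, env.fibronectin
    r = env.config.lattice_resolution
    h = env.config.h
    ix, iy = sites[:, 0], sites[:, 1]
    c_s = c[ix, iy]
    f_s = f[ix, iy]
    chi_eff = chi / (1.0 + settings.ac_alpha * c_s)
    w = np.empty((len(sites), 5), dtype=float)
    w[:, 0] = settings.ac_stay_weight
    moves = ((1, 0), (-1, 0), (0, 1), (0, -1))
    for k, (dx, dy) in enumerate(moves, start=1):
        jx = ix + dx
        jy = iy + dy
        valid = (jx >= 0) & (jx < r) & (jy >= 0) & (jy < r)
        jxc = np.clip(jx, 0, r - 1)
        jyc = np.clip(jy, 0, r - 1)
        drift = (settings.ac_diffusion
                 + chi_eff * (c[jxc, jyc] - c_s) / h
                 + rho * (f[jxc, jyc] - f_s) / h)
        w[:, k] = np.where(valid, np.maximum(drift, 0.0), 0.0)
    return w


def ac_move_probabilities(
    tip: TipCell,
    fields: EnvironmentFields,
    params: ModelParams,
    config: DomainConfig,
    settings: SimulatorSettings = SimulatorSettings(),
) -> np.ndarray:
    """Probabilities (P0..P4) = (stay, +x, -x, +y, -y) for one AC tip.

    Weights toward higher VEGF exceed the opposite move whenever ``chi > 0``
    (and likewise ``rho`` for fibronectin); moves off the lattice get
    probability zero; negative weights are clamped to zero; the vector is
    renormalized to sum to one.  If every weight is zero the tip stays put
    (``P0 = 1``).
    """
    del config  # geometry comes with the fields
    site = np.asarray(tip.position, dtype=int).reshape(1, 2)
    w = _ac_weights(site, fields, params["chi"], params["rho"], settings)[0]
    total = w.sum()
    if total <= 0.0:
        p = np.zeros(5)
        p[0] = 1.0
        return p
    return w / total


def sl_velocity_step(
    tip: TipCell,
    fields: EnvironmentFields,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
    settings: SimulatorSettings = SimulatorSettings(),
) -> TipCell:
    """One Euler--Maruyama step of the SL velocity SDE for a single tip.

    ``w <- w + (-beta w + kappa grad c) dt + sigma sqrt(dt) xi`` with
    ``xi ~ N(0, I2)``; the position advances by ``w dt``.  Side and bottom
    walls reflect, the top edge absorbs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos = np.asarray(tip.position, dtype=float)
    vel = np.asarray(tip.velocity, dtype=float)
    grad = fields.vegf_gradient(pos[0], pos[1])
    noise = rng.standard_normal(2)
    vel = vel + dt * (-settings.sl_drag * vel + params["kappa"] * grad) \
        + params["sigma"] * math.sqrt(dt) * noise
    if not np.all(np.isfinite(vel)):
        raise SimulationError(
            f"non-finite SL velocity (lineage {tip.lineage})")
    pos = pos + vel * dt
    L = fields.config.side_length
    active = tip.active
    if pos[0] < 0:
        pos[0] = -pos[0]
        vel[0] = -vel[0]
    elif pos[0] > L:
        pos[0] = 2 * L - pos[0]
        vel[0] = -vel[0]
    if pos[1] < 0:
        pos[1] = -pos[1]
        vel[1] = -vel[1]
    elif pos[1] >= L:
        pos[1] = L
        active = False
    return replace(tip, position=pos, velocity=vel, active=active)


def _ps_turn_rates(
    heading: np.ndarray,
    grad: np.ndarray,
    dc: float,
    dr: float,
    dt: float,
    phi_hat: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Turning probabilities (tau+, tau-) for PS headings (vectorized).

    ``heading`` holds heading indices k (angle from vertical ``k * phi_hat``);
    ``grad`` is (n, 2) VEGF gradients.  Where the gradient vanishes the turn
    is unbiased.
    """
    theta = heading * phi_hat
    gnorm = np.hypot(grad[..., 0], grad[..., 1])
    target = np.where(gnorm > 0, np.arctan2(grad[..., 0], grad[..., 1]), 0.0)
    bias = np.where(gnorm > 0, dc, 0.0)

    def adist(angle: np.ndarray) -> np.ndarray:
        d = np.mod(angle - target + math.pi, 2 * math.pi) - math.pi
        return np.abs(d)

    a0 = adist(theta)
    tau_p = 0.5 * dr * dt * np.exp(-bias * (adist(theta + phi_hat) - a0) / phi_hat)
    tau_m = 0.5 * dr * dt * np.exp(-bias * (adist(theta - phi_hat) - a0) / phi_hat)
    return tau_p, tau_m


def ps_turn_step(
    tip: TipCell,
    fields: EnvironmentFields,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
    settings: SimulatorSettings = SimulatorSettings(),
) -> TipCell:
    """One PS step for a single tip: possibly turn by +-phi_hat, then advance.

    Speed is constant over the tip's lifetime.  Raises a configuration error
    if the turning probabilities could exceed one for this (Dr, dc, dt).
    """
    phi = settings.phi_hat
    dr, dc = params["dr"], params["dc"]
    if dr * dt * math.cosh(dc) > 1.0:
        raise ValueError(
            "ps turning probabilities tau+ + tau- can exceed 1 for this "
            f"(Dr={dr}, dc={dc}, dt={dt}); choose a smaller dt")
    pos = np.asarray(tip.position, dtype=float)
    grad = fields.vegf_gradient(pos[0], pos[1]).reshape(1, 2)
    tau_p, tau_m = _ps_turn_rates(np.array([tip.heading]), grad, dc, dr, dt, phi)
    u = rng.random()
    heading = tip.heading
    if u < tau_p[0]:
        heading += 1
    elif u < tau_p[0] + tau_m[0]:
        heading -= 1
    speed = settings.ps_speed_for(fields.config)
    theta = heading * phi
    pos = pos + speed * dt * np.array([math.sin(theta), math.cos(theta)])
    pos, heading, active = _ps_reflect(pos, heading, fields.config.side_length,
                                       settings.ps_half_turns, tip.active)
    return replace(tip, position=pos, heading=heading, active=active)


def _ps_reflect(pos, heading, L, half_turns, active):
    n_angles = 2 * half_turns
    if pos[0] < 0:
        pos[0] = -pos[0]
        heading = -heading
    elif pos[0] > L:
        pos[0] = 2 * L - pos[0]
        heading = -heading
    if pos[1] < 0:
        pos[1] = -pos[1]
        heading = half_turns - heading  # mirror about the horizontal
    elif pos[1] >= L:
        pos[1] = L
        active = False
    heading = (heading + half_turns) % n_angles - half_turns
    return pos, heading, active


def branch_check(
    tip: TipCell,
    fields: EnvironmentFields,
    params: ModelParams,
    rng: np.random.Generator,
    settings: SimulatorSettings = SimulatorSettings(),
    *,
    new_lineage: int = -1,
) -> Optional[TipCell]:
    """Return a daughter tip if the branching gate fires, else ``None``.

    A tip may bifurcate only when its age exceeds ``abr`` *and* the VEGF
    concentration at its location exceeds ``cbr``; eligibility then fires
    with probability ``settings.branch_probability``.  Both parent and
    daughter ages reset to zero (the caller resets the parent).  ``position``
    must be in domain coordinates (AC callers convert lattice sites).
    """
    if not tip.active:
        return None
    pos = np.asarray(tip.position, dtype=float)
    c_here = fields.vegf_at(float(pos[0]), float(pos[1]))
    if not (tip.age > params["abr"] and c_here > params["cbr"]):
        return None
    if rng.random() >= settings.branch_probability:
        return None
    daughter = replace(tip, age=0.0, lineage=new_lineage)
    if tip.velocity is not None:
        daughter = replace(daughter, velocity=np.array(
            [-tip.velocity[0], tip.velocity[1]]))
    else:
        daughter = replace(daughter, heading=-tip.heading)
    return daughter


def anastomosis_check(
    tip: TipCell,
    lineage_grid: np.ndarray,
    cells_entered: Set[Tuple[int, int]],
) -> bool:
    """True iff the tip's newly entered cells touch a foreign trail.

    ``lineage_grid`` maps lattice cells to the lineage that laid them (-1 for
    empty).  The fusing tip deactivates; callers record the loop.
    """
    for cx, cy in cells_entered:
        owner = lineage_grid[cx, cy]
        if owner >= 0 and owner != tip.lineage:
            return True
    return False


# ---------------------------------------------------------------------------
# full simulations


def _initial_x(config: DomainConfig) -> np.ndarray:
    n = config.n_initial_tips
    return (np.arange(n) + 0.5) / n * config.side_length


def _segment_cells(p0, p1, cs, r) -> Set[Tuple[int, int]]:
    """Cells along one short trail segment (fast path for sub-cell steps)."""
    c0 = (int(np.clip(p0[0] // cs, 0, r - 1)), int(np.clip(p0[1] // cs, 0, r - 1)))
    c1 = (int(np.clip(p1[0] // cs, 0, r - 1)), int(np.clip(p1[1] // cs, 0, r - 1)))
    if c0 == c1:
        return {c0}
    if abs(c0[0] - c1[0]) + abs(c0[1] - c1[1]) == 1:
        return {c0, c1}
    return supercover_cells(tuple(p0), tuple(p1), cs, r)


def simulate(
    model_id: str,
    params: ModelParams,
    config: DomainConfig,
    seed: int,
    settings: SimulatorSettings = SimulatorSettings(),
) -> SimulationResult:
    """Run one simulation to its final timestep.

    Deterministic given ``(model_id, params, config, seed, settings)``.  The
    run ends after ``config.n_timesteps`` steps or when no tip is active.
    """
    if params.model_id != model_id:
        raise ValueError("params do not belong to this model")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    env = make_environment(config, settings.vegf_profile,
                           decay=settings.vegf_decay,
                           fibronectin_slope=settings.fibronectin_slope)
    if model_id == "ac":
        return _simulate_ac(params, config, env, seed, settings, rng)
    return _simulate_offlattice(model_id, params, config, env, seed, settings, rng)


def _simulate_ac(params, config, env, seed, settings, rng) -> SimulationResult:
    r = config.lattice_resolution
    chi, rho = params["chi"], params["rho"]
    abr, cbr = params["abr"], params["cbr"]
    dt = config.dt

    lineage_grid = -np.ones((r, r), dtype=np.int32)
    x0 = np.clip(np.round(_initial_x(config) / config.h).astype(int), 0, r - 1)
    sites = np.column_stack([x0, np.zeros_like(x0)])
    n = len(sites)
    ages = np.zeros(n)
    lineages = np.arange(n)
    active = np.ones(n, dtype=bool)
    paths: List[List[Tuple[int, int]]] = [[tuple(s)] for s in sites]
    tip_start = [0] * n
    lineage_grid[sites[:, 0], sites[:, 1]] = lineages
    n_ana = 0
    n_br = 0

    for step in range(config.n_timesteps):
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            break
        cur = sites[idx]
        w = _ac_weights(cur, env, chi, rho, settings)
        tot = w.sum(axis=1)
        zero = tot <= 0
        w[zero] = 0.0
        w[zero, 0] = 1.0
        tot[zero] = 1.0
        p = w / tot[:, None]
        u = rng.random(len(idx))
        moves = (np.cumsum(p, axis=1) > u[:, None]).argmax(axis=1)
        deltas = np.array([(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)])
        new = cur + deltas[moves]

        for k, i in enumerate(idx):
            if moves[k] == 0:
                continue
            nx, ny = int(new[k, 0]), int(new[k, 1])
            owner = lineage_grid[nx, ny]
            if owner >= 0 and owner != lineages[i]:
                active[i] = False
                n_ana += 1
                continue
            sites[i] = (nx, ny)
            lineage_grid[nx, ny] = lineages[i]
            paths[i].append((nx, ny))
            if ny == r - 1:  # reached the tumour: absorbed
                active[i] = False

        ages[active] += dt
        if settings.fibronectin_dynamic:
            occ = sites[active]
            if len(occ):
                f = env.fibronectin
                f[occ[:, 0], occ[:, 1]] = np.clip(
                    f[occ[:, 0], occ[:, 1]]
                    + dt * (settings.fibro_production
                            - settings.fibro_degradation * f[occ[:, 0], occ[:, 1]]),
                    0.0, 1.0)

        # branching (one draw per active tip, in index order)
        act_idx = np.nonzero(active)[0]
        if len(act_idx):
            c_here = env.vegf[sites[act_idx, 0], sites[act_idx, 1]]
            eligible = (ages[act_idx] > abr) & (c_here > cbr)
            fire = rng.random(len(act_idx)) < settings.branch_probability
            for k, i in enumerate(act_idx):
                if not (eligible[k] and fire[k]):
                    continue
                if active.sum() >= settings.max_tips:
                    break
                sites = np.vstack([sites, sites[i]])
                ages = np.append(ages, 0.0)
                ages[i] = 0.0
                lineages = np.append(lineages, len(lineages))
                active = np.append(active, True)
                paths.append([tuple(sites[i])])
                tip_start.append(step + 1)
                n_br += 1

    occupied = np.nonzero(lineage_grid >= 0)
    trail_cells = np.column_stack(
        [occupied[0], occupied[1], lineage_grid[occupied]])
    return SimulationResult(
        model_id="ac", params=params, config=config, settings=settings,
        seed=seed, trail_sites=np.column_stack(occupied),
        polylines=None, trail_cells=trail_cells, tip_start=tip_start,
        n_tips_final=int(active.sum()), n_tips_total=len(sites),
        n_anastomoses=n_ana, n_branches=n_br)


def _simulate_offlattice(model_id, params, config, env, seed, settings, rng):
    L = config.side_length
    r = config.lattice_resolution
    cs = L / r
    dt = config.dt
    abr, cbr = params["abr"], params["cbr"]
    is_sl = model_id == "sl"
    if is_sl:
        beta, kappa, sigma = settings.sl_drag, params["kappa"], params["sigma"]
    else:
        dc, dr = params["dc"], params["dr"]
        phi = settings.phi_hat
        if dr * dt * math.cosh(dc) > 1.0:
            raise ValueError(
                "ps turning probabilities can exceed 1; choose a smaller dt")
        speed = settings.ps_speed_for(config)
        half = settings.ps_half_turns

    x0 = _initial_x(config)
    pos = np.column_stack([x0, np.zeros_like(x0)])
    n = len(pos)
    if is_sl:
        vel = np.column_stack([np.zeros(n), np.full(n, settings.sl_init_speed)])
    else:
        heading = np.zeros(n, dtype=int)
    ages = np.zeros(n)
    lineages = np.arange(n)
    active = np.ones(n, dtype=bool)
    paths: List[List[np.ndarray]] = [[pos[i].copy()] for i in range(n)]
    tip_start = [0] * n
    lineage_grid = -np.ones((r, r), dtype=np.int32)
    for i in range(n):
        cx = int(np.clip(pos[i, 0] // cs, 0, r - 1))
        lineage_grid[cx, 0] = lineages[i]
    n_ana = 0
    n_br = 0

    for step in range(config.n_timesteps):
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            break
        cur = pos[idx]
        grads = env.vegf_gradient_many(cur)
        if is_sl:
            noise = rng.standard_normal((len(idx), 2))
            v = vel[idx]
            v = v + dt * (-beta * v + kappa * grads) + sigma * math.sqrt(dt) * noise
            if not np.all(np.isfinite(v)):
                raise SimulationError(
                    f"non-finite SL velocity at seed {seed}, timestep {step}")
            new = cur + v * dt
        else:
            tau_p, tau_m = _ps_turn_rates(heading[idx], grads, dc, dr, dt, phi)
            u = rng.random(len(idx))
            dh = np.where(u < tau_p, 1, np.where(u < tau_p + tau_m, -1, 0))
            hd = heading[idx] + dh
            theta = hd * phi
            new = cur + speed * dt * np.column_stack(
                [np.sin(theta), np.cos(theta)])

        # fast path: tips that stay strictly inside the domain and inside
        # their current raster cell need no boundary or trail bookkeeping
        if is_sl:
            vel[idx] = v
        else:
            heading[idx] = hd
        inside = ((new[:, 0] >= 0) & (new[:, 0] <= L)
                  & (new[:, 1] >= 0) & (new[:, 1] < L))
        cell_old = np.clip((cur // cs).astype(np.int64), 0, r - 1)
        cell_new = np.clip((np.clip(new, 0, L) // cs).astype(np.int64),
                           0, r - 1)
        simple = inside & np.all(cell_new == cell_old, axis=1)
        for k in np.nonzero(simple)[0]:
            i = idx[k]
            pos[i] = new[k]
            paths[i].append(new[k].copy())

        for k, i in enumerate(idx):
            if simple[k]:
                continue
            p_old = pos[i].copy()
            p_new = new[k]
            deactivate = False
            if is_sl:
                v_i = vel[i]
                if p_new[0] < 0:
                    p_new[0] = -p_new[0]
                    v_i[0] = -v_i[0]
                elif p_new[0] > L:
                    p_new[0] = 2 * L - p_new[0]
                    v_i[0] = -v_i[0]
                if p_new[1] < 0:
                    p_new[1] = -p_new[1]
                    v_i[1] = -v_i[1]
                elif p_new[1] >= L:
                    p_new[1] = L
                    deactivate = True
                vel[i] = v_i
            else:
                h_i = int(hd[k])
                p_new, h_i, still = _ps_reflect(p_new, h_i, L, half, True)
                heading[i] = h_i
                deactivate = not still
            cells = _segment_cells(p_old, p_new, cs, r)
            start_cell = (int(np.clip(p_old[0] // cs, 0, r - 1)),
                          int(np.clip(p_old[1] // cs, 0, r - 1)))
            cells.discard(start_cell)
            fused = False
            for cx, cy in cells:
                owner = lineage_grid[cx, cy]
                if owner >= 0 and owner != lineages[i]:
                    fused = True
                    break
            pos[i] = p_new
            paths[i].append(p_new.copy())
            if fused:
                active[i] = False
                n_ana += 1
                continue
            for cx, cy in cells:
                if lineage_grid[cx, cy] < 0:
                    lineage_grid[cx, cy] = lineages[i]
            if deactivate:
                active[i] = False

        ages[active] += dt

        act_idx = np.nonzero(active)[0]
        if len(act_idx):
            c_here = env.vegf_at_many(pos[act_idx])
            eligible = (ages[act_idx] > abr) & (c_here > cbr)
            fire = rng.random(len(act_idx)) < settings.branch_probability
            for k, i in enumerate(act_idx):
                if not (eligible[k] and fire[k]):
                    continue
                if active.sum() >= settings.max_tips:
                    break
                pos = np.vstack([pos, pos[i]])
                ages = np.append(ages, 0.0)
                ages[i] = 0.0
                lineages = np.append(lineages, len(lineages))
                active = np.append(active, True)
                if is_sl:
                    vel = np.vstack([vel, [-vel[i, 0], vel[i, 1]]])
                else:
                    heading = np.append(heading, -heading[i])
                paths.append([pos[i].copy()])
                tip_start.append(step + 1)
                n_br += 1

    occupied = np.nonzero(lineage_grid >= 0)
    trail_cells = np.column_stack(
        [occupied[0], occupied[1], lineage_grid[occupied]])
    return SimulationResult(
        model_id=model_id, params=params, config=config, settings=settings,
        seed=seed, trail_sites=None,
        polylines=[np.asarray(p) for p in paths], trail_cells=trail_cells,
        tip_start=tip_start,
        n_tips_final=int(active.sum()), n_tips_total=len(pos),
        n_anastomoses=n_ana, n_branches=n_br)
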