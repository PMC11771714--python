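"""Dynamic canopy photosynthesis under fluctuating light with finite-rate
NPQ relaxation and Rubisco activation.

The leaf layer is a Farquhar-von Caemmerer-Berry (FvCB) model (assimilation
as the minimum of the Rubisco-limited rate Wc and the electron-transport-
limited rate Wj) extended with two first-order dynamic states:

* Rubisco activation relaxes toward a light-dependent steady state with
  time constant tau_act on light increase and 2 * tau_act on decrease.
* NPQ is carried in three pools (fast qE, intermediate qM, slow qI) that
  relax toward their shares of the light-dependent steady-state NPQ with
  their own time constants; induction (rising NPQ) is faster than
  relaxation by a configurable factor.

Excess NPQ after a light decrease penalizes the light-limited electron
transport drive by the quantum-yield factor
f = (1 + NPQ_ss(I)) / (1 + NPQ(t)), capped at 1.  Each state update uses
the exact exponential-Euler step, unconditionally stable at the default
10-s timestep.  Canopy uptake aggregates leaf pixels:
Ac(t) = sum_i A_i(t) * S_i / S_ground.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LeafConstants",
    "NPQKinetics",
    "LeafPixelLight",
    "steady_state_leaf",
    "step_dynamics",
    "simulate_canopy",
    "loss_report",
    "synthetic_day_par",
    "two_layer_canopy",
    "canopy_light_field",
    "AcSummary",
]


@dataclass(frozen=True)
class LeafConstants:
    """FvCB leaf biochemistry constants (25 degC, units umol, mol-fraction ppm).

    ``kco`` is the effective Michaelis constant Kc * (1 + O/Ko).  ``ci`` is
    held constant (no stomatal dynamics).  ``k_npq``/``k_act`` set the
    half-saturation irradiance of the steady-state NPQ and Rubisco
    activation responses; ``act_min`` is the activation floor in darkness.
    """

    vcmax25: float = 110.0
    jmax25: float = 190.0
    rd: float = 1.5
    ci: float = 270.0
    gamma_star: float = 40.0
    kco: float = 710.0
    phi_psii_max: float = 0.85
    theta: float = 0.7
    k_npq: float = 600.0
    k_act: float = 250.0
    act_min: float = 0.3
    npq_ref_ppfd: float = 2000.0

    def __post_init__(self):
        if self.gamma_star >= self.ci:
            raise ValueError("nonphysical constants: gamma_star >= ci")


@dataclass(frozen=True)
class NPQKinetics:
    """NPQ amplitudes/time constants and the Rubisco activation constant.

    Time constants are minutes.  Deactivation of Rubisco is enforced as
    2 * tau_act; NPQ induction time constants are ``induction_factor`` times
    the relaxation constants.
    """

    tau_qe: float = 1.05
    tau_qm: float = 23.51
    a_qe: float = 1.96
    a_qm: float = 1.58
    a_qi: float = 0.47
    tau_qi: float = 300.0
    tau_act: float = 4.0
    induction_factor: float = 0.5

    @property
    def tau_deact(self) -> float:
        return 2.0 * self.tau_act

    @property
    def amplitude_sum(self) -> float:
        return self.a_qe + self.a_qm + self.a_qi

    def pool_weights(self) -> np.ndarray:
        s = self.amplitude_sum
        if s <= 0:
            return np.array([1.0, 0.0, 0.0])
        return np.array([self.a_qe, self.a_qm, self.a_qi]) / s


@dataclass
class LeafPixelLight:
    """Absorbed PPFD series of one leaf pixel at 1-min cadence."""

    pixel_id: str
    area_m2: float
    t_s: np.ndarray  # seconds of day
    ppfd: np.ndarray  # umol m-2 s-1

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.ppfd = np.asarray(self.ppfd, dtype=float)
        if np.any(self.ppfd < 0):
            raise ValueError("ppfd must be >= 0")
        if self.t_s.shape != self.ppfd.shape:
            raise ValueError("time and ppfd series must align")


# ---------------------------------------------------------------------------
# steady-state leaf model


def _electron_transport(i2, jmax, theta):
    """Non-rectangular hyperbola for potential electron transport J."""
    b = i2 + jmax
    return (b - np.sqrt(b * b - 4.0 * theta * i2 * jmax)) / (2.0 * theta)


def npq_steady_state(ppfd, kin: NPQKinetics, const: LeafConstants):
    """Saturating steady-state NPQ, scaled so NPQ_ss(ref ppfd) = amplitude sum."""
    ppfd = np.asarray(ppfd, dtype=float)
    ref = const.npq_ref_ppfd / (const.npq_ref_ppfd + const.k_npq)
    return kin.amplitude_sum * (ppfd / (ppfd + const.k_npq)) / ref


def activation_steady_state(ppfd, const: LeafConstants):
    ppfd = np.asarray(ppfd, dtype=float)
    return const.act_min + (1.0 - const.act_min) * ppfd / (ppfd + const.k_act)


def _assimilation(ppfd, act, f_npq, const: LeafConstants):
    """Net assimilation from activation state and NPQ penalty factor."""
    wc = const.vcmax25 * act * (const.ci - const.gamma_star) / (const.ci + const.kco)
    i2 = 0.5 * const.phi_psii_max * np.asarray(ppfd, dtype=float) * f_npq
    j = _electron_transport(i2, const.jmax25, const.theta)
    wj = j * (const.ci - const.gamma_star) / (4.0 * const.ci + 8.0 * const.gamma_star)
    return np.minimum(wc, wj) - const.rd


def steady_state_leaf(ppfd, const: LeafConstants, kin: NPQKinetics):
    """Steady-state (A, NPQ, Rubisco activation) at a constant irradiance."""
    if np.any(np.asarray(ppfd) < 0):
        raise ValueError("ppfd must be >= 0")
    npq_ss = npq_steady_state(ppfd, kin, const)
    act_ss = activation_steady_state(ppfd, const)
    a_ss = _assimilation(ppfd, act_ss, 1.0, const)
    return a_ss, npq_ss, act_ss


# ---------------------------------------------------------------------------
# dynamics


@dataclass
class LeafState:
    """Dynamic state: the three NPQ pools and the Rubisco activation fraction."""

    npq_pools: np.ndarray  # shape (..., 3): qE, qM, qI
    act: np.ndarray

    @classmethod
    def at_steady_state(cls, ppfd, kin: NPQKinetics, const: LeafConstants):
        ppfd = np.asarray(ppfd, dtype=float)
        npq_ss = npq_steady_state(ppfd, kin, const)
        pools = np.multiply.outer(npq_ss, kin.pool_weights())
        return cls(npq_pools=pools, act=np.asarray(activation_steady_state(ppfd, const)))


def _relax(x, target, tau_s, dt_s):
    """Exact exponential-Euler step of dx/dt = (target - x)/tau."""
    return target + (x - target) * np.exp(-dt_s / tau_s)


def step_dynamics(state: LeafState, ppfd, kin: NPQKinetics, const: LeafConstants, dt_s: float = 10.0):
    """Advance the leaf state one timestep; returns (new_state, A).

    Assimilation is evaluated from the updated state with the quantum-yield
    penalty f = (1 + NPQ_ss) / (1 + NPQ), capped at 1, applied to the
    light-limited drive, and capped by the steady-state rate at the
    instantaneous irradiance (a lagging state can never out-perform steady
    state).
    """
    ppfd = np.asarray(ppfd, dtype=float)
    npq_ss = npq_steady_state(ppfd, kin, const)
    weights = kin.pool_weights()
    targets = np.multiply.outer(npq_ss, weights)

    taus_relax = np.array([kin.tau_qe, kin.tau_qm, kin.tau_qi]) * 60.0
    taus_ind = taus_relax * kin.induction_factor
    rising = targets > state.npq_pools
    taus = np.where(rising, taus_ind, taus_relax)
    new_pools = _relax(state.npq_pools, targets, taus, dt_s)

    act_target = activation_steady_state(ppfd, const)
    tau_act = np.where(act_target > state.act, kin.tau_act, kin.tau_deact) * 60.0
    new_act = _relax(state.act, act_target, tau_act, dt_s)

    npq_total = new_pools.sum(axis=-1)
    f = np.minimum(1.0, (1.0 + npq_ss) / (1.0 + npq_total))
    a_dyn = _assimilation(ppfd, new_act, f, const)
    a_ss = _assimilation(ppfd, act_target, 1.0, const)
    a = np.minimum(a_dyn, a_ss)
    return LeafState(npq_pools=new_pools, act=new_act), a


# ---------------------------------------------------------------------------
# canopy aggregation


@dataclass
class AcSummary:
    """Daily canopy CO2 uptake: per-step series and its trapezoidal integral."""

    t_s: np.ndarray
    ac: np.ndarray  # umol CO2 m-2 ground s-1
    daily_mol: float  # mol CO2 m-2 ground day-1

    def pct_difference(self, reference: "AcSummary") -> float:
        """% difference of daily Ac vs a reference scenario (loss if positive)."""
        return 100.0 * (reference.daily_mol - self.daily_mol) / reference.daily_mol


def simulate_canopy(
    pixels: list[LeafPixelLight],
    s_ground: float,
    kin: NPQKinetics,
    const: LeafConstants | None = None,
    dt_s: float = 10.0,
) -> AcSummary:
    """Integrate every pixel's dynamic leaf model and aggregate to the canopy.

    The 1-min absorbed-light series are linearly interpolated to the
    timestep; states start at the steady state of the first light value.
    """
    const = const or LeafConstants()
    if dt_s > 60.0:
        raise ValueError("dt must be <= 60 s")
    t0, t1 = pixels[0].t_s[0], pixels[0].t_s[-1]
    for px in pixels:
        if px.t_s[0] != t0 or px.t_s[-1] != t1:
            raise ValueError("all pixels must cover identical time ranges")
    tgrid = np.arange(t0, t1 + 0.5 * dt_s, dt_s)
    light = np.stack([np.interp(tgrid, px.t_s, px.ppfd) for px in pixels])  # (npix, nt)
    areas = np.array([px.area_m2 for px in pixels])

    state = LeafState.at_steady_state(light[:, 0], kin, const)
    ac = np.empty(tgrid.size)
    _, a0 = step_dynamics(state, light[:, 0], kin, const, dt_s=1e-9)
    ac[0] = float(a0 @ areas / s_ground)
    for it in range(1, tgrid.size):
        state, a = step_dynamics(state, light[:, it], kin, const, dt_s=dt_s)
        ac[it] = float(a @ areas / s_ground)
    daily = float(np.trapezoid(ac, tgrid)) * 1e-6  # umol s -> mol
    return AcSummary(t_s=tgrid, ac=ac, daily_mol=daily)


def loss_report(
    scenarios: dict[str, NPQKinetics],
    days: dict[str, list[LeafPixelLight]],
    s_ground: float,
    reference: str,
    const: LeafConstants | None = None,
    dt_s: float = 10.0,
) -> pd.DataFrame:
    """% daily-assimilation loss of each kinetic scenario vs the reference.

    ``days`` maps day labels (e.g. 'cloudy', 'sunny') to pixel light sets;
    all scenarios share the pixels and leaf constants and differ only in
    kinetics.  Loss = 100 * (Ac_ref - Ac_scenario) / Ac_ref.
    """
    if reference not in scenarios:
        raise ValueError(f"reference scenario {reference!r} missing")
    rows = []
    for day_label, pixels in days.items():
        ref = simulate_canopy(pixels, s_ground, scenarios[reference], const, dt_s)
        for name, kin in scenarios.items():
            sim = ref if name == reference else simulate_canopy(pixels, s_ground, kin, const, dt_s)
            rows.append(
                {
                    "day": day_label,
                    "scenario": name,
                    "daily_ac_mol": sim.daily_mol,
                    "loss_pct": sim.pct_difference(ref),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic light drivers


def synthetic_day_par(
    cloudy: bool,
    seed: int = 0,
    par_max: float = 1800.0,
    t_start_h: float = 5.0,
    t_end_h: float = 19.0,
    cloud_transmission: float = 0.10,
    mean_cloud_min: float = 25.0,
    mean_clear_min: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Incident PAR at 1-min cadence for a clear or intermittently cloudy day.

    The clear-sky curve is a half-sine over daylight hours; on a cloudy day
    a seeded two-state Markov process (mean cloud/clear episode lengths in
    minutes) drops transmission to ``cloud_transmission`` during cloud
    passages.  Returns (seconds of day, PAR umol m-2 s-1).
    """
    t_min = np.arange(t_start_h * 60.0, t_end_h * 60.0 + 0.5, 1.0)
    clear = par_max * np.sin(np.pi * (t_min / 60.0 - t_start_h) / (t_end_h - t_start_h))
    clear = np.maximum(clear, 0.0)
    if not cloudy:
        return t_min * 60.0, clear
    rng = np.random.default_rng(seed)
    p_to_cloud = 1.0 / mean_clear_min
    p_to_clear = 1.0 / mean_cloud_min
    state = 0  # 0 clear, 1 cloud
    trans = np.empty(t_min.size)
    for i in range(t_min.size):
        u = rng.random()
        if state == 0 and u < p_to_cloud:
            state = 1
        elif state == 1 and u < p_to_clear:
            state = 0
        trans[i] = cloud_transmission if state == 1 else 1.0
    return t_min * 60.0, clear * trans


def two_layer_canopy(
    t_s: np.ndarray,
    par: np.ndarray,
    n_sun: int = 60,
    n_shade: int = 140,
    pixel_area_m2: float = 5e-6,
    sun_absorptance: float = 0.85,
    shade_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[list[LeafPixelLight], float]:
    """Expand an incident-PAR series into a toy sun/shade pixel canopy.

    Sun pixels absorb ``sun_absorptance`` of incident PAR (with a small
    seeded pixel-to-pixel factor); shade pixels see the diffuse fraction
    plus brief within-canopy sunflecks when the sky is clear.  Returns the
    pixels and the occupied ground area (total leaf area / LAI ~ 3.5).
    """
    rng = np.random.default_rng(seed)
    pixels = []
    for i in range(n_sun):
        scale = sun_absorptance * rng.uniform(0.9, 1.0)
        pixels.append(LeafPixelLight(f"sun{i}", pixel_area_m2, t_s, par * scale))
    for i in range(n_shade):
        base = shade_fraction * rng.uniform(0.6, 1.4)
        series = par * base
        # sporadic sunflecks: short windows where the pixel sees near-full sun
        n_flecks = rng.integers(2, 6)
        for _ in range(n_flecks):
            start = rng.integers(0, max(t_s.size - 10, 1))
            length = rng.integers(2, 8)
            series = series.copy()
            series[start : start + length] = par[start : start + length] * sun_absorptance * 0.9
        pixels.append(LeafPixelLight(f"shade{i}", pixel_area_m2, t_s, series))
    leaf_area = pixel_area_m2 * (n_sun + n_shade)
    s_ground = leaf_area / 3.5
    return pixels, s_ground


def canopy_light_field(
    t_s: np.ndarray,
    par: np.ndarray,
    n_pixels: int = 200,
    lai: float = 3.5,
    seed: int = 0,
    mean_sun_min: float = 10.0,
    sun_absorptance: float = 0.85,
) -> tuple[list[LeafPixelLight], float]:
    """Stochastic stand-in for a ray-traced canopy light field.

    Each pixel sits at a random cumulative leaf-area depth x ~ U(0, LAI);
    its sunlit probability is exp(-0.5 x) (spherical leaf-angle gap
    fraction) and its light alternates between the sunlit level
    (``sun_absorptance`` * incident PAR) and a depth-attenuated diffuse
    level, following a seeded telegraph process whose sunlit episodes last
    ``mean_sun_min`` minutes on average — emulating sun/shade transitions
    from solar movement and leaf flutter.  Returns the pixels and the
    occupied ground area (total leaf area / LAI).
    """
    rng = np.random.default_rng(seed)
    par = np.asarray(par, dtype=float)
    pixels = []
    for i in range(n_pixels):
        depth = rng.uniform(0.0, lai)
        p_sun = float(np.exp(-0.5 * depth))
        diffuse = 0.13 * np.exp(-0.5 * depth) + 0.02
        mean_shade = mean_sun_min * (1.0 - p_sun) / max(p_sun, 1e-3)
        state = rng.random() < p_sun
        sunlit = np.empty(t_s.size, dtype=bool)
        for t in range(t_s.size):
            sunlit[t] = state
            if state and rng.random() < 1.0 / mean_sun_min:
                state = False
            elif not state and rng.random() < 1.0 / max(mean_shade, 1.0):
                state = True
        series = np.where(sunlit, par * sun_absorptance, par * diffuse)
        pixels.append(LeafPixelLight(f"px{i}", 5e-6, t_s, series))
    leaf_area = 5e-6 * n_pixels
    return pixels, leaf_area / lai


def read_pixel_csv(path) -> list[LeafPixelLight]:
    """Read a per-pixel absorbed-light CSV (pixel_id, area_m2, t_s, ppfd)."""
    df = pd.read_csv(path)
    pixels = []
    for pid, grp in df.groupby("pixel_id", sort=True):
        grp = grp.sort_values("t_s")
        pixels.append(
            LeafPixelLight(str(pid), float(grp["area_m2"].iloc[0]), grp["t_s"].to_numpy(), grp["ppfd"].to_numpy())
        )
    return pixels


def write_pixel_csv(pixels: list[LeafPixelLight], path) -> None:
    frames = [
        pd.DataFrame({"pixel_id": px.pixel_id, "area_m2": px.area_m2, "t_s": px.t_s, "ppfd": px.ppfd})
        for px in pixels
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
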