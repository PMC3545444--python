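"""Event-driven simulation of a myofilament walking on an actin filament.

The simulator couples the six-state chemistry of every head (exact Gillespie
sampling; kinetics are strain-independent) to the rigid-body spring
mechanics of the myofilament.  Chemistry dictates *when* something happens;
mechanics dictates *where* the filament sits afterwards:

* binding (2->3) attaches a head at zero strain at the current position;
* a powerstroke (3->4) advances the stepping head's anchor by d and the
  whole filament re-equilibrates, moving forward by d/N_attached;
* detachment (6->1) removes a spring and the filament re-equilibrates.

Because trailing-end heads rarely or never step, the leading end drags them
and the bare zone carries a compressive load.  With bending disabled the
load is unbounded and its mean maps out the force the motor ensemble can
generate; with bending enabled the spanned actin segment buckles
quasi-statically whenever the load would exceed the Euler force F_c, the
end-shortening delta pinning the force at F_c, and the filament breaks when
the buckle curvature reaches the critical value.

State is recorded on a uniform grid (``record_interval``); tension and
attached-head counts are additionally integrated exactly over event
intervals, so reported means do not depend on the grid.  Curvature and
breakage are assessed at the recorded samples: the quasi-static buckling
rule responds instantly even to sub-millisecond tension spikes that a real
filament, with its finite bending relaxation time, could not follow, so
breakage requires the critical curvature to persist on the observation
timescale rather than for a single chemical event.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import InvalidParameterError, RateSet, make_rates
from .mechanics import ActinMechanics, MyofilamentParams, shortening_to_curvature

__all__ = [
    "SimConfig",
    "SimTrace",
    "run_simulation",
    "mean_velocity",
    "sweep",
    "find_threshold_atp",
    "detect_breakage",
]

_LEADING, _TRAILING = 0, 1


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run."""

    atp: float = 1.0  # uM
    duration: float = 20.0  # s
    burn_in: float = 0.0  # s, discarded before means/velocity
    record_interval: float = 0.1  # s, trace grid and breakage assessment
    allow_bending: bool = False
    seed: int = 0
    params: MyofilamentParams = field(default_factory=MyofilamentParams)
    actin: ActinMechanics = field(default_factory=ActinMechanics)
    rates: RateSet | None = None  # overrides make_rates(atp) when given
    record_events: bool = False

    def __post_init__(self) -> None:
        if self.atp <= 0:
            raise InvalidParameterError("atp must be > 0")
        if not self.duration > self.burn_in >= 0:
            raise InvalidParameterError("need duration > burn_in >= 0")
        if self.record_interval <= 0:
            raise InvalidParameterError("record_interval must be > 0")

    def resolved_rates(self) -> RateSet:
        return self.rates if self.rates is not None else make_rates(self.atp)


@dataclass
class SimTrace:
    """Gridded time series plus exact summaries of one run.

    Arrays share the uniform time grid.  ``mean_tension`` and
    ``mean_attached`` are exact time-weighted averages over the post
    burn-in interval; ``X_burn_in`` is the position when the burn-in ended.
    """

    time: np.ndarray
    X: np.ndarray
    tension: np.ndarray
    delta: np.ndarray
    curvature: np.ndarray
    n_attached: np.ndarray
    breakages: list[float]
    events: list[tuple[float, int, int]]  # (time, head, new state), optional
    config: SimConfig
    mean_tension: float
    mean_attached: float
    X_burn_in: float
    max_curvature: float

    @property
    def duration(self) -> float:
        return self.config.duration

    def to_frame(self) -> pd.DataFrame:
        """Trace as a tidy table (units: s, nm, pN, nm, 1/um, count)."""
        return pd.DataFrame(
            {
                "time_s": self.time,
                "X_nm": self.X,
                "tension_pN": self.tension,
                "delta_nm": self.delta,
                "curvature_per_um": self.curvature,
                "n_attached": self.n_attached,
            }
        )


def run_simulation(cfg: SimConfig) -> SimTrace:
    """Run one seeded realization of the model and return its trace."""
    p = cfg.params
    rates = cfg.resolved_rates()
    k = np.concatenate([[0.0], rates.as_array()])  # k[s] = exit rate of state s
    F_c = cfg.actin.F_c
    l_bz = p.l_bz
    kappa = p.kappa
    delta_crit = l_bz * (cfg.actin.kappa_crit * 1e-3 * l_bz / (2 * math.pi)) ** 2

    rng = random.Random(cfg.seed)
    n_m = p.n_m
    end = [_LEADING] * p.n_leading + [_TRAILING] * p.n_trailing
    state = [1] * n_m
    rest = [0.0] * n_m
    # O(1) Gillespie bookkeeping: heads bucketed by state, swap-pop removal
    buckets: dict[int, list[int]] = {s: [] for s in range(1, 7)}
    pos = list(range(n_m))
    buckets[1].extend(range(n_m))
    count = [0] * 7
    count[1] = n_m
    # O(1) mechanics bookkeeping: per-end attached counts and anchor sums
    SL = ST = 0.0
    NL = NT = 0
    X = 0.0
    delta = 0.0
    tension = 0.0

    t = 0.0
    duration, burn_in = cfg.duration, cfg.burn_in
    n_rec = int(math.floor(duration / cfg.record_interval)) + 1
    rec_t = np.arange(n_rec) * cfg.record_interval
    rec_X = np.empty(n_rec)
    rec_T = np.empty(n_rec)
    rec_d = np.empty(n_rec)
    rec_n = np.empty(n_rec, dtype=np.int64)
    i_rec = 0
    int_T = int_N = t_int = 0.0
    X_burn = 0.0
    breakages: list[float] = []
    events: list[tuple[float, int, int]] = []

    def equilibrate() -> None:
        """Zero the net spring force; with bending, pin tension at F_c."""
        nonlocal X, delta, tension
        N = NL + NT
        if N == 0:
            delta, tension = 0.0, 0.0  # free filament: X frozen
            return
        if NL == 0 or NT == 0:
            delta, tension = 0.0, 0.0
            X = (SL + ST) / N
            return
        if cfg.allow_bending:
            # tension(delta) is linear with slope -kappa*NL*NT/N
            A = kappa * (NT * SL - NL * ST) / N
            B = kappa * NL * NT / N
            delta = max(0.0, (A - F_c) / B)
        X = (SL + ST + NT * delta) / N
        tension = abs(kappa * (NT * X - ST - NT * delta))

    while True:
        R = (
            count[1] * k[1]
            + count[2] * k[2]
            + count[3] * k[3]
            + count[4] * k[4]
            + count[5] * k[5]
            + count[6] * k[6]
        )
        t_next = t + rng.expovariate(R)
        # record every grid point inside [t, t_next); state is constant there
        while i_rec < n_rec and rec_t[i_rec] < min(t_next, duration) + 1e-12:
            rec_X[i_rec] = X
            rec_d[i_rec] = delta
            rec_n[i_rec] = NL + NT
            if cfg.allow_bending and delta >= delta_crit:
                # breakage: the broken-off segment releases all stress
                breakages.append(float(rec_t[i_rec]))
                rec_T[i_rec] = tension
                delta = 0.0
                tension = 0.0
                for j in range(n_m):
                    if 3 <= state[j] <= 6:
                        rest[j] = X
                SL, ST = NL * X, NT * X
            else:
                rec_T[i_rec] = tension
            i_rec += 1
        # exact time integrals of tension and attached count past burn-in
        lo = max(t, burn_in)
        hi = min(t_next, duration)
        if hi > lo:
            int_T += tension * (hi - lo)
            int_N += (NL + NT) * (hi - lo)
            t_int += hi - lo
        if t < burn_in <= t_next:
            X_burn = X
        t = t_next
        if t >= duration:
            break

        # choose the transitioning state, then a uniform head within it
        u = rng.random() * R
        acc = 0.0
        for s in range(1, 7):
            acc += count[s] * k[s]
            if u < acc:
                break
        lst = buckets[s]
        j = rng.randrange(len(lst))
        i = lst[j]
        s2 = 1 if s == 6 else s + 1
        last = lst[-1]
        lst[j] = last
        pos[last] = j
        lst.pop()
        b2 = buckets[s2]
        pos[i] = len(b2)
        b2.append(i)
        count[s] -= 1
        count[s2] += 1
        state[i] = s2
        if cfg.record_events:
            events.append((t, i, s2))

        if s == 2:  # binding: attach at zero strain (X unchanged by construction)
            if end[i] == _LEADING:
                rest[i] = X
                SL += X
                NL += 1
            else:
                rest[i] = X - delta
                ST += X - delta
                NT += 1
        elif s == 3:  # powerstroke
            if end[i] == _LEADING or rng.random() < p.p_st:
                rest[i] += p.d
                if end[i] == _LEADING:
                    SL += p.d
                else:
                    ST += p.d
                equilibrate()
        elif s == 6:  # detachment
            if end[i] == _LEADING:
                SL -= rest[i]
                NL -= 1
            else:
                ST -= rest[i]
                NT -= 1
            equilibrate()

    curvature = np.array(
        [shortening_to_curvature(d, l_bz) for d in rec_d]
    )
    return SimTrace(
        time=rec_t,
        X=rec_X,
        tension=rec_T,
        delta=rec_d,
        curvature=curvature,
        n_attached=rec_n,
        breakages=breakages,
        events=events,
        config=cfg,
        mean_tension=int_T / t_int if t_int > 0 else 0.0,
        mean_attached=int_N / t_int if t_int > 0 else 0.0,
        X_burn_in=X_burn,
        max_curvature=float(curvature.max()) if len(curvature) else 0.0,
    )


def mean_velocity(trace: SimTrace, burn_in: float | None = None) -> float:
    """Net filament velocity (X(end) - X(burn_in)) / (duration - burn_in), nm/s."""
    if burn_in is None:
        burn_in = trace.config.burn_in
    duration = trace.duration
    if not duration > burn_in:
        raise InvalidParameterError("need duration > burn_in")
    x0 = float(np.interp(burn_in, trace.time, trace.X))
    return (float(trace.X[-1]) - x0) / (duration - burn_in)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0]) for c in ss.spawn(n)]


def sweep(
    cfg: SimConfig,
    atp_list,
    n_m_list=None,
    p_st_list=None,
    reps: int = 10,
) -> pd.DataFrame:
    """Full-factorial parameter sweep with independent seeds per replicate.

    Returns one row per (atp, n_m, p_st) cell with replicate means and
    standard errors of the mean tension, velocity and attached fraction,
    plus the maximum recorded curvature and breakage rate.
    """
    atp_list = list(atp_list)
    n_m_list = [cfg.params.n_m] if n_m_list is None else list(n_m_list)
    p_st_list = [cfg.params.p_st] if p_st_list is None else list(p_st_list)
    if reps < 1 or not atp_list or not n_m_list or not p_st_list:
        raise InvalidParameterError("need non-empty lists and reps >= 1")
    cells = [(a, n, p) for a in atp_list for n in n_m_list for p in p_st_list]
    seeds = _child_seeds(cfg.seed, len(cells) * reps)
    rows = []
    span = cfg.duration - cfg.burn_in
    for ci, (atp, n_m, p_st) in enumerate(cells):
        params = replace(
            cfg.params, n_m=n_m, n_leading=n_m // 2, n_trailing=n_m - n_m // 2, p_st=p_st
        )
        T, V, A, C, B = [], [], [], [], []
        for r in range(reps):
            run_cfg = replace(cfg, atp=atp, params=params, seed=seeds[ci * reps + r])
            tr = run_simulation(run_cfg)
            T.append(tr.mean_tension)
            V.append(mean_velocity(tr))
            A.append(tr.mean_attached / n_m)
            C.append(tr.max_curvature)
            B.append(len(tr.breakages) / span)
        rows.append(
            {
                "atp_uM": atp,
                "n_m": n_m,
                "p_st": p_st,
                "mean_tension_pN": float(np.mean(T)),
                "se_tension": float(np.std(T, ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0,
                "mean_velocity_nm_s": float(np.mean(V)),
                "se_velocity": float(np.std(V, ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0,
                "mean_attached_fraction": float(np.mean(A)),
                "max_curvature_per_um": float(np.max(C)),
                "breakage_rate_per_s": float(np.mean(B)),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


def find_threshold_atp(
    cfg: SimConfig,
    F_target: float,
    atp_grid,
    reps: int = 10,
) -> tuple[float | None, pd.DataFrame]:
    """Largest grid ATP at which the mean tension still reaches ``F_target``.

    Runs a bending-off sweep over ``atp_grid`` (sorted ascending) and
    returns ``(threshold_atp, sweep_table)``; the threshold is ``None`` if
    even the lowest ATP falls short, and the grid spacing is its resolution.
    """
    atp_grid = sorted(atp_grid)
    if cfg.allow_bending:
        raise InvalidParameterError("threshold search requires bending disabled")
    table = sweep(cfg, atp_grid, reps=reps)
    ok = table[table["mean_tension_pN"] >= F_target]
    threshold = float(ok["atp_uM"].max()) if len(ok) else None
    return threshold, table


def detect_breakage(
    trace: SimTrace | np.ndarray,
    kappa_crit: float,
    reset: bool = True,
    time: np.ndarray | None = None,
) -> np.ndarray:
    """Times at which the recorded curvature first reaches the critical value.

    Scans the (sampled) curvature series for upward crossings of
    ``kappa_crit``.  With ``reset`` every first-reach after the curvature
    has dropped below threshold counts (matching the simulator's
    record-and-reset bookkeeping, where the filament re-breaks after the
    trailing end re-engages); without it only the first crossing is
    returned.
    """
    if isinstance(trace, SimTrace):
        curv, time = trace.curvature, trace.time
    else:
        curv = np.asarray(trace, dtype=float)
        if time is None:
            time = np.arange(len(curv), dtype=float)
    above = curv >= kappa_crit
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if len(above) and above[0]:
        crossings = np.unique(np.concatenate([[0], crossings]))
    if not reset and len(crossings) > 1:
        crossings = crossings[:1]
    return np.asarray(time)[crossings]
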