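"""Individual-based spatially explicit wolf population model.

Simulated wolves live on the synthetic risk landscape, occupy 225 km^2
territories (one breeding pair per territory), and step through an annual
cycle of eight life-history events:

    1. mate-finding        (widowed breeders, then unpaired wolves)
    2. winter dispersal    (lognormal distance, uniform direction)
    3. mate-finding        (same procedure again)
    -- mid-winter census --
    4. reproduction        (litter ~ round(Normal(5.41, 0.79)))
    5. targeted lethal control  (10% of last winter WI count once WI >= 350)
    6. fall dispersal      (pack members in excess of 10 forced out)
    7. spatial mortality   (die with the local cell's risk probability)
    8. aging               (die at age 12)

Mate search is restricted to a circular perception neighborhood of radius
15 km x (1..5 territories); "unrelated" means sharing no parent and not
being parent/offspring (pedigree depth 1, configurable).  Wolves crossing
the landscape boundary during winter dispersal emigrate and are replaced
by an equal number of unrelated age-2 immigrants entering on the Minnesota
edge.  Every repetition is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Landscape, TerritoryMap

__all__ = [
    "SimConfig",
    "WolfState",
    "Trajectory",
    "initialize",
    "mate_finding",
    "winter_dispersal",
    "reproduce",
    "lethal_control",
    "fall_dispersal",
    "risk_mortality",
    "age_and_cull",
    "run_repetition",
    "run_experiment",
    "DISPERSAL_LOG_MEANS",
    "default_scenarios",
]

#: the three dispersal kernels: median distances of ~25, ~50 and ~100 km
DISPERSAL_LOG_MEANS = {"low": 3.23, "ave": 3.92, "high": 4.61}
DISPERSAL_LOG_SD = 1.01

FEMALE, MALE = 0, 1


@dataclass(frozen=True)
class SimConfig:
    perception_territories: int = 1  # search radius = 15 km x this
    dispersal_log_mean: float = 3.92
    dispersal_log_sd: float = DISPERSAL_LOG_SD
    litter_mean: float = 5.41
    litter_sd: float = 0.79
    pack_cap: int = 10
    control_trigger_wi: int = 350
    control_fraction: float = 0.10
    max_age: int = 12
    init_breeding_pairs: int = 20
    founder_age_range: tuple = (2, 5)
    horizon_years: int = 40
    pedigree_depth: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.perception_territories <= 5:
            raise ValueError("perception_territories must be in 1..5")
        if self.init_breeding_pairs < 1:
            raise ValueError("need at least one founding pair")
        if self.pedigree_depth != 1:
            raise NotImplementedError("only depth-1 pedigrees are implemented")

    @property
    def perception_radius_km(self) -> float:
        return 15.0 * self.perception_territories


class WolfState:
    """The living population as parallel arrays (one row per wolf)."""

    __slots__ = (
        "wid", "sex", "age", "mother", "father", "x", "y",
        "territory", "breeder", "next_id",
    )

    def __init__(self) -> None:
        self.wid = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.age = np.empty(0, dtype=np.int16)
        self.mother = np.empty(0, dtype=np.int64)
        self.father = np.empty(0, dtype=np.int64)
        self.x = np.empty(0, dtype=float)
        self.y = np.empty(0, dtype=float)
        self.territory = np.empty(0, dtype=np.int32)
        self.breeder = np.empty(0, dtype=bool)
        self.next_id = 0

    def __len__(self) -> int:
        return len(self.wid)

    def add(self, sex, age, mother, father, x, y, territory, breeder) -> None:
        k = len(sex)
        ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        self.wid = np.concatenate([self.wid, ids])
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.int8)])
        self.age = np.concatenate([self.age, np.asarray(age, np.int16)])
        self.mother = np.concatenate([self.mother, np.asarray(mother, np.int64)])
        self.father = np.concatenate([self.father, np.asarray(father, np.int64)])
        self.x = np.concatenate([self.x, np.asarray(x, float)])
        self.y = np.concatenate([self.y, np.asarray(y, float)])
        self.territory = np.concatenate(
            [self.territory, np.asarray(territory, np.int32)]
        )
        self.breeder = np.concatenate([self.breeder, np.asarray(breeder, bool)])

    def remove(self, mask: np.ndarray) -> None:
        keep = ~mask
        for name in ("wid", "sex", "age", "mother", "father", "x", "y",
                     "territory", "breeder"):
            setattr(self, name, getattr(self, name)[keep])

    def unrelated_matrix_row(self, i: int) -> np.ndarray:
        """Depth-1 unrelatedness of wolf i to every wolf (vectorized)."""
        mi, fi = self.mother[i], self.father[i]
        wi = self.wid[i]
        rel = (
            (self.mother == wi) | (self.father == wi)
            | (self.wid == mi) | (self.wid == fi)
        )
        if mi >= 0:
            rel |= (self.mother == mi) | (self.father == mi)
        if fi >= 0:
            rel |= (self.mother == fi) | (self.father == fi)
        rel[i] = True  # a wolf is not a mate for itself
        return ~rel

    def pack_sizes(self, n_territories: int) -> np.ndarray:
        counts = np.zeros(n_territories, dtype=int)
        has = self.territory >= 0
        np.add.at(counts, self.territory[has], 1)
        return counts

    def breeders_per_territory(self, n_territories: int) -> np.ndarray:
        counts = np.zeros(n_territories, dtype=int)
        m = self.breeder & (self.territory >= 0)
        np.add.at(counts, self.territory[m], 1)
        return counts


@dataclass
class Trajectory:
    """Per-year census record of one repetition."""

    scenario: dict = field(default_factory=dict)
    rows: list = field(default_factory=list)

    def append(self, row: dict) -> None:
        self.rows.append(row)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def years(self) -> np.ndarray:
        return np.array([r["year"] for r in self.rows], dtype=int)

    @property
    def n_sls(self) -> np.ndarray:
        return np.array([r["n_sls"] for r in self.rows], dtype=int)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def check_accounting(self) -> bool:
        """Conservation identity N_t = N_{t-1} + births - deaths + imm - em."""
        for prev, cur in zip(self.rows, self.rows[1:]):
            deaths = (
                cur["deaths_control"] + cur["deaths_fall"]
                + cur["deaths_risk"] + cur["deaths_age"]
            )
            if cur["n_total"] != (
                prev["n_total"] + cur["births"] - deaths
                + cur["immigrants"] - cur["emigrants"]
            ):
                return False
        return True


def _new_tally() -> dict:
    return {
        "births": 0, "deaths_control": 0, "deaths_fall": 0,
        "deaths_risk": 0, "deaths_age": 0, "emigrants": 0,
        "immigrants": 0, "control_shortfall": 0,
    }


def initialize(
    landscape: Landscape,
    territories: TerritoryMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> WolfState:
    """Found the population: breeding pairs in distinct Minnesota territories."""
    mn = territories.by_region("MN")
    if len(mn) < config.init_breeding_pairs:
        raise ValueError(
            f"need {config.init_breeding_pairs} Minnesota territories, "
            f"found {len(mn)}"
        )
    chosen = rng.choice(len(mn), size=config.init_breeding_pairs, replace=False)
    state = WolfState()
    lo, hi = config.founder_age_range
    for j in chosen:
        t = mn[j]
        ages = rng.integers(lo, hi + 1, size=2)
        state.add(
            sex=[FEMALE, MALE],
            age=ages,
            mother=[-1, -1],
            father=[-1, -1],
            x=[t.center_x, t.center_x],
            y=[t.center_y, t.center_y],
            territory=[t.id, t.id],
            breeder=[True, True],
        )
    return state


def _establish(state, i, j, territories, occupied, landscape) -> bool:
    """Move wolves i, j to the nearest unoccupied territory as breeders."""
    free = np.flatnonzero(~occupied)
    if len(free) == 0:
        return False
    centers = territories.centers[free]
    mx = 0.5 * (state.x[i] + state.x[j])
    my = 0.5 * (state.y[i] + state.y[j])
    d2 = (centers[:, 0] - mx) ** 2 + (centers[:, 1] - my) ** 2
    tid = int(free[int(np.argmin(d2))])
    t = territories.territories[tid]
    for w in (i, j):
        state.territory[w] = tid
        state.breeder[w] = True
        state.x[w] = t.center_x
        state.y[w] = t.center_y
    occupied[tid] = True
    return True


def mate_finding(
    state: WolfState,
    landscape: Landscape,
    territories: TerritoryMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Two-pass mate search within the perception neighborhood.

    Pass A: widowed breeders recruit the nearest eligible wolf, first from
    their own pack, else from within the perception radius.  Pass B:
    unpaired wolves that are unrelated to their pack (or sit outside
    breeding range) pair with the nearest eligible partner in the radius
    and claim the nearest breeder-free territory.
    """
    if len(state) == 0:
        return
    radius = config.perception_radius_km
    n_terr = len(territories)

    # --- pass A: widowed breeders ---------------------------------------
    bcount = state.breeders_per_territory(n_terr)
    widowed = np.flatnonzero(
        state.breeder & (state.territory >= 0)
        & (bcount[state.territory] == 1)
    )
    rng.shuffle(widowed)
    for w in widowed:
        if state.breeders_per_territory(n_terr)[state.territory[w]] != 1:
            continue  # already re-mated via an earlier widow this pass
        elig = (
            ~state.breeder
            & (state.sex != state.sex[w])
            & state.unrelated_matrix_row(w)
        )
        if not elig.any():
            continue
        idx = np.flatnonzero(elig)
        same_pack = idx[state.territory[idx] == state.territory[w]]
        d2 = (state.x[idx] - state.x[w]) ** 2 + (state.y[idx] - state.y[w]) ** 2
        if len(same_pack):
            dp = d2[state.territory[idx] == state.territory[w]]
            mate = same_pack[int(np.argmin(dp))]
        else:
            near = d2 <= radius**2
            if not near.any():
                continue
            mate = idx[near][int(np.argmin(d2[near]))]
        tid = state.territory[w]
        t = territories.territories[tid]
        state.territory[mate] = tid
        state.breeder[mate] = True
        state.x[mate] = t.center_x
        state.y[mate] = t.center_y

    # --- pass B: unpaired wolves pair up and colonize -------------------
    occupied = state.breeders_per_territory(n_terr) > 0
    nonbreeders = np.flatnonzero(~state.breeder)
    if len(nonbreeders) == 0:
        return
    outside = ~(
        landscape.in_bounds(state.x, state.y)
        & (landscape.risk_at(state.x, state.y) < 0.75)
    )
    candidate = np.zeros(len(state), dtype=bool)
    candidate[nonbreeders] = (state.territory[nonbreeders] < 0) | outside[
        nonbreeders
    ]
    # in-pack non-breeders qualify only if unrelated to every packmate
    in_pack = nonbreeders[
        (state.territory[nonbreeders] >= 0) & ~outside[nonbreeders]
    ]
    if len(in_pack):
        for tid in np.unique(state.territory[in_pack]):
            members = np.flatnonzero(state.territory == tid)
            parents = [
                {p for p in (state.mother[m], state.father[m]) if p >= 0}
                for m in members
            ]
            for k, m in enumerate(members):
                if state.breeder[m]:
                    continue
                ok = True
                for k2, m2 in enumerate(members):
                    if m2 == m:
                        continue
                    if (
                        parents[k] & parents[k2]
                        or state.wid[m2] in parents[k]
                        or state.wid[m] in parents[k2]
                    ):
                        ok = False
                        break
                candidate[m] = ok
    order = np.flatnonzero(candidate)
    rng.shuffle(order)
    paired = np.zeros(len(state), dtype=bool)
    for i in order:
        if paired[i] or not (~occupied).any():
            if not (~occupied).any():
                break
            continue
        elig = (
            candidate & ~paired & (state.sex != state.sex[i])
            & state.unrelated_matrix_row(i)
        )
        if not elig.any():
            continue
        idx = np.flatnonzero(elig)
        d2 = (state.x[idx] - state.x[i]) ** 2 + (state.y[idx] - state.y[i]) ** 2
        near = d2 <= radius**2
        if not near.any():
            continue
        j = idx[near][int(np.argmin(d2[near]))]
        if _establish(state, i, int(j), territories, occupied, landscape):
            paired[i] = paired[j] = True


def _draw_moves(n: int, config: SimConfig, rng: np.random.Generator):
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    dist = rng.lognormal(config.dispersal_log_mean, config.dispersal_log_sd, size=n)
    return dist * np.cos(theta), dist * np.sin(theta)


def winter_dispersal(
    state: WolfState,
    landscape: Landscape,
    config: SimConfig,
    rng: np.random.Generator,
    tally: dict,
) -> None:
    """Solitary non-breeders relocate; boundary-crossers are swapped for
    immigrants entering on the Minnesota edge."""
    if len(state) == 0:
        return
    ix, iy = landscape.cell_index(state.x, state.y)
    cell = iy.astype(np.int64) * landscape.nx + ix
    _, inv, counts = np.unique(cell, return_inverse=True, return_counts=True)
    alone = counts[inv] == 1
    movers = np.flatnonzero(alone & ~state.breeder)
    if len(movers):
        dx, dy = _draw_moves(len(movers), config, rng)
        nx_ = state.x[movers] + dx
        ny_ = state.y[movers] + dy
        inb = landscape.in_bounds(nx_, ny_)
        gone = movers[~inb]
        stay = movers[inb]
        state.x[stay] = nx_[inb]
        state.y[stay] = ny_[inb]
        state.territory[stay] = -1
        n_out = len(gone)
        if n_out:
            state.remove(np.isin(np.arange(len(state)), gone))
            tally["emigrants"] += n_out
            # equal-count immigration: unrelated 2-year-olds on the MN edge
            edge = np.argwhere(
                landscape.breeding_mask[:, :1]
            )  # (iy, 0) cells on the west (Minnesota) edge
            if len(edge) == 0:
                edge = np.argwhere(
                    (landscape.region_code == 0) & landscape.breeding_mask
                )
            pick = rng.integers(0, len(edge), size=n_out)
            cy = edge[pick][:, 0]
            cx = edge[pick][:, 1] if edge.shape[1] > 1 else np.zeros(n_out, int)
            px = (cx + rng.random(n_out)) * landscape.cell_km
            py = (cy + rng.random(n_out)) * landscape.cell_km
            state.add(
                sex=rng.integers(0, 2, size=n_out),
                age=np.full(n_out, 2),
                mother=np.full(n_out, -1),
                father=np.full(n_out, -1),
                x=px,
                y=py,
                territory=np.full(n_out, -1),
                breeder=np.zeros(n_out, bool),
            )
            tally["immigrants"] += n_out


def reproduce(
    state: WolfState,
    territories: TerritoryMap,
    config: SimConfig,
    rng: np.random.Generator,
    tally: dict,
) -> None:
    """Each complete breeding pair whelps a litter of round(N(5.41, 0.79))."""
    if len(state) == 0:
        return
    n_terr = len(territories)
    fem = np.zeros(n_terr, dtype=np.int64)
    mal = np.zeros(n_terr, dtype=np.int64)
    fem[:] = -1
    mal[:] = -1
    b = state.breeder & (state.territory >= 0)
    for i in np.flatnonzero(b):
        if state.sex[i] == FEMALE:
            fem[state.territory[i]] = i
        else:
            mal[state.territory[i]] = i
    pairs = np.flatnonzero((fem >= 0) & (mal >= 0))
    if len(pairs) == 0:
        return
    litters = np.rint(
        rng.normal(config.litter_mean, config.litter_sd, size=len(pairs))
    ).astype(int)
    litters = np.maximum(litters, 0)
    total = int(litters.sum())
    if total == 0:
        return
    tid = np.repeat(pairs, litters)
    mothers = state.wid[fem[tid]]
    fathers = state.wid[mal[tid]]
    centers = territories.centers
    cx = centers[tid, 0]
    cy = centers[tid, 1]
    state.add(
        sex=rng.integers(0, 2, size=total),
        age=np.zeros(total, int),
        mother=mothers,
        father=fathers,
        x=cx,
        y=cy,
        territory=tid,
        breeder=np.zeros(total, bool),
    )
    tally["births"] += total


def lethal_control(
    state: WolfState,
    landscape: Landscape,
    config: SimConfig,
    rng: np.random.Generator,
    tally: dict,
    last_winter_wi: int,
) -> None:
    """Remove 10% of the last winter Wisconsin count from depredation zones
    (with their 5-km buffers) once that count reaches the trigger."""
    if len(state) == 0 or last_winter_wi < config.control_trigger_wi:
        return
    n_kill = int(np.floor(config.control_fraction * last_winter_wi))
    if n_kill == 0:
        return
    mask = landscape.depredation_mask
    ix, iy = landscape.cell_index(state.x, state.y)
    in_zone = mask[iy, ix] & landscape.in_bounds(state.x, state.y)
    pool = np.flatnonzero(in_zone)
    if len(pool) < n_kill:
        tally["control_shortfall"] += n_kill - len(pool)
        victims = pool
    else:
        victims = rng.choice(pool, size=n_kill, replace=False)
    if len(victims):
        state.remove(np.isin(np.arange(len(state)), victims))
        tally["deaths_control"] += len(victims)


def fall_dispersal(
    state: WolfState,
    landscape: Landscape,
    territories: TerritoryMap,
    config: SimConfig,
    rng: np.random.Generator,
    tally: dict,
) -> None:
    """Pack members in excess of the 10-wolf cap disperse, youngest first.

    A forced disperser that lands inside its natal territory footprint
    dies; one that crosses the landscape boundary emigrates (without
    replacement — replacement is a winter event); otherwise it becomes a
    loner at its landing point.
    """
    if len(state) == 0:
        return
    n_terr = len(territories)
    sizes = state.pack_sizes(n_terr)
    dispersers = []
    for tid in np.flatnonzero(sizes > config.pack_cap):
        members = np.flatnonzero(state.territory == tid)
        nonb = members[~state.breeder[members]]
        excess = sizes[tid] - config.pack_cap
        nonb = nonb[np.argsort(state.age[nonb], kind="stable")]
        dispersers.extend(nonb[:excess].tolist())
    if not dispersers:
        return
    dispersers = np.array(dispersers, dtype=int)
    natal = state.territory[dispersers].copy()
    dx, dy = _draw_moves(len(dispersers), config, rng)
    nx_ = state.x[dispersers] + dx
    ny_ = state.y[dispersers] + dy
    inb = landscape.in_bounds(nx_, ny_)
    in_natal = np.zeros(len(dispersers), dtype=bool)
    for k, (w, t) in enumerate(zip(dispersers, natal)):
        in_natal[k] = bool(territories.footprint_contains(int(t), nx_[k], ny_[k]))
    dies = inb & in_natal
    leaves = ~inb
    ok = inb & ~in_natal
    idx_ok = dispersers[ok]
    state.x[idx_ok] = nx_[ok]
    state.y[idx_ok] = ny_[ok]
    state.territory[idx_ok] = -1
    tally["deaths_fall"] += int(dies.sum())
    tally["emigrants"] += int(leaves.sum())
    drop = dispersers[dies | leaves]
    if len(drop):
        state.remove(np.isin(np.arange(len(state)), drop))


def risk_mortality(
    state: WolfState,
    landscape: Landscape,
    rng: np.random.Generator,
    tally: dict,
) -> None:
    """Each wolf survives with probability 1 - risk of its current cell."""
    if len(state) == 0:
        return
    if not np.all(landscape.in_bounds(state.x, state.y)):
        raise RuntimeError("wolf off-grid at mortality step (movement bug)")
    risk = landscape.risk_at(state.x, state.y)
    dead = rng.random(len(state)) < risk
    tally["deaths_risk"] += int(dead.sum())
    state.remove(dead)


def age_and_cull(
    state: WolfState, config: SimConfig, tally: dict
) -> None:
    """Advance every age by one year; wolves reaching 12 die."""
    if len(state) == 0:
        return
    state.age += 1
    dead = state.age >= config.max_age
    tally["deaths_age"] += int(dead.sum())
    state.remove(dead)


def _census_row(
    state: WolfState, landscape: Landscape, territories: TerritoryMap,
    year: int, tally: dict,
) -> dict:
    if len(state):
        reg = landscape.region_at(state.x, state.y)
        n_mn = int((reg == 0).sum())
        n_wi = int((reg == 1).sum())
        n_mi = int((reg == 2).sum())
    else:
        n_mn = n_wi = n_mi = 0
    bcount = state.breeders_per_territory(len(territories))
    return {
        "year": year,
        "n_total": len(state),
        "n_sls": n_wi + n_mi,
        "n_wi": n_wi,
        "n_mi": n_mi,
        "n_mn": n_mn,
        "packs": int((bcount > 0).sum()),
        "breeders": int(state.breeder.sum()),
        **tally,
    }


def run_repetition(
    landscape: Landscape,
    territories: TerritoryMap,
    config: SimConfig,
) -> Trajectory:
    """One 40-year repetition; record the mid-winter census every year."""
    rng = np.random.default_rng(config.seed)
    state = initialize(landscape, territories, config, rng)
    traj = Trajectory(
        scenario={
            "perception_territories": config.perception_territories,
            "dispersal_log_mean": config.dispersal_log_mean,
            "seed": config.seed,
        }
    )
    last_winter_wi = 0
    tally = _new_tally()
    for year in range(1, config.horizon_years + 1):
        mate_finding(state, landscape, territories, config, rng)
        winter_dispersal(state, landscape, config, rng, tally)
        mate_finding(state, landscape, territories, config, rng)
        row = _census_row(state, landscape, territories, year, tally)
        traj.append(row)
        last_winter_wi = row["n_wi"]
        tally = _new_tally()
        if len(state) == 0:
            break
        reproduce(state, territories, config, rng, tally)
        lethal_control(state, landscape, config, rng, tally, last_winter_wi)
        fall_dispersal(state, landscape, territories, config, rng, tally)
        risk_mortality(state, landscape, rng, tally)
        age_and_cull(state, config, tally)
    return traj


def repetition_seed(base_seed: int, scenario_index: int, rep_index: int) -> int:
    """Stable per-repetition seed: SeedSequence(base, spawn_key=(s, r))."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(scenario_index, rep_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def default_scenarios() -> list:
    """The 15-cell design: perception 1-5 x dispersal low/ave/high."""
    return [
        (pn, name)
        for pn in (1, 2, 3, 4, 5)
        for name in ("low", "ave", "high")
    ]


def run_experiment(
    landscape: Landscape,
    territories: TerritoryMap,
    scenarios: list | None = None,
    reps: int = 100,
    base_seed: int = 0,
    config_kwargs: dict | None = None,
    n_jobs: int = 1,
) -> list:
    """Run the scenario grid; returns [(scenario_dict, Trajectory), ...].

    Per-repetition seeds come from ``repetition_seed`` so serial and
    parallel execution give identical results.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    jobs = []
    for si, (pn, disp) in enumerate(scenarios):
        log_mean = DISPERSAL_LOG_MEANS[disp] if isinstance(disp, str) else float(disp)
        for ri in range(reps):
            cfg = SimConfig(
                perception_territories=pn,
                dispersal_log_mean=log_mean,
                seed=repetition_seed(base_seed, si, ri),
                **(config_kwargs or {}),
            )
            jobs.append((si, ri, pn, disp, cfg))

    def one(job):
        si, ri, pn, disp, cfg = job
        traj = run_repetition(landscape, territories, cfg)
        traj.scenario.update(
            {"scenario_index": si, "rep_index": ri, "dispersal": disp}
        )
        return traj

    if n_jobs == 1:
        results = [one(j) for j in jobs]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(j) for j in jobs)
    return [(t.scenario, t) for t in results]
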