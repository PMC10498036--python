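"""Synthetic inputs with the statistical structure the pipeline assumes.

Every table the analysis consumes can be generated here: open-flow
respirometry traces with first-order chamber washout, baseline drift and
analyser noise; radial-arm-maze visit sequences from agents spanning
random, stereotypic and memory-guided behaviour; log-normal shelter
latencies with individual random effects and right-censoring at 600 s;
and dyadic contest outcomes from latent dominance abilities.  Generators
carry their ground truth as metadata so recovery tests never re-derive
truth from the data, and are bit-reproducible given a seed.

Default protocol constants match the study design the pipeline targets:
12 chicks, 14 maze trials each on an 8-arm maze, 6 respirometry sessions
per chick through a 12 l chamber at 1600 ml min^-1 (washout time constant
12000/1600 = 7.5 min), personality latencies capped at 600 s in two
blocks of three trials, and six group dominance trials.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dominance import BEHAVIOURS, InteractionMatrix
from .ram import RAMTrial
from .repeatability import LatencyRecord
from .respirometry import RespirometrySession

__all__ = [
    "SimConfig",
    "AgentSpec",
    "LatencySample",
    "generate_respirometry_session",
    "generate_ram_trial",
    "generate_latency_data",
    "generate_dominance_data",
    "generate_body_masses",
    "generate_dataset",
    "write_dataset_csvs",
]


class SyntheticError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design constants for the generators."""

    seed: int = 0
    n_chicks: int = 12
    n_ram_trials: int = 14
    n_arms: int = 8
    rmr_sessions_per_chick: int = 6
    flow_rate_ml_min: float = 1600.0
    chamber_volume_ml: float = 12000.0
    ambient_o2_frac: float = 0.2095
    ambient_co2_frac: float = 0.0004
    baseline_drift_frac_per_min: float = 2e-6
    noise_sd_frac: float = 1e-5
    latency_cap_s: float = 600.0
    sample_period_s: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_chicks": self.n_chicks,
            "n_ram_trials": self.n_ram_trials,
            "n_arms": self.n_arms,
            "rmr_sessions_per_chick": self.rmr_sessions_per_chick,
        }
        for name, v in counts.items():
            if v < 1:
                raise SyntheticError(f"{name} must be >= 1")
        for name, v in (
            ("ambient_o2_frac", self.ambient_o2_frac),
            ("ambient_co2_frac", self.ambient_co2_frac),
        ):
            if not 0.0 < v < 1.0:
                raise SyntheticError(f"{name} must lie in (0, 1)")
        if self.flow_rate_ml_min <= 0 or self.chamber_volume_ml <= 0:
            raise SyntheticError("flow rate and chamber volume must be positive")
        if self.noise_sd_frac < 0 or self.latency_cap_s <= 0:
            raise SyntheticError("noise SD must be >= 0 and latency cap > 0")

    @property
    def washout_tau_min(self) -> float:
        """Chamber time constant V / FR in minutes (7.5 min at defaults)."""
        return self.chamber_volume_ml / self.flow_rate_ml_min


@dataclass(frozen=True)
class AgentSpec:
    """Behavioural model of one simulated maze solver.

    ``memory`` agents pick an unvisited arm with probability
    ``memory_fidelity`` (rho) and otherwise any arm uniformly; ``random``
    is the rho = 0 special case; ``stereotypic`` agents follow a
    row-stochastic first-order transition matrix.
    """

    kind: str  # random | stereotypic | memory
    memory_fidelity: Optional[float] = None
    transition_matrix: Optional[np.ndarray] = None
    visit_cap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("random", "stereotypic", "memory"):
            raise SyntheticError(f"unknown agent kind {self.kind!r}")
        if self.kind == "memory":
            rho = self.memory_fidelity
            if rho is None or not 0.0 <= rho <= 1.0:
                raise SyntheticError("memory agents need memory_fidelity in [0, 1]")
        if self.kind == "stereotypic":
            tm = self.transition_matrix
            if tm is None:
                raise SyntheticError("stereotypic agents need a transition matrix")
            tm = np.asarray(tm, dtype=float)
            if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
                raise SyntheticError("transition matrix must be square")
            if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
                raise SyntheticError("transition matrix rows must sum to 1")
            object.__setattr__(self, "transition_matrix", tm)
        if self.visit_cap is not None and self.visit_cap < 1:
            raise SyntheticError("visit_cap must be >= 1")


def _rng(seed: Union[int, np.random.SeedSequence, np.random.Generator, None]):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# respirometry traces


def generate_respirometry_session(
    config: SimConfig,
    true_vo2_ml_min: float,
    true_vco2_ml_min: float,
    seed: Union[int, np.random.Generator, None] = None,
    chick_id: str = "chick",
    session_id: str = "session",
    baseline1_min: float = 20.0,
    animal_min: float = 20.0,
    baseline2_min: float = 10.0,
) -> RespirometrySession:
    """Simulate one baseline-animal-baseline open-flow trace.

    The chamber is treated as a single well-mixed compartment: on placing
    the animal the excurrent fractions relax exponentially from ambient
    toward the steady state implied by inverting the rate equations, with
    time constant ``chamber_volume / flow_rate``.  A linear analyser
    drift and i.i.d. Gaussian noise are superimposed on every reading,
    and the baselines sample ambient air through the same analyser.
    """
    if true_vo2_ml_min < 0 or true_vco2_ml_min < 0:
        raise SyntheticError("true rates must be non-negative")
    fr = config.flow_rate_ml_min
    fi_o2, fi_co2 = config.ambient_o2_frac, config.ambient_co2_frac
    # steady-state excurrent fractions from the inverted rate equations
    fe_o2 = fi_o2 - true_vo2_ml_min * (1.0 - fi_o2) / fr
    fe_co2 = fi_co2 + true_vco2_ml_min * (1.0 - fi_co2) / fr
    if fe_o2 <= 0:
        raise SyntheticError(
            "steady-state excurrent O2 <= 0: VO2 too large for this flow"
        )
    rng = _rng(seed)
    dt = config.sample_period_s
    tau_s = config.washout_tau_min * 60.0
    n1 = int(round(baseline1_min * 60.0 / dt))
    n2 = int(round(animal_min * 60.0 / dt))
    n3 = int(round(baseline2_min * 60.0 / dt))
    t = np.arange(n1 + n2 + n3) * dt
    segment = np.array(
        ["baseline1"] * n1 + ["animal"] * n2 + ["baseline2"] * n3, dtype=object
    )
    o2 = np.full(t.shape, fi_o2)
    co2 = np.full(t.shape, fi_co2)
    animal_t = t[n1 : n1 + n2] - t[n1]
    decay = np.exp(-animal_t / tau_s)
    o2[n1 : n1 + n2] = fe_o2 + (fi_o2 - fe_o2) * decay
    co2[n1 : n1 + n2] = fe_co2 + (fi_co2 - fe_co2) * decay
    drift = config.baseline_drift_frac_per_min * (t / 60.0)
    o2 = o2 + drift
    co2 = co2 + drift
    if config.noise_sd_frac > 0:
        o2 = o2 + rng.normal(0.0, config.noise_sd_frac, size=t.shape)
        co2 = co2 + rng.normal(0.0, config.noise_sd_frac, size=t.shape)
    co2 = np.clip(co2, 1e-9, None)
    data = pd.DataFrame(
        {"time_s": t, "segment": segment, "o2_frac": o2, "co2_frac": co2}
    )
    truth = {
        "true_vo2_ml_min": true_vo2_ml_min,
        "true_vco2_ml_min": true_vco2_ml_min,
        "steady_state_o2": fe_o2,
        "steady_state_co2": fe_co2,
        "tau_min": config.washout_tau_min,
        "drift_frac_per_min": config.baseline_drift_frac_per_min,
    }
    return RespirometrySession(
        data=data,
        flow_rate_ml_min=fr,
        session_id=session_id,
        chick_id=chick_id,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# maze agents


def generate_ram_trial(
    agent: AgentSpec,
    n_arms: int = 8,
    seed: Union[int, np.random.Generator, None] = None,
    chick_id: str = "chick",
    trial_number: int = 1,
    max_steps: int = 10_000,
) -> RAMTrial:
    """Simulate one visit sequence until all arms are seen or a cap hits."""
    if n_arms < 2:
        raise SyntheticError("n_arms must be >= 2")
    rng = _rng(seed)
    cap = agent.visit_cap if agent.visit_cap is not None else max_steps
    visits: list[int] = []
    seen: set[int] = set()
    if agent.kind == "stereotypic":
        tm = agent.transition_matrix
        if tm.shape[0] != n_arms:
            raise SyntheticError("transition matrix size must equal n_arms")
        cum = np.cumsum(tm, axis=1)
        cum[:, -1] = 1.0
        arm = int(rng.integers(n_arms))
        visits.append(arm)
        seen.add(arm)
        while len(seen) < n_arms and len(visits) < cap:
            arm = int(np.searchsorted(cum[arm], rng.random(), side="right"))
            visits.append(arm)
            seen.add(arm)
    else:
        rho = 0.0 if agent.kind == "random" else float(agent.memory_fidelity)
        while len(seen) < n_arms and len(visits) < cap:
            if rho > 0 and rng.random() < rho:
                unvisited = [a for a in range(n_arms) if a not in seen]
                arm = int(unvisited[rng.integers(len(unvisited))])
            else:
                arm = int(rng.integers(n_arms))
            visits.append(arm)
            seen.add(arm)
    if len(seen) < n_arms and agent.visit_cap is None:
        raise SyntheticError(
            f"agent failed to cover {n_arms} arms within {max_steps} steps"
        )
    return RAMTrial(
        chick_id=chick_id,
        trial_number=trial_number,
        visits=np.array(visits),
        n_arms=n_arms,
    )


# ---------------------------------------------------------------------------
# latencies


@dataclass
class LatencySample:
    """Generated latency records plus the generating truth."""

    records: list
    truth: dict

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def generate_latency_data(
    config: SimConfig,
    icc_target: float,
    block_shift: float = 0.0,
    seed: Union[int, np.random.Generator, None] = None,
    trait: str = "boldness",
    n_trials_per_block: int = 3,
    mean_log_latency: float = float(np.log(60.0)),
    total_log_sd: float = 1.0,
) -> LatencySample:
    """Log-normal latencies with individual repeatability ``icc_target``.

    On the log scale each record is individual intercept (variance
    icc * total) + block effect (``block_shift`` added post-RAM) +
    residual (variance (1 - icc) * total).  Latencies above the 600 s cap
    are recorded at the cap with the censoring flag set.
    """
    if not 0.0 <= icc_target < 1.0:
        raise SyntheticError("icc_target must lie in [0, 1)")
    rng = _rng(seed)
    var_total = total_log_sd**2
    sd_ind = np.sqrt(icc_target * var_total)
    sd_res = np.sqrt((1.0 - icc_target) * var_total)
    records = []
    intercepts = rng.normal(0.0, sd_ind, size=config.n_chicks)
    for c in range(config.n_chicks):
        cid = f"chick{c + 1:02d}"
        for b, block in enumerate(("pre_RAM", "post_RAM")):
            shift = block_shift if block == "post_RAM" else 0.0
            for trial in range(1, n_trials_per_block + 1):
                log_lat = (
                    mean_log_latency
                    + intercepts[c]
                    + shift
                    + rng.normal(0.0, sd_res)
                )
                lat = float(np.exp(log_lat))
                censored = lat >= config.latency_cap_s
                records.append(
                    LatencyRecord(
                        chick_id=cid,
                        trait=trait,
                        block=block,
                        trial_index=trial + b * n_trials_per_block,
                        latency_s=config.latency_cap_s if censored else lat,
                        censored=censored,
                    )
                )
    truth = {
        "icc_target": icc_target,
        "block_shift": block_shift,
        "individual_intercepts": intercepts,
        "mean_log_latency": mean_log_latency,
        "total_log_sd": total_log_sd,
    }
    return LatencySample(records, truth)


# ---------------------------------------------------------------------------
# dominance contests


def generate_dominance_data(
    config: SimConfig,
    ability_sd: float = 1.0,
    encounters_per_dyad_mean: float = 2.0,
    seed: Union[int, np.random.Generator, None] = None,
) -> InteractionMatrix:
    """Dyadic win counts from latent abilities (Bradley-Terry contests).

    Abilities are Normal(0, ability_sd^2); each dyad fights a Poisson
    number of times and chick *i* wins a contest against *j* with
    probability logistic(d_i - d_j).  Wins are split at random across the
    three recorded behaviours.  The latent abilities are attached as
    ground truth.
    """
    if ability_sd < 0:
        raise SyntheticError("ability_sd must be >= 0")
    if encounters_per_dyad_mean < 0:
        raise SyntheticError("encounter rate must be >= 0")
    rng = _rng(seed)
    n = config.n_chicks
    ids = [f"chick{c + 1:02d}" for c in range(n)]
    ability = rng.normal(0.0, ability_sd, size=n) if ability_sd > 0 else np.zeros(n)
    wins = np.zeros((n, n), dtype=np.int64)
    behaviours = {b: np.zeros((n, n), dtype=np.int64) for b in BEHAVIOURS}
    for i in range(n):
        for j in range(i + 1, n):
            n_enc = rng.poisson(encounters_per_dyad_mean)
            if n_enc == 0:
                continue
            p_i = 1.0 / (1.0 + np.exp(-(ability[i] - ability[j])))
            wins_i = rng.binomial(n_enc, p_i)
            wins[i, j] = wins_i
            wins[j, i] = n_enc - wins_i
    for (i, j), w in np.ndenumerate(wins):
        if w:
            split = rng.multinomial(w, np.full(len(BEHAVIOURS), 1 / len(BEHAVIOURS)))
            for b, c in zip(BEHAVIOURS, split):
                behaviours[b][i, j] = c
    return InteractionMatrix(
        ids,
        wins,
        behaviours=behaviours,
        truth={"ability": ability, "ability_sd": ability_sd},
    )


# ---------------------------------------------------------------------------
# body mass and full-dataset bundles


def generate_body_masses(
    config: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
    days: Optional[np.ndarray] = None,
    start_mass_g: float = 170.0,
    growth_g_per_day: float = 16.0,
    between_chick_sd_g: float = 15.0,
    within_sd_g: float = 4.0,
) -> pd.DataFrame:
    """Growth-curve body masses: linear growth plus chick-level offsets."""
    rng = _rng(seed)
    if days is None:
        days = np.linspace(21, 41, config.rmr_sessions_per_chick).round().astype(int)
    offsets = rng.normal(0.0, between_chick_sd_g, size=config.n_chicks)
    rows = []
    for c in range(config.n_chicks):
        cid = f"chick{c + 1:02d}"
        for d in days:
            mass = (
                start_mass_g
                + growth_g_per_day * (d - days[0])
                + offsets[c]
                + rng.normal(0.0, within_sd_g)
            )
            rows.append((cid, int(d), float(max(mass, 1.0))))
    return pd.DataFrame(rows, columns=["chick_id", "date_index", "mass_g"])


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, with truth attached."""

    config: SimConfig
    sessions: list
    ram_trials: list
    latencies: dict  # trait -> LatencySample
    interactions: list  # per-trial InteractionMatrix
    masses: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_dataset(
    config: SimConfig,
    icc_boldness: float = 0.45,
    icc_neophobia: float = 0.31,
    block_shift: float = 0.7,
    ability_sd: float = 1.0,
    memory_fidelity_range: tuple[float, float] = (0.3, 0.7),
    rmr_effect: float = 0.0,
    n_dominance_trials: int = 6,
    encounters_per_dyad_mean: float = 2.4,
) -> SyntheticDataset:
    """Generate a full coherent study dataset from one master seed.

    Per-chick mass-specific metabolic intensity declines slightly with
    age while absolute VO2 rises with growth, emulating the observed time
    trends.  ``rmr_effect = 0`` (the default) makes memory, personality
    and dominance independent of metabolic rate, the condition under
    which the null models should win the AIC comparisons; a non-zero
    value couples each behavioural trait to the chick's relative RMR.

    The master seed fans out into one independent stream per data type,
    so e.g. changing the number of maze trials never perturbs the
    latencies.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("mass", "rmr", "ram", "boldness", "neophobia", "dominance", "traits"),
            root.spawn(7),
        )
    }
    masses = generate_body_masses(config, seed=streams["mass"])
    days = np.sort(masses["date_index"].unique())

    # chick-level relative metabolic intensity (drives rmr_effect couplings)
    intensity = streams["traits"].normal(0.0, 0.0025, size=config.n_chicks)
    sessions = []
    rmr_rng = streams["rmr"]
    for c in range(config.n_chicks):
        cid = f"chick{c + 1:02d}"
        for si, d in enumerate(days):
            mass = float(
                masses.query("chick_id == @cid and date_index == @d")["mass_g"].iloc[0]
            )
            # ml O2 / min / g declines gently with age; absolute VO2 grows
            per_g = 0.032 - 0.0002 * (d - days[0]) + intensity[c]
            vo2 = max(per_g, 0.005) * mass
            vco2 = 0.85 * vo2
            sessions.append(
                generate_respirometry_session(
                    config,
                    vo2,
                    vco2,
                    seed=rmr_rng,
                    chick_id=cid,
                    session_id=f"{cid}_d{d:02d}",
                )
            )

    # memory fidelity per chick, optionally coupled to metabolic intensity
    lo, hi = memory_fidelity_range
    base = streams["traits"].uniform(lo, hi, size=config.n_chicks)
    z = (intensity - intensity.mean()) / (intensity.std() + 1e-12)
    rho = np.clip(base + rmr_effect * z, 0.0, 1.0)
    ram_rng = streams["ram"]
    trials = []
    for c in range(config.n_chicks):
        cid = f"chick{c + 1:02d}"
        agent = AgentSpec(kind="memory", memory_fidelity=float(rho[c]))
        for tnum in range(1, config.n_ram_trials + 1):
            trials.append(
                generate_ram_trial(
                    agent,
                    n_arms=config.n_arms,
                    seed=ram_rng,
                    chick_id=cid,
                    trial_number=tnum,
                )
            )

    latencies = {
        "boldness": generate_latency_data(
            config,
            icc_boldness,
            block_shift=block_shift,
            seed=streams["boldness"],
            trait="boldness",
        ),
        "neophobia": generate_latency_data(
            config,
            icc_neophobia,
            block_shift=block_shift,
            seed=streams["neophobia"],
            trait="neophobia",
        ),
    }

    dom_rng = streams["dominance"]
    interactions = [
        generate_dominance_data(
            config,
            ability_sd=ability_sd,
            encounters_per_dyad_mean=encounters_per_dyad_mean,
            seed=dom_rng,
        )
        for _ in range(n_dominance_trials)
    ]

    truth = {
        "memory_fidelity": rho,
        "metabolic_intensity": intensity,
        "rmr_effect": rmr_effect,
    }
    return SyntheticDataset(
        config, sessions, trials, latencies, interactions, masses, truth
    )


# ---------------------------------------------------------------------------
# CSV output


def write_dataset_csvs(dataset: SyntheticDataset, outdir: Union[str, Path]) -> dict:
    """Write the bundle to the pipeline's tidy CSV schema plus a metadata
    sidecar echoing the seed and configuration.  Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": outdir / "sessions.csv",
        "ram_trials": outdir / "ram_trials.csv",
        "latencies": outdir / "latencies.csv",
        "interactions": outdir / "interactions.csv",
        "masses": outdir / "masses.csv",
        "metadata": outdir / "metadata.json",
    }

    session_frames = []
    for s in dataset.sessions:
        frame = s.data.copy()
        frame.insert(0, "session_id", s.session_id)
        frame.insert(1, "chick_id", s.chick_id)
        frame["flow_ml_min"] = s.flow_rate_ml_min
        session_frames.append(frame)
    pd.concat(session_frames, ignore_index=True).to_csv(
        paths["sessions"], index=False
    )

    ram_rows = [
        (tr.chick_id, tr.trial_number, k, int(arm))
        for tr in dataset.ram_trials
        for k, arm in enumerate(tr.visits)
    ]
    pd.DataFrame(
        ram_rows, columns=["chick_id", "trial", "visit_index", "arm"]
    ).to_csv(paths["ram_trials"], index=False)

    lat_rows = [
        (r.chick_id, r.trait, r.block, r.trial_index, r.latency_s, r.censored)
        for sample in dataset.latencies.values()
        for r in sample.records
    ]
    pd.DataFrame(
        lat_rows,
        columns=["chick_id", "trait", "block", "trial", "latency_s", "censored"],
    ).to_csv(paths["latencies"], index=False)

    int_rows = []
    for tid, m in enumerate(dataset.interactions, start=1):
        mats = m.behaviours or {"all": m.wins}
        for behaviour, wins in mats.items():
            for (i, j), c in np.ndenumerate(wins):
                if c:
                    int_rows.append((tid, m.ids[i], m.ids[j], behaviour, int(c)))
    pd.DataFrame(
        int_rows, columns=["trial_id", "winner_id", "loser_id", "behaviour", "count"]
    ).to_csv(paths["interactions"], index=False)

    dataset.masses.to_csv(paths["masses"], index=False)

    meta = {"config": asdict(dataset.config), "truth_keys": sorted(dataset.truth)}
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}
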