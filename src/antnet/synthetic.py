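"""Synthetic colony generator with known ground truth.

Every downstream stage has a parameter-recovery test against colonies built
here: weighted networks with a planted two-community structure and tunable
modularity, bimodal maturity profiles with a configurable intermediate
fraction and high:low imbalance, approximately log-normal strength
distributions that decrease with maturity, three queen archetypes
(specialist / hub / worker-like) and random-walk trajectories whose home
ranges grow with maturity.

The generator targets the statistical structure the analysis assumes —
Poisson interaction counts with log-normal per-ant activity multipliers,
a logistic maturity-to-community coupling — not behavioural realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .network import WeightedNetwork, build_network
from .queen_kinetics import HourlyContacts
from collections import Counter

__all__ = [
    "ColonyConfig",
    "SyntheticColony",
    "generate_planted_network",
    "generate_block_network",
    "generate_maturity_profile",
    "generate_queen_schedule",
    "generate_trajectories",
    "generate_colony",
    "generate_cohort",
]

QUEEN_ID = "queen"
ARCHETYPES = ("specialist", "hub", "worker_like")


@dataclass(frozen=True)
class ColonyConfig:
    """Ground-truth parameters of one synthetic colony."""

    n_workers: int = 100
    planted_split: float = 0.55  # fraction of workers in the forager community
    q_in: float = 2.0  # within-community events per pair per hour
    q_out: float = 0.2  # between-community events per pair per hour
    strength_lognorm_sigma: float = 0.4
    intermediate_fraction: float = 0.2
    high_low_imbalance: float = 0.44  # (n_{>0.9} - n_{<0.1}) / n_{<0.1}
    queen_archetype: str = "specialist"
    duration_hours: int = 24
    arena_dims: tuple[float, float] = (30.0, 40.0)  # body lengths
    body_length: float = 1.0
    seed: int = 0
    # generative knobs beyond the headline parameters
    membership_steepness: float = 8.0
    strength_maturity_coupling: float = 1.0  # >0: strength falls with maturity
    forage_scale: float = 0.5
    forage_exponent: float = 2.0
    frame_rate_hz: float = 1.0
    specialist_partners: int = 3
    species: str | None = None
    colony_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_workers < 4:
            raise ConfigError("n_workers must be >= 4")
        if not 0.0 < self.planted_split < 1.0:
            raise ConfigError("planted_split must lie in (0, 1)")
        if not (self.q_in > self.q_out >= 0.0):
            raise ConfigError("require q_in > q_out >= 0")
        if not 0.0 <= self.intermediate_fraction < 1.0:
            raise ConfigError("intermediate_fraction must lie in [0, 1)")
        if self.duration_hours < 2:
            raise ConfigError("duration_hours must be >= 2")
        if self.queen_archetype not in ARCHETYPES:
            raise ConfigError(f"unknown queen archetype {self.queen_archetype!r}")
        if self.arena_dims[0] <= 0 or self.arena_dims[1] <= 0:
            raise ConfigError("arena_dims must be positive")


@dataclass
class SyntheticColony:
    """Generator output: data files plus the ground truth that made them."""

    config: ColonyConfig
    worker_ids: list
    truth_maturity: pd.Series
    truth_membership: pd.Series  # 0 = nurse community, 1 = forager community
    edge_counts: pd.DataFrame  # symmetric, zero diagonal, includes the queen
    foraging_proportion: pd.Series  # includes queen (0.0)
    detection_count: pd.Series
    hourly_queen_contacts: HourlyContacts
    detections: pd.DataFrame

    @property
    def queen_id(self) -> str:
        return QUEEN_ID

    @property
    def ids(self) -> list:
        return list(self.edge_counts.index)

    def metadata(self) -> pd.DataFrame:
        ids = self.ids
        meta = pd.DataFrame(
            {
                "is_queen": [a == QUEEN_ID for a in ids],
                "foraging_proportion": self.foraging_proportion.reindex(ids),
                "detection_count": self.detection_count.reindex(ids),
            },
            index=pd.Index(ids, name="ant_id"),
        )
        if self.config.species is not None:
            meta["species"] = self.config.species
        return meta

    def network(self, excluded=()) -> WeightedNetwork:
        return build_network(
            self.edge_counts,
            metadata=self.metadata(),
            excluded=excluded,
            colony=self.config.colony_id,
            species=self.config.species,
        )

    def write(self, outdir) -> None:
        """Write detections CSV, edge-list CSV, metadata CSV and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.detections.to_csv(outdir / "detections.csv", index=False)
        rows = []
        ids = self.ids
        W = self.edge_counts.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if W[i, j] > 0:
                    rows.append((ids[i], ids[j], int(W[i, j])))
        pd.DataFrame(rows, columns=["ant_i", "ant_j", "count"]).to_csv(
            outdir / "edges.csv", index=False
        )
        self.metadata().to_csv(outdir / "metadata.csv")
        truth = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
            "truth_maturity": self.truth_maturity.round(10).to_dict(),
            "truth_membership": {k: int(v) for k, v in self.truth_membership.items()},
        }
        (outdir / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))


# -- planted networks ------------------------------------------------------


def _activities(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal activity multipliers with unit mean."""
    return np.exp(sigma * rng.standard_normal(n) - sigma**2 / 2.0)


def generate_block_network(
    block_sizes,
    q_in: float,
    q_out: float,
    sigma: float = 0.4,
    hours: float = 24.0,
    seed=None,
    activities: np.ndarray | None = None,
    ids=None,
) -> tuple[WeightedNetwork, np.ndarray]:
    """Poisson planted-partition network with any number of blocks.

    Pair (i, j) receives a count drawn from
    Poisson(hours * a_i * a_j * q), with q = q_in for within-block pairs and
    q_out otherwise; a_i are log-normal activity multipliers.
    """
    block_sizes = [int(b) for b in block_sizes]
    n = sum(block_sizes)
    if n < 4:
        raise ConfigError("need at least 4 nodes")
    if not q_in > q_out >= 0:
        raise ConfigError("require q_in > q_out >= 0")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    a = _activities(n, sigma, rng) if activities is None else np.asarray(activities)
    same = labels[:, None] == labels[None, :]
    rate = hours * np.outer(a, a) * np.where(same, q_in, q_out)
    iu, ju = np.triu_indices(n, k=1)
    counts = rng.poisson(rate[iu, ju])
    W = np.zeros((n, n))
    W[iu, ju] = counts
    W += W.T
    net = build_network(W, ids=ids if ids is not None else list(range(n)))
    return net, labels


def generate_planted_network(
    n: int,
    split: float,
    q_in: float,
    q_out: float,
    sigma: float = 0.4,
    hours: float = 24.0,
    seed=None,
) -> tuple[WeightedNetwork, np.ndarray]:
    """Two-block planted network; ``split`` is the second (forager) block's
    fraction of nodes.  Returns (network, truth_membership in {0, 1})."""
    if n < 4:
        raise ConfigError("need at least 4 nodes")
    if not 0.0 < split < 1.0:
        raise ConfigError("split must lie in (0, 1)")
    n1 = int(round(n * split))
    n1 = min(max(n1, 1), n - 1)
    return generate_block_network(
        [n - n1, n1], q_in, q_out, sigma=sigma, hours=hours, seed=seed
    )


# -- maturity profile ------------------------------------------------------


def generate_maturity_profile(
    n: int,
    intermediate_fraction: float,
    high_low_imbalance: float = 0.44,
    seed=None,
) -> np.ndarray:
    """Bimodal maturity values in [0, 1] with planted composition.

    Exactly round(n * intermediate_fraction) values fall in the open
    interval (0.25, 0.75); the remainder are extremal, split between a low
    mode on (0, 0.1) and a high mode on (0.9, 1) so that
    (n_high - n_low) / n_low matches ``high_low_imbalance`` up to integer
    rounding.
    """
    if not 0.0 <= intermediate_fraction < 1.0:
        raise ConfigError("intermediate_fraction must lie in [0, 1)")
    if high_low_imbalance <= -1.0:
        raise ConfigError("high_low_imbalance must exceed -1")
    rng = np.random.default_rng(seed)
    n_int = int(round(n * intermediate_fraction))
    n_ext = n - n_int
    if n_ext > 0:
        n_low = int(round(n_ext / (2.0 + high_low_imbalance)))
        n_high = n_ext - n_low
        if n_low == 0:
            raise ConfigError(
                "infeasible composition: imbalance leaves no low-maturity ants"
            )
    else:
        n_low = n_high = 0
    vals = np.concatenate(
        [
            rng.uniform(0.0, 0.1, size=n_low),
            rng.uniform(0.9, 1.0, size=n_high),
            rng.uniform(0.25, 0.75, size=n_int),
        ]
    )
    # keep interval membership strict under the open-interval counting rule
    vals = np.clip(vals, 1e-9, 1.0 - 1e-9)
    rng.shuffle(vals)
    return vals


# -- queen schedules -------------------------------------------------------


def generate_queen_schedule(
    archetype: str,
    n_workers: int,
    hours: int,
    seed=None,
    worker_ids=None,
    rate_per_worker: np.ndarray | None = None,
    target_total: float | None = None,
    strength_sd: float | None = None,
    n_partners: int = 3,
    hub_sd_multiplier: float = 3.0,
) -> HourlyContacts:
    """Hourly queen-contact schedule for one of the three archetypes.

    ``rate_per_worker`` gives each worker's expected total queen contacts
    over the experiment (its shape sets the queen's interaction profile);
    when omitted a uniform profile is used.  ``target_total`` rescales the
    expected grand total (worker-mean strength for specialist/worker_like);
    the hub archetype inflates it by ``hub_sd_multiplier * strength_sd``.

    specialist -- ``n_partners`` fixed partners, contacted every hour
    (hour-to-hour identity conservation is 1 by construction).
    hub        -- worker-shaped profile, total inflated to push the queen's
    strength z-score above +2.
    worker_like-- worker-shaped profile at the worker-typical total.
    """
    if archetype not in ARCHETYPES:
        raise ConfigError(f"unknown queen archetype {archetype!r}")
    if hours < 2:
        raise ConfigError("hours must be >= 2")
    rng = np.random.default_rng(seed)
    if worker_ids is None:
        worker_ids = list(range(n_workers))
    worker_ids = list(worker_ids)
    if rate_per_worker is None:
        rate_per_worker = np.full(len(worker_ids), 1.0)
    rate = np.asarray(rate_per_worker, dtype=float)
    if rate.sum() <= 0:
        raise ConfigError("rate_per_worker must have positive total")
    total = float(target_total) if target_total is not None else float(rate.sum())
    sd = float(strength_sd) if strength_sd is not None else 0.5 * total

    counts = [Counter() for _ in range(hours)]
    if archetype == "specialist":
        k = min(n_partners, len(worker_ids))
        # partners come from the high-rate (nurse-side) half of the roster,
        # keeping the queen unambiguously oriented toward her own community
        # even with very few edges
        eligible = np.flatnonzero(rate >= np.median(rate))
        if eligible.size < k:
            eligible = np.arange(len(worker_ids))
        p = rate[eligible] / rate[eligible].sum()
        partners = eligible[rng.choice(eligible.size, size=k, replace=False, p=p)]
        per_hour = total / (hours * k)
        for t in range(hours):
            for w in partners:
                counts[t][worker_ids[w]] = max(1, int(rng.poisson(per_hour)))
    else:
        if archetype == "hub":
            total = total + hub_sd_multiplier * sd
        totals = rng.poisson(rate / rate.sum() * total)
        for w, c in enumerate(totals):
            if c == 0:
                continue
            hrs = rng.integers(0, hours, size=c)
            for t in hrs:
                counts[t][worker_ids[w]] += 1
    return HourlyContacts(counts=counts)


# -- trajectories ----------------------------------------------------------


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def generate_trajectories(
    colony: "SyntheticColony",
    step_scale_by_maturity=None,
    seed=None,
    n_frames: int = 600,
) -> pd.DataFrame:
    """Per-frame random-walk detections for every ant in the colony.

    Step scale grows with maturity (default 0.05 + 0.6 * maturity body
    lengths per frame) so the expected 90% home range increases with
    maturity by construction.  Each frame's arena label is drawn
    Bernoulli(foraging_proportion); the queen stays in the nest.  A step
    scale of zero pins the ant to its starting point.
    """
    cfg = colony.config
    if step_scale_by_maturity is None:
        step_scale_by_maturity = lambda m: 0.05 + 0.6 * m  # noqa: E731
    rng = np.random.default_rng(seed)
    width, height = cfg.arena_dims
    times = np.arange(n_frames) / cfg.frame_rate_hz
    frames = []
    roster = list(colony.ids)
    for ant in roster:
        m = 0.0 if ant == QUEEN_ID else float(colony.truth_maturity[ant])
        scale = float(step_scale_by_maturity(m))
        start = rng.uniform([0, 0], [width, height])
        steps = scale * rng.standard_normal((n_frames, 2))
        steps[0] = 0.0
        pos = start + np.cumsum(steps, axis=0)
        x = _fold(pos[:, 0], 0.0, width)
        y = _fold(pos[:, 1], 0.0, height)
        angle = np.arctan2(*np.gradient(np.c_[y, x], axis=0).T)
        fp = 0.0 if ant == QUEEN_ID else float(colony.foraging_proportion[ant])
        forage = rng.random(n_frames) < fp
        frames.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "ant_id": ant,
                    "x": x,
                    "y": y,
                    "angle_rad": angle,
                    "arena": np.where(forage, "forage", "nest"),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["time_s", "ant_id"], kind="stable").reset_index(drop=True)


# -- full colony and cohorts -----------------------------------------------


def _membership_from_maturity(
    maturity: np.ndarray, split: float, steepness: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli forager membership, logistic in maturity.

    The logistic centre is tuned (bisection) so the expected forager
    fraction equals ``split``; with a symmetric profile the centre sits
    near maturity 0.5.
    """

    def mean_p(c):
        return float(np.mean(1.0 / (1.0 + np.exp(-steepness * (maturity - c)))))

    lo, hi = -2.0, 3.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) > split:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(-steepness * (maturity - c)))
    return (rng.random(maturity.size) < p).astype(int)


def generate_colony(
    config: ColonyConfig,
    n_frames: int = 0,
    low_detection_worker: int | None = None,
) -> SyntheticColony:
    """Generate a full synthetic colony from its configuration.

    ``n_frames`` > 0 additionally simulates frame-level detections (for
    spatial and capsule tests); interaction counts are always generated at
    the hourly scale.  ``low_detection_worker`` plants one worker with a
    detection count far below the colony mean, to exercise the exclusion
    rule downstream.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_workers
    worker_ids = [f"w{i:03d}" for i in range(n)]

    maturity = generate_maturity_profile(
        n, cfg.intermediate_fraction, cfg.high_low_imbalance, seed=rng
    )
    membership = _membership_from_maturity(
        maturity, cfg.planted_split, cfg.membership_steepness, rng
    )
    base_act = _activities(n, cfg.strength_lognorm_sigma, rng)
    act = base_act * np.exp(
        -cfg.strength_maturity_coupling * (maturity - maturity.mean())
    )

    # worker-worker interaction counts
    same = membership[:, None] == membership[None, :]
    rate = cfg.duration_hours * np.outer(act, act) * np.where(same, cfg.q_in, cfg.q_out)
    iu, ju = np.triu_indices(n, k=1)
    Www = np.zeros((n, n))
    Www[iu, ju] = rng.poisson(rate[iu, ju])
    Www += Www.T

    # queen contacts: archetype-dependent totals over a rate profile halfway
    # between a nurse's profile and the average worker's profile — the queen
    # stays oriented toward the nurse community while her contact spread
    # (entropy) remains workforce-typical
    worker_strength = Www.sum(axis=1)
    q_nurse = np.where(membership == 0, cfg.q_in, cfg.q_out)
    same_frac = np.where(
        membership == 0, (membership == 0).mean(), (membership == 1).mean()
    )
    q_avg = same_frac * cfg.q_in + (1.0 - same_frac) * cfg.q_out
    queen_rate = cfg.duration_hours * act * (0.72 * q_nurse + 0.28 * q_avg)
    hc = generate_queen_schedule(
        cfg.queen_archetype,
        n_workers=n,
        hours=cfg.duration_hours,
        seed=rng,
        worker_ids=worker_ids,
        rate_per_worker=queen_rate,
        target_total=float(worker_strength.mean()),
        strength_sd=float(worker_strength.std(ddof=1)),
        n_partners=cfg.specialist_partners,
    )
    queen_totals = hc.total_contacts()

    ids = worker_ids + [QUEEN_ID]
    W = np.zeros((n + 1, n + 1))
    W[:n, :n] = Www
    for w, c in queen_totals.items():
        i = worker_ids.index(w)
        W[i, n] = W[n, i] = c
    edge_counts = pd.DataFrame(W, index=ids, columns=ids)

    forage_p = np.clip(
        cfg.forage_scale * maturity**cfg.forage_exponent
        + rng.normal(0.0, 0.02, size=n),
        0.0,
        1.0,
    )
    foraging = pd.Series(
        np.append(forage_p, 0.0), index=pd.Index(ids, name="ant_id"),
        name="foraging_proportion",
    )
    det_counts = np.full(n + 1, 1000.0)
    if low_detection_worker is not None:
        det_counts[low_detection_worker] = 10.0
    detection_count = pd.Series(
        det_counts, index=pd.Index(ids, name="ant_id"), name="detection_count"
    )

    colony = SyntheticColony(
        config=cfg,
        worker_ids=worker_ids,
        truth_maturity=pd.Series(
            maturity, index=pd.Index(worker_ids, name="ant_id"), name="maturity"
        ),
        truth_membership=pd.Series(
            membership, index=pd.Index(worker_ids, name="ant_id"), name="membership"
        ),
        edge_counts=edge_counts,
        foraging_proportion=foraging,
        detection_count=detection_count,
        hourly_queen_contacts=hc,
        detections=pd.DataFrame(
            columns=["time_s", "ant_id", "x", "y", "angle_rad", "arena"]
        ),
    )
    if n_frames > 0:
        colony.detections = generate_trajectories(
            colony, seed=rng, n_frames=n_frames
        )
    return colony


def generate_cohort(
    n_colonies: int,
    dol_modularity_slope: float,
    seed=None,
    base_config: ColonyConfig | None = None,
    n_species_groups: int = 5,
) -> list[SyntheticColony]:
    """Cohort of colonies with co-varying modularity and foraging skew.

    A latent colony trait u drives planted community separation
    (q_in / q_out); the foraging-skew knob follows
    v = tanh(slope) * u + sqrt(1 - tanh(slope)^2) * e with independent
    noise e, so the cross-colony correlation between measured modularity
    and measured division of labour carries the sign and approximate
    magnitude of ``dol_modularity_slope``.
    """
    if n_colonies < 3:
        raise ConfigError("a cohort needs at least 3 colonies")
    rng = np.random.default_rng(seed)
    base = base_config or ColonyConfig(n_workers=50)
    t = float(np.tanh(dol_modularity_slope))
    colonies = []
    for c in range(n_colonies):
        u = rng.uniform(-1.0, 1.0)
        e = rng.uniform(-1.0, 1.0)
        v = t * u + np.sqrt(max(0.0, 1.0 - t * t)) * e
        ratio = 2.0 + 10.0 * (u + 1.0) / 2.0
        q_out = 0.2
        forage_scale = 0.15 + 0.7 * (v + 1.0) / 2.0
        cfg = replace(
            base,
            q_in=q_out * ratio,
            q_out=q_out,
            forage_scale=forage_scale,
            seed=int(rng.integers(0, 2**31 - 1)),
            colony_id=f"colony{c:02d}",
            species=f"sp{c % n_species_groups + 1}",
        )
        colonies.append(generate_colony(cfg))
    return colonies
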