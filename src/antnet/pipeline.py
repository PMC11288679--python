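"""Per-colony and cross-colony analysis orchestration.

``run_colony`` executes the full chain — low-detection exclusion, network
construction, soft communities over k = 2..5, permutation test, per-ant and
colony metrics, queen kinetics — and returns a serializable
:class:`ColonyReport`.  ``run_cohort`` adds the cross-colony
modularity/division-of-labour correlation and per-group queen-vs-worker
comparisons.  All stages are deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import community, metrics, queen_kinetics, tracking
from .errors import AntnetError, DegenerateGroupError
from .network import WeightedNetwork, build_network

__all__ = [
    "PipelineConfig",
    "ColonyData",
    "ColonyReport",
    "CohortReport",
    "run_colony",
    "run_cohort",
    "validate_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the per-colony analysis, mirroring module defaults."""

    ks: tuple[int, ...] = (2, 3, 4, 5)
    n_rewires: int = 100
    n_restarts: int = 20
    tol: float = 1e-6
    max_iter: int = 500
    n_swap_multiplier: int = 10
    rewire_strategy: str = "swap_shuffle_weights"
    max_gap_frames: int = 0
    body_length: float = 1.0
    hex_circumradius: float | None = None  # default 2 x body_length
    arena_dims: tuple[float, float] | None = None  # inferred when None
    coverage: float = 0.9
    hour_length_s: float = 3600.0
    seed: int = 0
    run_profile: bool = True
    run_permutation: bool = True
    run_home_ranges: bool = True
    apply_low_detection_filter: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise AntnetError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ks", "arena_dims"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["ks"] = list(d["ks"])
        if d["arena_dims"] is not None:
            d["arena_dims"] = list(d["arena_dims"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)


@dataclass
class ColonyData:
    """Inputs of one colony analysis."""

    edge_counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    detections: pd.DataFrame | None = None
    events: list | None = None
    hourly_contacts: queen_kinetics.HourlyContacts | None = None
    colony_id: str | None = None
    species: str | None = None

    @classmethod
    def from_synthetic(cls, colony) -> "ColonyData":
        return cls(
            edge_counts=colony.edge_counts,
            metadata=colony.metadata(),
            detections=colony.detections if len(colony.detections) else None,
            hourly_contacts=colony.hourly_queen_contacts,
            colony_id=colony.config.colony_id,
            species=colony.config.species,
        )

    @classmethod
    def from_files(
        cls, edges_path, metadata_path=None, detections_path=None, colony_id=None,
        species=None,
    ) -> "ColonyData":
        edges = pd.read_csv(edges_path)
        meta = (
            pd.read_csv(metadata_path).set_index("ant_id")
            if metadata_path is not None
            else None
        )
        ids = (
            list(meta.index)
            if meta is not None
            else sorted(set(edges["ant_i"]) | set(edges["ant_j"]), key=str)
        )
        pos = {a: i for i, a in enumerate(ids)}
        W = np.zeros((len(ids), len(ids)))
        for _, row in edges.iterrows():
            i, j = pos[row["ant_i"]], pos[row["ant_j"]]
            W[i, j] = W[j, i] = row["count"]
        counts = pd.DataFrame(W, index=ids, columns=ids)
        detections = (
            tracking.read_detections(detections_path)
            if detections_path is not None
            else None
        )
        if species is None and meta is not None and "species" in meta.columns:
            species = str(meta["species"].iloc[0])
        return cls(
            edge_counts=counts, metadata=meta, detections=detections,
            colony_id=colony_id, species=species,
        )


@dataclass
class ColonyReport:
    colony_id: str | None
    species: str | None
    n_ants: int
    excluded: list
    q_by_k: dict[int, float]
    argmax_k: int | None
    permutation: dict | None
    dol: float | None
    maturity_stats: dict | None
    per_ant: list[dict]
    queen: dict | None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["q_by_k"] = {str(k): v for k, v in self.q_by_k.items()}
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1,
                          allow_nan=True, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ColonyReport":
        d = json.loads(Path(path).read_text())
        d["q_by_k"] = {int(k): v for k, v in d["q_by_k"].items()}
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _nan_to_none(x):
    if x is None:
        return None
    x = float(x)
    return x if np.isfinite(x) else None


def run_colony(data: ColonyData, config: PipelineConfig) -> ColonyReport:
    """Run the full per-colony analysis.

    Stage order: exclusion filter -> network -> soft communities (k range)
    -> permutation test -> maturity and summary metrics -> queen kinetics.
    Stage failures are recorded as flags and leave the affected fields
    empty rather than aborting the whole report.
    """
    flags: list[str] = []
    rng = np.random.default_rng(config.seed)

    # -- exclusion filter --------------------------------------------------
    excluded: set = set()
    meta = data.metadata
    if (
        config.apply_low_detection_filter
        and meta is not None
        and "detection_count" in meta.columns
        and meta["detection_count"].notna().all()
    ):
        excluded = tracking.low_detection_filter(meta["detection_count"])
    net = build_network(
        data.edge_counts, metadata=meta, excluded=excluded,
        colony=data.colony_id, species=data.species,
    )
    queen_id = net.queen_id
    if queen_id is None:
        flags.append("queen_absent_or_excluded")

    # -- communities -------------------------------------------------------
    ks = config.ks if config.run_profile else (2,)
    profile = community.modularity_profile(
        net, ks=ks, n_restarts=config.n_restarts, tol=config.tol,
        max_iter=config.max_iter, seed=rng,
    )
    if not profile.partitions[2].converged:
        flags.append("k2_fit_not_converged")

    permutation = None
    if config.run_permutation:
        res = community.modularity_permutation_test(
            net, k=2, n_rewires=config.n_rewires, seed=rng,
            n_restarts=config.n_restarts, tol=config.tol,
            max_iter=config.max_iter, n_swap_multiplier=config.n_swap_multiplier,
            rewire_strategy=config.rewire_strategy,
        )
        if res.flags.get("degenerate"):
            flags.append("permutation_degenerate")
        permutation = {
            "q_obs": _nan_to_none(res.q_obs),
            "p": res.p_value,
            "n_rewires": res.n_rewires,
            "null_mean": _nan_to_none(np.mean(res.null_q)) if res.null_q.size else None,
            "null_sd": _nan_to_none(np.std(res.null_q, ddof=1))
            if res.null_q.size > 1 else None,
        }

    # -- maturity ----------------------------------------------------------
    part2 = profile.partitions[2]
    fp = pd.Series(net.foraging_proportion, index=pd.Index(net.ids, name="ant_id"))
    if queen_id is not None:
        maturity = community.social_maturity(part2, queen_id)
    else:
        maturity = community.social_maturity_by_foraging(part2, fp)
        flags.append("maturity_oriented_by_foraging")

    # -- per-ant metrics ---------------------------------------------------
    ids = net.ids
    strengths = net.strengths()
    entropies = np.array(
        [
            metrics.node_entropy(np.delete(net.W[i], i))
            for i in range(net.n_nodes)
        ]
    )
    try:
        z_strength = metrics.z_normalize(strengths)
        z_entropy = metrics.z_normalize(entropies)
    except DegenerateGroupError:
        flags.append("degenerate_z_normalization")
        z_strength = np.full(net.n_nodes, np.nan)
        z_entropy = np.full(net.n_nodes, np.nan)

    homerange_prop = np.full(net.n_nodes, np.nan)
    if config.run_home_ranges and data.detections is not None and len(data.detections):
        nest = data.detections[data.detections["arena"] == "nest"]
        if config.arena_dims is not None:
            width, height = config.arena_dims
            origin = (0.0, 0.0)
        else:
            width = float(nest["x"].max() - nest["x"].min()) or 1.0
            height = float(nest["y"].max() - nest["y"].min()) or 1.0
            origin = (float(nest["x"].min()), float(nest["y"].min()))
        grid = metrics.HexGrid(
            width=width, height=height, body_length=config.body_length,
            circumradius=config.hex_circumradius, origin=origin,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, ant in enumerate(ids):
                sub = nest[nest["ant_id"] == ant]
                if len(sub):
                    hr = metrics.home_range_90(
                        sub, grid, ant_id=ant, coverage=config.coverage
                    )
                    homerange_prop[i] = hr.proportion_of_arena

    is_queen = net.is_queen
    per_ant = pd.DataFrame(
        {
            "ant_id": ids,
            "is_queen": is_queen.astype(bool),
            "maturity": maturity.reindex(ids).to_numpy(),
            "strength": strengths,
            "z_strength": z_strength,
            "entropy": entropies,
            "z_entropy": z_entropy,
            "foraging_proportion": fp.reindex(ids).to_numpy(),
            "homerange_prop": homerange_prop,
        }
    )

    # -- colony-level statistics (workers only) ----------------------------
    workers = per_ant[~per_ant["is_queen"]]
    dol = None
    if workers["foraging_proportion"].notna().all() and len(workers) >= 2:
        dol = metrics.division_of_labour(workers["foraging_proportion"])
    else:
        flags.append("dol_unavailable")
    maturity_stats = metrics.maturity_distribution_stats(workers["maturity"])

    # -- queen kinetics ----------------------------------------------------
    queen = None
    hc = data.hourly_contacts
    if hc is None and data.events is not None and queen_id is not None:
        hc = queen_kinetics.bin_queen_contacts(
            data.events, queen_id, hour_length_s=config.hour_length_s
        )
    if queen_id is not None:
        qrow = per_ant[per_ant["is_queen"]].iloc[0]
        queen = {
            "queen_id": str(queen_id),
            "z_strength": _nan_to_none(qrow["z_strength"]),
            "z_entropy": _nan_to_none(qrow["z_entropy"]),
            "maturity": _nan_to_none(qrow["maturity"]),
        }
        if hc is not None and hc.n_hours >= 2:
            n_workers = int((~per_ant["is_queen"]).sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                queen.update(
                    {
                        "workers_per_hour": _nan_to_none(
                            queen_kinetics.workers_per_hour(hc, n_workers)
                        ),
                        "contacts_per_worker_per_hour": _nan_to_none(
                            queen_kinetics.contacts_per_worker_per_hour(hc)
                        ),
                        "identity_conservation": _nan_to_none(
                            queen_kinetics.identity_conservation(hc)
                        ),
                    }
                )

    per_ant_records = [
        {
            k: (bool(v) if k == "is_queen" else str(v) if k == "ant_id"
                else _nan_to_none(v))
            for k, v in row.items()
        }
        for row in per_ant.to_dict(orient="records")
    ]
    return ColonyReport(
        colony_id=data.colony_id,
        species=data.species,
        n_ants=net.n_nodes,
        excluded=sorted(str(a) for a in excluded),
        q_by_k={int(k): v for k, v in profile.q_by_k.items()},
        argmax_k=int(profile.argmax_k),
        permutation=permutation,
        dol=_nan_to_none(dol) if dol is not None else None,
        maturity_stats={
            k: (_nan_to_none(v) if isinstance(v, float) else v)
            for k, v in maturity_stats.items()
        },
        per_ant=per_ant_records,
        queen=queen,
        flags=flags,
    )


@dataclass
class CohortReport:
    colonies: list[ColonyReport]
    modularity_dol: dict | None
    group_comparisons: dict
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "colonies": [c.to_dict() for c in self.colonies],
            "modularity_dol": self.modularity_dol,
            "group_comparisons": self.group_comparisons,
            "flags": self.flags,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1,
                          default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_cohort(datasets: list[ColonyData], config: PipelineConfig) -> CohortReport:
    """Analyse many colonies and add cross-colony statistics.

    The Pearson correlation between Q(k=2) and division of labour is
    reported when at least 3 colonies have both defined (omitted with a
    flag otherwise); queen z-scores are compared to worker z-scores with
    Welch t-tests within each species group.
    """
    flags: list[str] = []
    reports = []
    rng = np.random.default_rng(config.seed)
    for data in datasets:
        sub = config.with_overrides(seed=int(rng.integers(0, 2**31 - 1)))
        reports.append(run_colony(data, sub))

    qs = np.array([r.q_by_k.get(2, np.nan) for r in reports], dtype=float)
    dols = np.array(
        [r.dol if r.dol is not None else np.nan for r in reports], dtype=float
    )
    ok = np.isfinite(qs) & np.isfinite(dols)
    modularity_dol = None
    if ok.sum() >= 3 and np.ptp(qs[ok]) > 0 and np.ptp(dols[ok]) > 0:
        r, p = stats.pearsonr(qs[ok], dols[ok])
        modularity_dol = {"r": float(r), "p": float(p), "n": int(ok.sum())}
    else:
        flags.append("modularity_dol_correlation_omitted")

    groups: dict[str, dict] = {}
    by_group: dict[str, list[ColonyReport]] = {}
    for r in reports:
        by_group.setdefault(r.species or "all", []).append(r)
    for g, rs in sorted(by_group.items()):
        queen_zs = {"z_strength": [], "z_entropy": []}
        worker_zs = {"z_strength": [], "z_entropy": []}
        for r in rs:
            for row in r.per_ant:
                target = queen_zs if row["is_queen"] else worker_zs
                for key in target:
                    if row[key] is not None:
                        target[key].append(row[key])
        comp = {}
        for key in ("z_strength", "z_entropy"):
            if len(queen_zs[key]) >= 2 and len(worker_zs[key]) >= 2:
                t, p = stats.ttest_ind(
                    queen_zs[key], worker_zs[key], equal_var=False
                )
                comp[key] = {
                    "t": float(t), "p": float(p),
                    "queen_mean": float(np.mean(queen_zs[key])),
                    "worker_mean": float(np.mean(worker_zs[key])),
                    "n_queens": len(queen_zs[key]),
                }
            else:
                comp[key] = None
        groups[g] = comp
    return CohortReport(
        colonies=reports, modularity_dol=modularity_dol,
        group_comparisons=groups, flags=flags,
    )


# -- report schema ---------------------------------------------------------

REPORT_SCHEMA = {
    "colony_id": (str, type(None)),
    "species": (str, type(None)),
    "n_ants": int,
    "excluded": list,
    "q_by_k": dict,
    "argmax_k": (int, type(None)),
    "permutation": (dict, type(None)),
    "dol": (float, type(None)),
    "maturity_stats": (dict, type(None)),
    "per_ant": list,
    "queen": (dict, type(None)),
    "flags": list,
}


def validate_report(report: dict) -> None:
    """Check a colony report dict against the report schema.

    Raises :class:`AntnetError` on missing keys, wrong types, or non-finite
    numbers that are not explicit nulls.
    """
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise AntnetError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise AntnetError(f"report key {key!r} has type {type(report[key])}")
    for k, v in report["q_by_k"].items():
        if v is not None and not np.isfinite(v):
            raise AntnetError(f"non-finite modularity at k={k}")
    for row in report["per_ant"]:
        for key, v in row.items():
            if isinstance(v, float) and not np.isfinite(v):
                raise AntnetError(f"non-finite per-ant value {key}")
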