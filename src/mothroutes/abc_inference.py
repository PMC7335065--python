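"""Coalescent simulation of the three invasion scenarios and ABC inference.

The invasion history of the cactus moth is modeled as a chain of founder
events: a native Argentinian source (Ayuí) seeds an unsampled "ghost"
population (the Australia/South Africa biological-control step), which seeds
Antigua, then La Romana (Dominican Republic), then Santiago (Cuba); the
three competing scenarios differ only in how Highlands (Florida) was
founded — from Cuba (scenario 1), from the Dominican Republic (scenario 2),
or as an admixture of both (scenario 3, rate ``r5`` = proportion of
Highlands lineages drawn from La Romana).  Every founding passes through a
bottleneck of ``n_b`` founders lasting ``db`` generations.

Scenario choice follows the rejection + polychotomous-logistic-regression
recipe: simulate a reference table of summary statistics under each
scenario's priors, retain the simulations closest to the observed vector
(default 1%), and read the scenario posterior probabilities off a
multinomial logistic regression evaluated at the observed point.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _coalsim
from .genotype_data import GenotypeDataset, LocusInfo

__all__ = [
    "Deme",
    "Founding",
    "ScenarioSpec",
    "PriorSpec",
    "MutationModel",
    "ReferenceTable",
    "DEFAULT_LOCI",
    "builtin_scenarios",
    "config_document",
    "default_priors",
    "default_mutation_config",
    "sample_priors",
    "draw_mutation_model",
    "simulate_dataset",
    "summarize",
    "summary_stat_names",
    "build_reference_table",
    "simulate_pod",
    "scenario_choice",
    "estimate_parameters",
    "confusion_errors",
]


# Allele-size ranges (bp) of the ten retained dinucleotide loci.
DEFAULT_LOCI: list[LocusInfo] = [
    LocusInfo("cc11", 192, 234, 2),
    LocusInfo("cc12", 222, 286, 2),
    LocusInfo("cc13", 115, 149, 2),
    LocusInfo("cc15", 95, 119, 2),
    LocusInfo("cc3", 138, 164, 2),
    LocusInfo("cc4b", 80, 130, 2),
    LocusInfo("cc59", 101, 117, 2),
    LocusInfo("cc6", 119, 143, 2),
    LocusInfo("cc60", 85, 117, 2),
    LocusInfo("cc63", 130, 136, 2),
]


# ---------------------------------------------------------------------------
# Scenario and prior declarations


@dataclass(frozen=True)
class Deme:
    name: str
    sample_size: int = 0  # diploids; 0 = unsampled (ghost)

    @property
    def sampled(self) -> bool:
        return self.sample_size > 0


@dataclass(frozen=True)
class Founding:
    """Founding of ``deme`` from ``source`` at time parameter ``time``.

    When ``source_b`` is set the founding is an admixture event: each lineage
    of ``deme`` traces to ``source`` with probability given by ``rate``
    (parameter name), else to ``source_b``.  ``n_b``/``db`` name the
    founder-count and bottleneck-duration parameters.
    """

    deme: str
    source: str
    time: str
    n_b: str
    db: str
    source_b: str | None = None
    rate: str | None = None


@dataclass(frozen=True)
class ScenarioSpec:
    sid: int
    name: str
    demes: tuple[Deme, ...]
    foundings: tuple[Founding, ...]
    root: str  # native deme whose size changes to an ancestral size at T1
    root_time: str = "T1"
    root_size: str = "N_anc"

    def parameter_names(self) -> list[str]:
        names = [f"N_{d.name}" for d in self.demes] + [self.root_size, self.root_time]
        for f in self.foundings:
            names += [f.time, f.n_b, f.db]
            if f.rate:
                names.append(f.rate)
        # preserve order, drop duplicates (shared time parameters)
        seen: dict[str, None] = {}
        for n in names:
            seen.setdefault(n)
        return list(seen)

    def sampled_demes(self) -> list[Deme]:
        return [d for d in self.demes if d.sampled]

    def has_admixture(self) -> bool:
        return any(f.source_b for f in self.foundings)


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors: uniform, log-uniform, or fixed."""

    entries: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        for name, (shape, lo, hi) in self.entries.items():
            if shape not in ("uniform", "loguniform", "fixed"):
                raise ValueError(f"unknown prior shape {shape!r} for {name}")
            if lo > hi:
                raise ValueError(f"prior for {name} has min > max")
            if shape == "loguniform" and lo <= 0:
                raise ValueError(f"log-uniform prior for {name} needs min > 0")

    def draw(self, name: str, rng: np.random.Generator) -> float:
        if name not in self.entries:
            raise KeyError(f"no prior configured for parameter {name!r}")
        shape, lo, hi = self.entries[name]
        if shape == "fixed":
            return lo
        if shape == "uniform":
            return float(rng.uniform(lo, hi))
        return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))

    def bounds(self, name: str) -> tuple[str, float, float]:
        return self.entries[name]


@dataclass(frozen=True)
class MutationModel:
    """Generalized stepwise mutation model for one dataset.

    ``rates``: per-locus mutation rates (per locus per generation);
    ``p_geom``: geometric parameter of multi-step jumps (0 = strict SMM);
    allele-size bounds and motif come from the loci themselves.
    """

    rates: tuple[float, ...]
    p_geom: float
    loci: tuple[LocusInfo, ...]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.rates):
            raise ValueError("mutation rates must be positive")
        if not 0 <= self.p_geom < 1:
            raise ValueError("geometric parameter must be in [0, 1)")
        if len(self.rates) != len(self.loci):
            raise ValueError("one rate per locus required")

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates))


def default_mutation_config() -> dict:
    """Hyper-priors of the mutation model drawn once per simulated dataset."""
    return {
        "mu_mean_range": (1e-4, 1e-3),  # log-uniform mean rate
        "gamma_shape": 2.0,  # per-locus rate spread around the mean
        "p_geom_range": (0.1, 0.3),  # uniform geometric parameter
    }


def draw_mutation_model(
    loci: list[LocusInfo], rng: np.random.Generator, config: dict | None = None
) -> MutationModel:
    cfg = default_mutation_config()
    if config:
        cfg.update(config)
    lo, hi = cfg["mu_mean_range"]
    mu_bar = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    shape = cfg["gamma_shape"]
    rates = rng.gamma(shape, mu_bar / shape, size=len(loci))
    rates = np.clip(rates, 1e-8, None)
    p_lo, p_hi = cfg["p_geom_range"]
    p = float(rng.uniform(p_lo, p_hi))
    return MutationModel(tuple(float(r) for r in rates), p, tuple(loci))


# ---------------------------------------------------------------------------
# Built-in scenarios and priors


_DEMES = (
    Deme("Ayui", 24),
    Deme("ghost", 0),
    Deme("Antigua", 15),
    Deme("LaRomana", 20),
    Deme("Santiago", 29),
    Deme("Highlands", 15),
)

_CHAIN = (
    Founding("ghost", "Ayui", "Tg", "nb_ghost", "db_ghost"),
    Founding("Antigua", "ghost", "T2", "nb_Antigua", "db_Antigua"),
    Founding("LaRomana", "Antigua", "T3", "nb_LaRomana", "db_LaRomana"),
    Founding("Santiago", "LaRomana", "T4", "nb_Santiago", "db_Santiago"),
)


def builtin_scenarios() -> list[ScenarioSpec]:
    """The three competing invasion scenarios (Highlands founded from Cuba,
    from the Dominican Republic, or by admixture of both)."""
    s1 = ScenarioSpec(
        1,
        "florida-from-cuba",
        _DEMES,
        _CHAIN
        + (Founding("Highlands", "Santiago", "T5", "nb_Highlands", "db_Highlands"),),
        root="Ayui",
    )
    s2 = ScenarioSpec(
        2,
        "florida-from-hispaniola",
        _DEMES,
        _CHAIN
        + (Founding("Highlands", "LaRomana", "T5", "nb_Highlands", "db_Highlands"),),
        root="Ayui",
    )
    s3 = ScenarioSpec(
        3,
        "florida-admixture",
        _DEMES,
        _CHAIN
        + (
            Founding(
                "Highlands",
                "LaRomana",
                "T5",
                "nb_Highlands",
                "db_Highlands",
                source_b="Santiago",
                rate="r5",
            ),
        ),
        root="Ayui",
    )
    return [s1, s2, s3]


def default_priors() -> PriorSpec:
    entries: dict[str, tuple[str, float, float]] = {}
    for d in _DEMES:
        entries[f"N_{d.name}"] = ("uniform", 10, 3000)
    entries["N_anc"] = ("uniform", 10, 3000)
    for f in _CHAIN + (Founding("Highlands", "x", "T5", "nb_Highlands", "db_Highlands"),):
        entries[f.n_b] = ("loguniform", 2, 200)
        entries[f.db] = ("uniform", 1, 10)
    entries["T1"] = ("uniform", 200, 1000)
    entries["Tg"] = ("fixed", 172, 172)
    entries["T2"] = ("fixed", 104, 104)
    entries["T3"] = ("uniform", 80, 100)
    entries["T4"] = ("uniform", 64, 74)
    entries["T5"] = ("uniform", 44, 54)
    entries["r5"] = ("uniform", 0.1, 0.9)
    return PriorSpec(entries)


def config_document(
    scenarios: list[ScenarioSpec] | None = None,
    priors: PriorSpec | None = None,
    mutation_config: dict | None = None,
) -> dict:
    """Declarative scenario + prior + mutation configuration as one mapping
    (YAML-serializable); defaults to the three built-in invasion scenarios."""
    scenarios = scenarios if scenarios is not None else builtin_scenarios()
    priors = priors if priors is not None else default_priors()
    mut = default_mutation_config()
    if mutation_config:
        mut.update(mutation_config)
    doc: dict = {"scenarios": [], "priors": {}, "mutation": {
        "mu_mean_range": list(mut["mu_mean_range"]),
        "gamma_shape": mut["gamma_shape"],
        "p_geom_range": list(mut["p_geom_range"]),
        "loci": [
            {"name": l.name, "size_min": l.size_min, "size_max": l.size_max,
             "motif": l.motif}
            for l in DEFAULT_LOCI
        ],
    }}
    for s in scenarios:
        doc["scenarios"].append(
            {
                "id": s.sid,
                "name": s.name,
                "demes": [
                    {"name": d.name, "sample_size": d.sample_size} for d in s.demes
                ],
                "foundings": [
                    {k: v for k, v in {
                        "deme": f.deme, "source": f.source, "time": f.time,
                        "n_b": f.n_b, "db": f.db, "source_b": f.source_b,
                        "rate": f.rate,
                    }.items() if v is not None}
                    for f in s.foundings
                ],
                "root": {"deme": s.root, "time": s.root_time, "size": s.root_size},
            }
        )
        for name in s.parameter_names():
            shape, lo, hi = priors.bounds(name)
            doc["priors"][name] = {"shape": shape, "min": lo, "max": hi}
    return doc


def sample_priors(
    spec: ScenarioSpec, priors: PriorSpec, seed_or_rng
) -> dict[str, float]:
    """Draw one complete parameter set for ``spec`` (reproducible by seed)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return {name: priors.draw(name, rng) for name in spec.parameter_names()}


# ---------------------------------------------------------------------------
# Scenario compilation and simulation


def _compile_events(spec: ScenarioSpec, params: dict[str, float]):
    names = [d.name for d in spec.demes]
    idx = {n: i for i, n in enumerate(names)}
    sizes0 = np.array([float(params[f"N_{n}"]) for n in names])
    if (sizes0 <= 0).any() or params[spec.root_size] <= 0:
        raise ValueError("deme sizes must be positive at every epoch")
    events = []  # (time, kind, a, b, c, p)
    for f in spec.foundings:
        T = params[f.time]
        db = min(params[f.db], T - 1e-6)
        nb = max(params[f.n_b], 1.0)
        a = idx[f.deme]
        events.append((T - db, _coalsim.SIZE, a, 0, 0, nb))
        if f.source_b is None:
            events.append((T, _coalsim.MOVE, a, idx[f.source], 0, 0.0))
        else:
            r = params[f.rate]
            if not 0 < r < 1:
                raise ValueError("admixture rate must be in (0,1)")
            events.append((T, _coalsim.ADMIX, a, idx[f.source], idx[f.source_b], r))
    events.append((params[spec.root_time], _coalsim.SIZE, idx[spec.root], 0, 0,
                   float(params[spec.root_size])))
    events.sort(key=lambda e: (e[0], e[1] != _coalsim.SIZE))
    ev = list(zip(*events))
    return (
        sizes0,
        np.array(ev[0], dtype=np.float64),
        np.array(ev[1], dtype=np.int8),
        np.array(ev[2], dtype=np.int8),
        np.array(ev[3], dtype=np.int8),
        np.array(ev[4], dtype=np.int8),
        np.array(ev[5], dtype=np.float64),
    )


def _n_states(loci) -> np.ndarray:
    out = []
    for l in loci:
        if l.size_min is None or l.size_max is None:
            raise ValueError(f"locus {l.name} lacks an allele-size range")
        motif = l.motif or 2
        out.append((l.size_max - l.size_min) // motif + 1)
    return np.array(out, dtype=np.int64)


def _simulate_states(
    spec: ScenarioSpec, params: dict, mutation: MutationModel, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (geno_states (n_ind, L, 2) int32, deme index per individual
    over the *sampled* demes, in spec order)."""
    copies = np.array([2 * d.sample_size for d in spec.demes], dtype=np.int64)
    if copies.sum() == 0:
        raise ValueError("scenario has no sampled demes")
    sizes0, *ev = _compile_events(spec, params)
    mu = np.asarray(mutation.rates, dtype=np.float64)
    ns = _n_states(mutation.loci)
    states = _coalsim.sim_dataset_states(
        copies, sizes0, *ev, mu, mutation.p_geom, ns, seed & 0x7FFFFFFF
    )
    if states[0, 0] < 0 and (states < 0).all():
        raise RuntimeError(
            f"genealogy failed to coalesce for scenario {spec.sid} (seed {seed})"
        )
    n_ind = states.shape[0] // 2
    L = states.shape[1]
    geno = states.reshape(n_ind, 2, L).transpose(0, 2, 1).copy()
    deme_sizes = [d.sample_size for d in spec.demes if d.sampled]
    ind_deme = np.repeat(np.arange(len(deme_sizes)), deme_sizes).astype(np.int64)
    return geno, ind_deme


def simulate_dataset(
    spec: ScenarioSpec, params: dict, mutation: MutationModel, seed: int
) -> GenotypeDataset:
    """Simulate one microsatellite dataset under ``spec``; alleles in bp."""
    geno, ind_deme = _simulate_states(spec, params, mutation, seed)
    bp = geno.copy()
    for j, l in enumerate(mutation.loci):
        motif = l.motif or 2
        bp[:, j, :] = l.size_min + motif * geno[:, j, :]
    pops = [d.name for d in spec.sampled_demes()]
    return GenotypeDataset.from_arrays(bp, ind_deme, pops, list(mutation.loci))


def summary_stat_names(demes: list[str]) -> list[str]:
    names = []
    for d in demes:
        names += [f"na_{d}", f"he_{d}", f"var_{d}", f"mratio_{d}"]
    for i in range(len(demes)):
        for j in range(i + 1, len(demes)):
            names += [f"fst_{demes[i]}_{demes[j]}", f"dmu2_{demes[i]}_{demes[j]}"]
    return names


def summarize(ds: GenotypeDataset) -> np.ndarray:
    """Summary-statistic vector of a genotype dataset (fixed layout).

    Allele sizes are converted to repeat-unit states per locus before the
    variance/M-ratio/(delta mu)^2 statistics; loci without a declared range
    use their observed min and a motif of 2.
    """
    alleles, pop_idx = ds.to_arrays()
    L = ds.n_loci
    states = np.full_like(alleles, -1)
    ns = np.empty(L, dtype=np.int64)
    for j, l in enumerate(ds.loci):
        motif = l.motif or 2
        obs = alleles[:, j, :]
        present = obs > 0
        lo = l.size_min if l.size_min is not None else (obs[present].min() if present.any() else 0)
        states[:, j, :][present] = (obs[present] - lo) // motif
        hi = l.size_max if l.size_max is not None else (obs[present].max() if present.any() else lo)
        ns[j] = max((hi - lo) // motif + 1, int(states[:, j, :].max()) + 1, 2)
    return _coalsim.summary_stats(
        states.astype(np.int32), pop_idx.astype(np.int64), len(ds.populations), ns
    )


# ---------------------------------------------------------------------------
# Reference table


@dataclass
class ReferenceTable:
    scenario_ids: np.ndarray  # (n,)
    params: pd.DataFrame  # (n, union of parameter names), NaN where absent
    stats: np.ndarray  # (n, n_stats)
    stat_names: list[str]
    master_seed: int
    norm_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    norm_sd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.norm_mean is None:
            self.norm_mean = self.stats.mean(axis=0)
        if self.norm_sd is None:
            self.norm_sd = self.stats.std(axis=0)

    @property
    def n(self) -> int:
        return len(self.scenario_ids)

    def write(self, path) -> None:
        df = self.params.copy()
        df.insert(0, "scenario", self.scenario_ids)
        for k, name in enumerate(self.stat_names):
            df[name] = self.stats[:, k]
        df.to_csv(path, index=False)
        meta = {
            "master_seed": int(self.master_seed),
            "stat_names": self.stat_names,
            "param_names": list(self.params.columns),
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
        }
        with open(str(path) + ".meta.json", "wt") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, path) -> "ReferenceTable":
        with open(str(path) + ".meta.json", "rt") as fh:
            meta = json.load(fh)
        df = pd.read_csv(path)
        stats = df[meta["stat_names"]].values
        return cls(
            df["scenario"].values,
            df[meta["param_names"]],
            stats,
            meta["stat_names"],
            meta["master_seed"],
            np.array(meta["norm_mean"]),
            np.array(meta["norm_sd"]),
        )


def _row_rng(master_seed: int, scenario_id: int, row: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(scenario_id, row))
    )


def simulate_pod(
    spec: ScenarioSpec,
    priors: PriorSpec,
    seed: int,
    mutation_config: dict | None = None,
    loci: list[LocusInfo] | None = None,
) -> tuple[np.ndarray, dict]:
    """One pseudo-observed dataset: draw parameters and return (summary, params)."""
    rng = np.random.default_rng(seed)
    loci = list(loci) if loci is not None else list(DEFAULT_LOCI)
    params = sample_priors(spec, priors, rng)
    mut = draw_mutation_model(loci, rng, mutation_config)
    geno, ind_deme = _simulate_states(spec, params, mut, int(rng.integers(2**31)))
    stats = _coalsim.summary_stats(
        geno, ind_deme, len(spec.sampled_demes()), _n_states(mut.loci)
    )
    return stats, params


def build_reference_table(
    scenarios: list[ScenarioSpec],
    priors: PriorSpec,
    n_per_scenario: int,
    seed: int,
    mutation_config: dict | None = None,
    loci: list[LocusInfo] | None = None,
    workers: int = 1,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and summarize each.

    Deterministic for a given master seed regardless of ``workers``: every
    row's RNG stream is derived from (seed, scenario id, row index).
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    loci = list(loci) if loci is not None else list(DEFAULT_LOCI)
    demes = [d.name for d in scenarios[0].sampled_demes()]
    stat_names = summary_stat_names(demes)
    all_params = sorted({p for s in scenarios for p in s.parameter_names()})

    def one_row(spec: ScenarioSpec, row: int):
        rng = _row_rng(seed, spec.sid, row)
        params = sample_priors(spec, priors, rng)
        mut = draw_mutation_model(loci, rng, mutation_config)
        geno, ind_deme = _simulate_states(spec, params, mut, int(rng.integers(2**31)))
        stats = _coalsim.summary_stats(geno, ind_deme, len(demes), _n_states(loci))
        return params, stats

    jobs = [(spec, row) for spec in scenarios for row in range(n_per_scenario)]
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers, batch_size=256)(
            delayed(one_row)(spec, row) for spec, row in jobs
        )
    else:
        results = []
        it = jobs
        if progress:
            try:
                from tqdm import tqdm

                it = tqdm(jobs, desc="reference table")
            except ImportError:
                pass
        for spec, row in it:
            results.append(one_row(spec, row))

    sids = np.array([spec.sid for spec, _ in jobs])
    stats = np.vstack([s for _, s in results])
    pmat = pd.DataFrame(
        [{k: p.get(k, np.nan) for k in all_params} for p, _ in results],
        columns=all_params,
    )
    return ReferenceTable(sids, pmat, stats, stat_names, seed)


# ---------------------------------------------------------------------------
# Scenario choice and parameter estimation


def _normalize(ref: ReferenceTable, stats: np.ndarray):
    sd = ref.norm_sd.copy()
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance statistic columns")
    z = (stats[..., keep] - ref.norm_mean[keep]) / sd[keep]
    return z, keep


def _retained_indices(zref: np.ndarray, zobs: np.ndarray, retention: float):
    d2 = ((zref - zobs) ** 2).sum(axis=1)
    n_keep = int(math.ceil(retention * zref.shape[0]))
    order = np.lexsort((np.arange(len(d2)), d2))  # stable: distance, then row index
    return order[:n_keep], d2


def scenario_choice(
    ref: ReferenceTable,
    observed: np.ndarray,
    retention: float = 0.01,
    ridge: float = 1e-6,
) -> dict:
    """Posterior scenario probabilities by rejection and logistic regression.

    Statistics are z-scored with the reference table's own moments; the
    ``retention`` fraction of rows nearest (Euclidean) to the observed vector
    is kept.  ``direct`` = scenario frequencies among retained rows;
    ``logistic`` = multinomial logistic regression of scenario on the stat
    differences, evaluated at the observed point (difference zero).
    """
    if not 0 < retention <= 0.5:
        raise ValueError("retention must be in (0, 0.5]")
    if ref.n == 0:
        raise ValueError("empty reference table")
    zref, keep = _normalize(ref, ref.stats)
    zobs = (np.asarray(observed)[keep] - ref.norm_mean[keep]) / ref.norm_sd[keep]
    idx, _ = _retained_indices(zref, zobs, retention)
    sids = ref.scenario_ids[idx]
    all_sids = np.unique(ref.scenario_ids)
    direct = {int(s): float((sids == s).mean()) for s in all_sids}

    X = zref[idx] - zobs
    present = np.unique(sids)
    logistic = {int(s): 0.0 for s in all_sids}
    if len(present) == 1:
        logistic[int(present[0])] = 1.0
    else:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(
            C=1.0 / ridge / max(len(sids), 1), solver="lbfgs", max_iter=2000
        )
        clf.fit(X, sids)
        proba = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        for s, p in zip(clf.classes_, proba):
            logistic[int(s)] = float(p)
    return {
        "direct": direct,
        "logistic": logistic,
        "n_retained": int(len(idx)),
        "best": int(max(logistic, key=logistic.get)),
    }


def _transform(x: np.ndarray, shape: str, lo: float, hi: float):
    if shape == "fixed":
        return x, lambda y: y
    if shape == "loguniform":
        return np.log(x), np.exp
    # bounded uniform: logit transform keeps adjusted draws inside the prior
    span = hi - lo
    eps = 1e-9
    u = np.clip((x - lo) / span, eps, 1 - eps)
    fwd = np.log(u / (1 - u))

    def back(y):
        return lo + span / (1.0 + np.exp(-y))

    return fwd, back


def estimate_parameters(
    ref: ReferenceTable,
    observed: np.ndarray,
    scenario: int,
    priors: PriorSpec,
    retention: float = 0.01,
) -> pd.DataFrame:
    """Local-linear (Beaumont) regression-adjusted posterior summaries.

    Retained draws of the chosen scenario are weighted by an Epanechnikov
    kernel on their distance to the observed vector; each parameter is
    transformed (log for log-uniform, logit for bounded-uniform priors),
    regressed on the stat differences, adjusted to the observed point, and
    back-transformed.  Reports weighted median and 2.5/97.5 percentiles.
    """
    mask = ref.scenario_ids == scenario
    if not mask.any():
        raise ValueError(f"scenario {scenario} has no rows in the reference table")
    zref, keep = _normalize(ref, ref.stats)
    zobs = (np.asarray(observed)[keep] - ref.norm_mean[keep]) / ref.norm_sd[keep]
    zs = zref[mask]
    d2 = ((zs - zobs) ** 2).sum(axis=1)
    n_keep = int(math.ceil(retention * len(d2)))
    if n_keep < 20:
        raise ValueError("fewer than 20 retained rows; increase retention or table size")
    order = np.lexsort((np.arange(len(d2)), d2))[:n_keep]
    d = np.sqrt(d2[order])
    delta = d.max() if d.max() > 0 else 1.0
    w = 1.0 - (d / delta) ** 2
    w = np.clip(w, 1e-12, None)
    X = zs[order] - zobs
    Xd = np.column_stack([np.ones(len(order)), X])
    W = w

    params_sc = ref.params.loc[mask].reset_index(drop=True)
    rows = []
    for name in params_sc.columns:
        col = params_sc[name].values[order]
        if np.isnan(col).all():
            continue
        shape, lo, hi = priors.bounds(name)
        if shape == "fixed" or np.nanstd(col) == 0:
            rows.append((name, col[0], col[0], col[0]))
            continue
        y, back = _transform(col, shape, lo, hi)
        WX = Xd * W[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ Xd, WX.T @ y, rcond=None)
        fitted = Xd @ beta
        adjusted = beta[0] + (y - fitted)
        vals = back(adjusted)
        qs = _weighted_quantiles(vals, W, [0.025, 0.5, 0.975])
        rows.append((name, qs[1], qs[0], qs[2]))
    return pd.DataFrame(rows, columns=["parameter", "median", "q025", "q975"]).set_index(
        "parameter"
    )


def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs: list[float]) -> list[float]:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    cw = (cw - 0.5 * ws) / cw[-1]
    return [float(np.interp(q, cw, xs)) for q in qs]


# ---------------------------------------------------------------------------
# Error rates from pseudo-observed datasets


def confusion_errors(
    ref: ReferenceTable,
    scenarios: list[ScenarioSpec],
    priors: PriorSpec,
    focal_scenario: int,
    n_pods: int = 500,
    seed: int = 0,
    retention: float = 0.01,
    mutation_config: dict | None = None,
    loci: list[LocusInfo] | None = None,
    progress: bool = False,
) -> dict:
    """Type I and mean type II error of selecting ``focal_scenario``.

    Type I: fraction of pods simulated under the focal scenario for which it
    is not the highest-probability scenario.  Type II (per alternative):
    fraction of pods simulated under that alternative for which the focal
    scenario is selected; the mean over alternatives is reported.  Binomial
    standard errors accompany each rate.
    """
    if n_pods < 50:
        raise ValueError("n_pods must be >= 50")
    loci = list(loci) if loci is not None else list(DEFAULT_LOCI)
    by_sid = {s.sid: s for s in scenarios}
    focal = by_sid[focal_scenario]

    def pods_for(spec: ScenarioSpec, tag: int) -> np.ndarray:
        out = np.empty((n_pods, len(ref.stat_names)))
        it = range(n_pods)
        if progress:
            try:
                from tqdm import tqdm

                it = tqdm(it, desc=f"pods s{spec.sid}")
            except ImportError:
                pass
        for i in it:
            rng = _row_rng(seed, 1000 + tag, i)
            params = sample_priors(spec, priors, rng)
            mut = draw_mutation_model(loci, rng, mutation_config)
            geno, ind_deme = _simulate_states(
                spec, params, mut, int(rng.integers(2**31))
            )
            out[i] = _coalsim.summary_stats(
                geno, ind_deme, len(spec.sampled_demes()), _n_states(loci)
            )
        return out

    def selection_rate(stats: np.ndarray) -> float:
        hits = 0
        for row in stats:
            res = scenario_choice(ref, row, retention=retention)
            if res["best"] == focal_scenario:
                hits += 1
        return hits / len(stats)

    focal_stats = pods_for(focal, focal.sid)
    p_correct = selection_rate(focal_stats)
    type1 = 1.0 - p_correct
    type2 = {}
    for sid, spec in by_sid.items():
        if sid == focal_scenario:
            continue
        alt_stats = pods_for(spec, sid)
        type2[sid] = selection_rate(alt_stats)
    mean_type2 = float(np.mean(list(type2.values())))

    def se(p):
        return math.sqrt(p * (1 - p) / n_pods)

    return {
        "type1": type1,
        "type1_se": se(type1),
        "type2_by_scenario": type2,
        "mean_type2": mean_type2,
        "mean_type2_se": float(np.mean([se(p) for p in type2.values()])),
        "n_pods": n_pods,
    }
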