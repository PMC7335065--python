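"""Synthetic inputs with known ground truth for every pipeline stage.

No genotype data ships with this package; these generators produce
study-shaped datasets (12 demes, 10 dinucleotide loci, 229 diploids) from
the admixture invasion scenario, single-population Hardy–Weinberg fixtures
with planted inbreeding/null-allele/missingness defects, and
hurricane-incidence category rasters for the circuit-theory stage.  Every
generator is a pure function of (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abc_inference import (
    DEFAULT_LOCI,
    Deme,
    Founding,
    PriorSpec,
    ScenarioSpec,
    builtin_scenarios,
    default_priors,
    draw_mutation_model,
    sample_priors,
    simulate_dataset,
)
from .genotype_data import GenotypeDataset, Individual, LocusInfo

__all__ = [
    "TruthRecord",
    "study_like_scenario",
    "study_like_priors",
    "generate_study_like_dataset",
    "generate_hw_population",
    "generate_hurricane_raster",
]


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of a synthetic dataset: everything needed to regenerate it."""

    scenario: int
    params: dict
    mutation_rates: tuple
    p_geom: float
    seed: int


# Extra demes beyond the three-scenario core, attached as serial foundations
# from their nearest scenario deme.  This is a fixture convention to obtain a
# 12-deme, 229-individual dataset shaped like the study design — it makes no
# historical claim about these populations.  Founding-time priors sit safely
# below each source's own founding time.
_EXTRA_DEMES = [
    # (name, diploids, source, time prior (lo, hi))
    ("Yuqueri", 20, "Ayui", (180.0, 199.0)),
    ("Nevis", 6, "Antigua", (80.0, 102.0)),
    ("Guanica", 24, "LaRomana", (40.0, 78.0)),
    ("Palisadores", 14, "Santiago", (30.0, 62.0)),
    ("Trinidad", 30, "Santiago", (30.0, 62.0)),
    ("PinarDelRio", 30, "Trinidad", (10.0, 28.0)),
    ("LeeCo", 2, "Highlands", (10.0, 42.0)),
]


def study_like_scenario() -> ScenarioSpec:
    """Admixture scenario extended to all 12 sampled demes of the study design."""
    base = builtin_scenarios()[2]
    demes = list(base.demes)
    foundings = list(base.foundings)
    for name, n, source, _ in _EXTRA_DEMES:
        demes.append(Deme(name, n))
        foundings.append(Founding(name, source, f"T_{name}", f"nb_{name}", f"db_{name}"))
    return ScenarioSpec(
        base.sid, "study-like", tuple(demes), tuple(foundings), root=base.root
    )


def study_like_priors() -> PriorSpec:
    entries = dict(default_priors().entries)
    for name, _, _, (lo, hi) in _EXTRA_DEMES:
        entries[f"N_{name}"] = ("uniform", 10, 3000)
        entries[f"nb_{name}"] = ("loguniform", 2, 200)
        entries[f"db_{name}"] = ("uniform", 1, 10)
        entries[f"T_{name}"] = ("uniform", lo, hi)
    return PriorSpec(entries)


def generate_study_like_dataset(
    seed: int, config: dict | None = None
) -> tuple[GenotypeDataset, TruthRecord]:
    """A 12-population, 10-locus, 229-individual dataset with known truth.

    Simulated under the admixture scenario with serial founder bottlenecks;
    native demes therefore carry more diversity than the invaded chain.
    ``config`` may override ``priors``, ``loci`` or ``mutation`` settings.
    """
    cfg = config or {}
    spec = cfg.get("scenario") or study_like_scenario()
    priors = cfg.get("priors") or study_like_priors()
    loci = cfg.get("loci") or list(DEFAULT_LOCI)
    rng = np.random.default_rng(seed)
    params = sample_priors(spec, priors, rng)
    mutation = cfg.get("mutation") or draw_mutation_model(
        loci, rng, cfg.get("mutation_config")
    )
    ds = simulate_dataset(spec, params, mutation, int(rng.integers(2**31)))
    truth = TruthRecord(
        spec.sid, params, tuple(mutation.rates), mutation.p_geom, seed
    )
    return ds, truth


def generate_hw_population(
    allele_freqs: dict[int, float],
    n: int,
    fis: float = 0.0,
    null_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    n_loci: int = 1,
    locus_prefix: str = "loc",
    population: str = "pop1",
) -> GenotypeDataset:
    """Single population drawn from given allele frequencies with planted defects.

    Genotypes follow the inbreeding model P(aa) = p^2 + fis*p*(1-p),
    P(ab) = 2*p_a*p_b*(1-fis).  A null allele of frequency ``null_rate`` is
    added to the pool before drawing: null homozygotes become missing and
    null heterozygotes appear as visible homozygotes.  Random missingness is
    applied last.  All ``n_loci`` loci are iid copies of the same model.
    """
    if not -1 < fis < 1:
        raise ValueError("fis must be in (-1, 1)")
    for name, v in [("null_rate", null_rate), ("missing_rate", missing_rate)]:
        if not 0 <= v < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    freqs = dict(allele_freqs)
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    if any(a <= 0 for a in freqs):
        raise ValueError("allele sizes must be positive")
    # extend with the null allele (code 0) and rescale
    pool = {a: p * (1.0 - null_rate) for a, p in freqs.items()}
    if null_rate > 0:
        pool[0] = null_rate
    alleles = np.array(sorted(pool))
    p = np.array([pool[a] for a in alleles])
    # genotype distribution under inbreeding
    probs = np.outer(p, p) * (1.0 - fis) + np.diag(p) * fis
    if (np.diag(probs) < -1e-12).any():
        raise ValueError(f"fis={fis} infeasible for the given frequencies")
    pairs = [(i, j) for i in range(len(alleles)) for j in range(len(alleles))]
    pvec = np.clip(probs.ravel(), 0, None)
    pvec /= pvec.sum()

    rng = np.random.default_rng(seed)
    inds = []
    for i in range(n):
        genos: list[tuple[int, int] | None] = []
        for _ in range(n_loci):
            k = rng.choice(len(pairs), p=pvec)
            a, b = alleles[pairs[k][0]], alleles[pairs[k][1]]
            if a == 0 and b == 0:
                genos.append(None)  # null homozygote drops out
            elif a == 0 or b == 0:
                v = int(max(a, b))
                genos.append((v, v))  # null heterozygote looks homozygous
            else:
                genos.append((int(a), int(b)))
            if missing_rate > 0 and rng.random() < missing_rate:
                genos[-1] = None
        inds.append(Individual(f"{population}_{i + 1}", genos))
    loci = [LocusInfo(f"{locus_prefix}{j + 1}") for j in range(n_loci)]
    return GenotypeDataset(loci, [population], [inds])


def generate_hurricane_raster(
    n_rows: int,
    n_cols: int,
    gradient_axis: str = "col",
    seed: int = 0,
    noise: float = 0.15,
    n_mask_blocks: int = 0,
) -> np.ndarray:
    """Hurricane-incidence category raster (1..5; 0 = masked land).

    A monotone gradient along ``gradient_axis`` plus low-amplitude Gaussian
    noise, quantized into the five categories.  With ``noise=0`` categories
    are monotone along the gradient.  Optional rectangular masked blocks are
    kept off the first and last gradient-axis lines so corridor anchors stay
    placeable.
    """
    if n_rows < 4 or n_cols < 4:
        raise ValueError("raster must be at least 4x4")
    if gradient_axis not in ("row", "col"):
        raise ValueError("gradient_axis must be 'row' or 'col'")
    rng = np.random.default_rng(seed)
    ramp = np.linspace(0.0, 1.0, n_cols if gradient_axis == "col" else n_rows)
    field = np.tile(ramp, (n_rows, 1)) if gradient_axis == "col" else np.tile(
        ramp[:, None], (1, n_cols)
    )
    field = field + noise * rng.standard_normal((n_rows, n_cols))
    cats = 1 + np.clip((field * 5).astype(int), 0, 4)
    for _ in range(n_mask_blocks):
        h = int(rng.integers(1, max(2, n_rows // 4)))
        w = int(rng.integers(1, max(2, n_cols // 4)))
        r0 = int(rng.integers(1, n_rows - h))
        c0 = int(rng.integers(1, n_cols - w))
        cats[r0 : r0 + h, c0 : c0 + w] = 0
    return cats
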