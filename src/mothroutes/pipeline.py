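"""Pipeline orchestration and packaged study tables.

The package ships two transcribed data tables — population metadata
(coordinates, sample sizes) and the published pairwise-FST matrix — which
are the only real data it contains.  ``run_pipeline`` drives the stages
(stats -> QC -> FST -> IBD/IBR -> clustering -> ABC) over a config mapping
and writes every artifact with a seed/checksum manifest.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_data import GenotypeDataset, read_genepop, write_genepop
from .landscape_ibr import (
    build_conductance_grid,
    geographic_distance_matrix,
    linearize_fst,
    mantel_test,
    pairwise_resistance,
    partial_mantel_test,
)
from .popgen_stats import DistanceMatrix, diversity_table, locus_qc_filter, pairwise_fst, subset_loci

__all__ = [
    "load_populations",
    "load_published_fst",
    "published_fst_summaries",
    "ibd_mantel",
    "run_pipeline",
]

NATIVE_POPULATIONS = ("Ayui", "Yuqueri")


def _norm(label: str) -> str:
    """Normalize population labels ('Pinar del Rio' == 'PinarDelRio' == 'pinar del rio')."""
    return "".join(ch for ch in label.lower() if ch.isalnum())


def published_coordinates(labels) -> dict[str, tuple[float, float]]:
    """Map the given labels to published (lat, lon), tolerant of spelling."""
    pops = load_populations()
    by_norm = {_norm(r.label): (r.lat, r.lon) for r in pops.itertuples()}
    return {l: by_norm[_norm(l)] for l in labels if _norm(l) in by_norm}


def load_populations() -> pd.DataFrame:
    """Published population metadata: label, status, lat/lon, sample size."""
    with resources.files("mothroutes.data").joinpath("populations.csv").open() as fh:
        return pd.read_csv(fh)


def load_published_fst() -> DistanceMatrix:
    """The published pairwise-FST matrix over the 12 populations."""
    path = resources.files("mothroutes.data").joinpath("pairwise_fst.csv")
    with resources.as_file(path) as p:
        return DistanceMatrix.read(p)


def published_fst_summaries(
    fst: DistanceMatrix | str | Path | None = None,
    natives: tuple[str, ...] = NATIVE_POPULATIONS,
    reference_native: str = "Ayui",
) -> dict[str, float]:
    """Partition means of the published FST matrix.

    Returns the mean over native x invaded pairs, the mean over invaded x
    invaded pairs, and the mean of the reference native population's
    entries against all invaded populations, rounded to 3 decimals.
    """
    if fst is None:
        fst = load_published_fst()
    elif not isinstance(fst, DistanceMatrix):
        fst = DistanceMatrix.read(fst)
    expected = set(load_published_fst().labels)
    unexpected = set(fst.labels) ^ expected
    if unexpected:
        raise ValueError(f"unexpected population labels: {sorted(unexpected)}")
    invaded = [l for l in fst.labels if l not in natives]
    v = fst.to_dataframe()
    nat_inv = [v.loc[a, b] for a in natives for b in invaded]
    inv_inv = [
        v.loc[invaded[i], invaded[j]]
        for i in range(len(invaded))
        for j in range(i + 1, len(invaded))
    ]
    ref_inv = [v.loc[reference_native, b] for b in invaded]
    return {
        "mean_native_invaded": round(float(np.mean(nat_inv)), 3),
        "mean_within_invaded": round(float(np.mean(inv_inv)), 3),
        "mean_reference_native_invaded": round(float(np.mean(ref_inv)), 3),
    }


def ibd_mantel(
    fst: DistanceMatrix | None = None,
    labels: list[str] | None = None,
    method: str = "planar",
    log_base: str = "ln",
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Isolation-by-distance Mantel test on the published tables.

    Linearized FST (x/(1-x)) against log geographic distances over the
    invaded populations (all ten by default).
    """
    pops = load_populations()
    if fst is None:
        fst = load_published_fst()
    if labels is None:
        labels = [
            r.label for r in pops.itertuples() if r.status == "invaded"
        ]
    coords = {r.label: (r.lat, r.lon) for r in pops.itertuples() if r.label in labels}
    gen = linearize_fst(fst.submatrix(labels))
    geo = geographic_distance_matrix(coords, method=method).submatrix(labels)
    logged = _log_offdiag(geo.values, log_base)
    return mantel_test(gen, DistanceMatrix(labels, logged), n_perm=n_perm, seed=seed)


def _log_offdiag(values: np.ndarray, log_base: str = "ln") -> np.ndarray:
    off = ~np.eye(values.shape[0], dtype=bool)
    if (values[off] <= 0).any():
        raise ValueError("zero geographic distance: log undefined")
    out = np.zeros_like(values)
    out[off] = np.log(values[off]) if log_base == "ln" else np.log10(values[off])
    return out


# ---------------------------------------------------------------------------
# End-to-end driver


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the enabled stages over a config mapping; returns the manifest.

    Config keys (all optional, with sensible defaults):
    ``seed``; ``genepop`` (input path; otherwise a synthetic study-like
    dataset is generated); ``stages`` (list drawn from stats, qc, fst, ibd,
    ibr, structure, abc); per-stage parameter blocks ``qc``, ``ibd``,
    ``ibr``, ``structure``, ``abc``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["stats", "qc", "fst", "ibd"])
    manifest: dict = {"seed": seed, "version": __version__, "stages": list(stages),
                      "inputs": {}, "outputs": {}}

    if config.get("genepop"):
        src = Path(config["genepop"])
        ds = read_genepop(src)
        manifest["inputs"]["genepop"] = {"path": str(src), "sha256": _sha256(src)}
    else:
        from .synthetic_data import generate_study_like_dataset

        ds, truth = generate_study_like_dataset(seed)
        gp = out / "synthetic_dataset.gen"
        write_genepop(ds, gp)
        manifest["inputs"]["synthetic"] = {"seed": seed, "scenario": truth.scenario}
        manifest["outputs"]["dataset"] = str(gp)

    def emit(name: str, path: Path):
        manifest["outputs"][name] = str(path)

    if "stats" in stages:
        div = diversity_table(ds)
        p = out / "diversity.csv"
        div.means.to_csv(p)
        div.per_locus.to_csv(out / "diversity_per_locus.csv")
        emit("diversity", p)

    if "qc" in stages:
        qc_cfg = config.get("qc", {})
        retained = locus_qc_filter(
            ds,
            null_threshold=qc_cfg.get("null_threshold", 0.20),
            hwe_alpha=qc_cfg.get("hwe_alpha", 0.05),
            min_pop_fraction=qc_cfg.get("min_pop_fraction", 0.5),
            n_mc=qc_cfg.get("n_mc", 2000),
            seed=seed,
        )
        ds = subset_loci(ds, retained)
        p = out / "retained_loci.txt"
        p.write_text("\n".join(retained) + "\n")
        emit("retained_loci", p)

    fst = None
    if "fst" in stages or "ibd" in stages or "ibr" in stages:
        fst = pairwise_fst(ds)
        p = out / "fst.csv"
        fst.write(p)
        fst.write(out / "fst_lower.csv", form="lower")
        emit("fst", p)

    if "ibd" in stages:
        ibd_cfg = config.get("ibd", {})
        coords = ibd_cfg.get("coords") or published_coordinates(fst.labels)
        labels = [l for l in fst.labels if l in coords]
        gen = linearize_fst(fst.submatrix(labels))
        geo = geographic_distance_matrix(
            {l: coords[l] for l in labels}, method=ibd_cfg.get("method", "planar")
        )
        vals = _log_offdiag(geo.values)
        res = mantel_test(
            gen,
            DistanceMatrix(labels, vals),
            n_perm=ibd_cfg.get("n_perm", 10_000),
            seed=seed,
        )
        p = out / "ibd.json"
        p.write_text(json.dumps({"r": res.r, "p": res.p, "n_perm": res.n_perm}, indent=1))
        emit("ibd", p)

    if "ibr" in stages:
        ibr_cfg = config.get("ibr", {})
        from .landscape_ibr import read_ascii_grid
        from .synthetic_data import generate_hurricane_raster

        if ibr_cfg.get("raster"):
            raster = read_ascii_grid(ibr_cfg["raster"])
        else:
            raster = generate_hurricane_raster(24, 36, seed=seed)
        anchors = ibr_cfg.get("anchors")
        if anchors is None:
            # spread anchors along the gradient for the synthetic raster
            labels = list(fst.labels)
            cols = np.linspace(1, raster.shape[1] - 2, len(labels)).astype(int)
            rows_ = np.linspace(1, raster.shape[0] - 2, len(labels)).astype(int)
            anchors = {l: (int(r), int(c)) for l, r, c in zip(labels, rows_, cols)}
        grid = build_conductance_grid(
            raster, anchors, ibr_cfg.get("mapping"), ibr_cfg.get("neighbors", 8)
        )
        resist = pairwise_resistance(grid)
        labels = [l for l in fst.labels if l in resist.labels]
        gen = linearize_fst(fst.submatrix(labels))
        coords = published_coordinates(labels)
        res_m = mantel_test(gen, resist.submatrix(labels), n_perm=ibr_cfg.get("n_perm", 10_000), seed=seed)
        outd = {"mantel_r": res_m.r, "mantel_p": res_m.p}
        if len(coords) == len(labels):
            geo = geographic_distance_matrix(coords, method="planar").submatrix(labels)
            vals = _log_offdiag(geo.values)
            pres = partial_mantel_test(
                gen,
                resist.submatrix(labels),
                DistanceMatrix(labels, vals),
                n_perm=ibr_cfg.get("n_perm", 10_000),
                seed=seed,
                conditioning_label="log_geographic_distance",
            )
            outd.update({"partial_r": pres.r, "partial_p": pres.p})
        p = out / "ibr.json"
        p.write_text(json.dumps(outd, indent=1))
        resist.write(out / "resistance.csv")
        emit("ibr", p)

    if "structure" in stages:
        from .structure_clustering import evanno_delta_k, run_admixture_mcmc

        st = config.get("structure", {})
        runs = []
        for K in range(st.get("k_min", 1), st.get("k_max", 4) + 1):
            for rep in range(st.get("replicates", 3)):
                runs.append(
                    run_admixture_mcmc(
                        ds,
                        K,
                        burn_in=st.get("burn_in", 2000),
                        iters=st.get("iters", 10_000),
                        thin=st.get("thin", 10),
                        seed=seed + 1000 * K + rep,
                    )
                )
        best = max(runs, key=lambda r: r.mean_ln_p)
        best.Q.to_csv(out / "q_matrix.csv", index=False)
        try:
            ev = evanno_delta_k(runs)
            ev.table.to_csv(out / "evanno.csv")
            manifest["selected_k"] = int(ev.selected_k)
        except ValueError:
            pass
        emit("structure", out / "q_matrix.csv")

    if "abc" in stages:
        from .abc_inference import (
            build_reference_table,
            builtin_scenarios,
            default_priors,
            scenario_choice,
            summarize,
        )

        abc_cfg = config.get("abc", {})
        scenarios = builtin_scenarios()
        priors = default_priors()
        ref = build_reference_table(
            scenarios,
            priors,
            n_per_scenario=abc_cfg.get("n_per_scenario", 2000),
            seed=seed,
        )
        ref.write(out / "reference_table.csv")
        sampled = [d.name for d in scenarios[0].sampled_demes()]
        if set(sampled) <= set(ds.populations):
            sub = _select_populations(ds, sampled)
            obs = summarize(sub)
            choice = scenario_choice(ref, obs, retention=abc_cfg.get("retention", 0.01))
            p = out / "scenario_choice.json"
            p.write_text(json.dumps(choice, indent=1))
            emit("abc_choice", p)
        emit("abc_reference", out / "reference_table.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _select_populations(ds: GenotypeDataset, labels: list[str]) -> GenotypeDataset:
    idx = [ds.population_index(l) for l in labels]
    return GenotypeDataset(
        ds.loci, [ds.populations[i] for i in idx], [ds.individuals[i] for i in idx]
    )
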