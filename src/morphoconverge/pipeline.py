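"""End-to-end workflow: ingest/simulate -> symmetric GPA -> size ANOVA ->
shape PCA/ANOVA on the full dataset (A) and the domestic-only subset (B)
-> convergence test. Writes per-stage CSV/JSON artifacts plus one
machine-readable run report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import convergence, landmark_io, ordination, perm_stats, superimposition
from .landmark_io import LandmarkDataset
from .synthetic import SimulationParams, simulate_dataset

logger = logging.getLogger(__name__)

DOMESTIC_LINEAGES = ("DE", "DL")


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("morphoconverge")
    except Exception:  # pragma: no cover
        return "unknown"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    Either the three input paths or ``simulate`` must be given. ``seed`` is
    mandatory; every permutation/randomization count must be >= 99.
    """

    seed: int
    outdir: str
    coords_path: str | None = None
    coords_schema: str = "long"
    meta_path: str | None = None
    pairs_path: str | None = None
    simulate: dict | None = None
    symmetric: bool = True
    tangent_projection: bool = False
    refit_dataset_b: bool = True
    n_perm: int = 999
    n_rand: int = 999

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_perm < 99 or self.n_rand < 99:
            raise ValueError("n_perm and n_rand must be >= 99")
        if self.simulate is None and self.coords_path is None:
            raise ValueError("either input paths or simulate params required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _anova_records(tab: perm_stats.AnovaTable) -> list[dict]:
    return tab.table.reset_index().to_dict(orient="records")


def _pairwise_records(res: perm_stats.PairwiseResult) -> dict:
    out = {"pairs": res.table.to_dict(orient="records"), "mode": res.mode}
    if res.group_variances:
        out["group_variances"] = res.group_variances
    return out


def _write_pca(pca: ordination.PcaResult, aligned, labels, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        pca.scores, columns=[f"PC{i + 1}" for i in range(pca.m)]
    ).assign(specimen_id=labels).to_csv(outdir / "scores.csv", index=False)
    pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(pca.m)], "var_prop": pca.var_prop}
    ).to_csv(outdir / "var_prop.csv", index=False)
    pd.DataFrame(pca.axes).to_csv(outdir / "axes.csv", index=False)


def _load_dataset(config: RunConfig) -> LandmarkDataset:
    if config.simulate is not None:
        params = (
            config.simulate
            if isinstance(config.simulate, SimulationParams)
            else SimulationParams(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        )
        dataset, _ = simulate_dataset(params)
        return dataset
    configs = landmark_io.read_landmarks_csv(config.coords_path, config.coords_schema)
    if config.meta_path is None:
        raise ValueError("meta_path is required when loading coordinates")
    meta = landmark_io.read_metadata(config.meta_path)
    symmetry = None
    if config.pairs_path is not None:
        pairs, midline = landmark_io.read_symmetry_table(config.pairs_path)
        k = configs[0].k
        claimed = {i for p in pairs for i in p} | set(midline)
        midline = sorted(set(midline) | (set(range(k)) - claimed))
        symmetry = landmark_io.SymmetryMap(tuple(pairs), tuple(midline))
    if config.symmetric and symmetry is None:
        raise ValueError("symmetric GPA requested but no pairs table given")
    return landmark_io.assemble_dataset(configs, meta, symmetry)


def _superimpose(dataset: LandmarkDataset, config: RunConfig):
    if config.symmetric:
        aligned = superimposition.symmetric_gpa(dataset)
    else:
        aligned = superimposition.gpa(dataset.coords)
    if config.tangent_projection:
        aligned = superimposition.project_to_tangent(aligned)
    return aligned


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run report dict.

    Stage order: load/simulate, symmetric GPA, log-CS ANOVA + pairwise size
    tests, full-dataset shape PCA, shape ANOVA + pairwise tests (Dataset A),
    domestic-only PCA + shape ANOVA (Dataset B), MCI randomization test.
    On a stage failure, partial outputs are kept alongside a FAILED marker
    naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"morphoconverge": _version(), "numpy": np.__version__},
        "config": {
            k: (asdict(v) if isinstance(v, SimulationParams) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
    }
    stage = "load"
    try:
        dataset = _stage(report, stage, lambda: _load_dataset(config))
        report["stages"]["load"]["n"] = dataset.n
        report["stages"]["load"]["k"] = dataset.k
        report["stages"]["load"]["input_hash"] = _hash_array(dataset.coords)

        stage = "gpa"
        aligned = _stage(report, stage, lambda: _superimpose(dataset, config))
        landmark_io.write_landmarks_csv(
            [
                landmark_io.LandmarkConfiguration(sid, aligned.coords[i], dataset.landmark_names)
                for i, sid in enumerate(dataset.specimen_ids)
            ],
            outdir / "aligned.csv",
            schema="long",
        )
        (outdir / "gpa_report.json").write_text(
            json.dumps(
                {
                    "n": aligned.n,
                    "k": aligned.k,
                    "symmetric": aligned.symmetric,
                    "iterations": aligned.n_iterations,
                    "final_change": aligned.final_change,
                },
                indent=2,
            )
        )
        report["stages"]["gpa"].update(
            {"iterations": aligned.n_iterations, "final_change": aligned.final_change}
        )

        factors = {"lineage": dataset.lineage, "period": dataset.period}

        stage = "size_anova"
        size_tab = _stage(
            report,
            stage,
            lambda: perm_stats.rrpp_anova(
                aligned.log_cs, factors, n_perm=config.n_perm, seed=config.seed
            ),
        )
        size_tab.table.to_csv(outdir / "anova_size.csv")
        size_means = perm_stats.pairwise_means(
            aligned.log_cs, dataset.lineage, dataset.period,
            n_perm=config.n_perm, seed=config.seed,
        )
        size_vars = perm_stats.pairwise_variances(
            aligned.log_cs, dataset.lineage, dataset.period,
            n_perm=config.n_perm, seed=config.seed,
        )
        pd.concat(
            [size_means.table.assign(mode="means"), size_vars.table.assign(mode="variances")]
        ).to_csv(outdir / "pairwise_size.csv", index=False)
        report["stages"]["size_anova"]["anova"] = _anova_records(size_tab)
        report["stages"]["size_anova"]["pairwise_means"] = _pairwise_records(size_means)
        report["stages"]["size_anova"]["pairwise_variances"] = _pairwise_records(size_vars)

        stage = "pca_full"
        pca_a = _stage(report, stage, lambda: ordination.shape_pca(aligned))
        _write_pca(pca_a, aligned, dataset.specimen_ids, outdir / "pca_full")
        group_labels = np.array(
            [f"{p} {g}" for g, p in zip(dataset.lineage, dataset.period)], dtype=object
        )
        means = ordination.group_mean_shapes(aligned, group_labels)
        landmark_io.write_landmarks_csv(
            [
                landmark_io.LandmarkConfiguration(lvl, shape, dataset.landmark_names)
                for lvl, shape in means.items()
            ],
            outdir / "pca_full" / "group_means.csv",
            schema="long",
        )
        report["stages"]["pca_full"]["var_prop"] = pca_a.var_prop[:10].tolist()

        stage = "shape_anova_A"
        shape_tab = _stage(
            report,
            stage,
            lambda: perm_stats.rrpp_anova(
                aligned.flat(), factors, n_perm=config.n_perm, seed=config.seed
            ),
        )
        shape_tab.table.to_csv(outdir / "anova_shape_A.csv")
        shape_means = perm_stats.pairwise_means(
            aligned.flat(), dataset.lineage, dataset.period,
            n_perm=config.n_perm, seed=config.seed,
        )
        shape_vars = perm_stats.pairwise_variances(
            aligned.flat(), dataset.lineage, dataset.period,
            n_perm=config.n_perm, seed=config.seed,
        )
        pd.concat(
            [shape_means.table.assign(mode="means"), shape_vars.table.assign(mode="variances")]
        ).to_csv(outdir / "pairwise_shape_A.csv", index=False)
        report["stages"]["shape_anova_A"]["anova"] = _anova_records(shape_tab)
        report["stages"]["shape_anova_A"]["pairwise_means"] = _pairwise_records(shape_means)
        report["stages"]["shape_anova_A"]["pairwise_variances"] = _pairwise_records(shape_vars)

        stage = "dataset_B"
        domestic = dataset.subset(np.isin(dataset.lineage, DOMESTIC_LINEAGES))
        if config.refit_dataset_b:
            aligned_b = _stage(report, stage, lambda: _superimpose(domestic, config))
        else:
            mask = np.isin(dataset.lineage, DOMESTIC_LINEAGES)
            aligned_b = superimposition.AlignedShapes(
                coords=aligned.coords[mask],
                consensus=aligned.coords[mask].mean(axis=0),
                centroid_sizes=aligned.centroid_sizes[mask],
                symmetric=aligned.symmetric,
            )
            report["stages"][stage] = {"status": "ok", "elapsed_s": 0.0}
        report["stages"]["dataset_B"]["refit"] = config.refit_dataset_b
        pca_b = ordination.shape_pca(aligned_b)
        _write_pca(pca_b, aligned_b, domestic.specimen_ids, outdir / "pca_domestic")
        report["stages"]["dataset_B"]["var_prop"] = pca_b.var_prop[:10].tolist()
        factors_b = {"lineage": domestic.lineage, "period": domestic.period}
        shape_tab_b = perm_stats.rrpp_anova(
            aligned_b.flat(), factors_b, n_perm=config.n_perm, seed=config.seed
        )
        shape_tab_b.table.to_csv(outdir / "anova_shape_B.csv")
        report["stages"]["dataset_B"]["anova"] = _anova_records(shape_tab_b)

        stage = "mci"
        result = _stage(
            report,
            stage,
            lambda: convergence.mci_test(
                aligned_b.coords,
                domestic.lineage,
                domestic.period,
                n_rand=config.n_rand,
                seed=config.seed,
            ),
        )
        mci_payload = {
            "mci": result.mci,
            "p": result.p,
            "null_mean": result.null_mean,
            "n_rand": result.n_rand,
            "seed": result.seed,
            "stratified": result.stratified,
            "null_values": result.null_values.tolist(),
        }
        (outdir / "mci.json").write_text(json.dumps(mci_payload, indent=2))
        report["stages"]["mci"].update(
            {k: mci_payload[k] for k in ("mci", "p", "null_mean", "n_rand")}
        )
    except PipelineError:
        (outdir / "FAILED").write_text(stage)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage(report: dict, name: str, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        report["stages"][name] = {"status": "FAILED", "error": str(exc)}
        logger.error("stage %s failed: %s", name, exc)
        raise PipelineError(name, exc) from exc
    elapsed = time.perf_counter() - t0
    report["stages"][name] = {"status": "ok", "elapsed_s": round(elapsed, 4)}
    logger.info("stage %s ok (%.3fs)", name, elapsed)
    return result
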