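"""End-to-end pipeline: chain every stage and write all artifacts.

Stage order: inputs -> path lengths -> distinctness/funnels -> theta
dissimilarity -> distance decay -> clustering/ANOSIM -> dbMEM/forward
selection -> dbRDA -> variation partitioning.  Every stage writes CSV (or
JSON) artifacts into the output directory and is recorded, with a sha256
checksum per file, in ``manifest.json``.

Seeding: one global seed in the config; each stochastic stage uses
``seed + offset`` with fixed documented offsets (funnel delta +10, funnel
lambda +11, bootstrap +20, anosim +30, selection env +40, selection mem
+41, partition +50) so stages stay reproducible independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assemblages import anosim, choose_k, pairwise_anosim, to_newick, ward_cluster
from .beta_decay import bootstrap_decay, fit_decay, geo_distance_matrix, pairs_long_form, theta_matrix
from .distinctness import build_funnel, classify_stations, distinctness_table
from .io import read_inputs, write_square_matrix
from .spatial_ordination import build_dbmem, dbrda, forward_select, variation_partition
from .synthetic_data import SyntheticScenario, default_scenario, gen_communities, gen_stations_env, gen_taxonomy
from .taxonomy import StepWeights, path_lengths

log = logging.getLogger("taxodist")

SEED_OFFSETS = {
    "funnel_delta": 10,
    "funnel_lambda": 11,
    "bootstrap": 20,
    "anosim": 30,
    "select_env": 40,
    "select_mem": 41,
    "partition": 50,
}


@dataclass
class PipelineConfig:
    """All pipeline settings; YAML-loadable, CLI-overridable."""

    taxonomy_path: str | None = None
    occurrence_path: str | None = None
    stations_path: str | None = None
    out_dir: str = "taxodist_out"
    simulate: bool = False  # generate inputs instead of reading them

    step_weights: StepWeights = field(default_factory=StepWeights)
    funnel_n_sim: int = 1000
    funnel_alpha: float = 0.05
    funnel_m_grid: list[int] | None = None
    decay_n_boot: int = 1000
    theta_form: str = "pooled"
    k_range: list[int] | None = None
    ward_method: str = "ward.D2"
    dbmem_truncation: float | None = None
    broad_mems: list[str] | None = None  # explicit broad-scale MEM names
    selection_alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "step_weights" in raw and isinstance(raw["step_weights"], dict):
            raw["step_weights"] = StepWeights(**raw["step_weights"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def split_broad_fine(
    selected_mems: list[str], retained: list[str], broad: list[str] | None = None
) -> tuple[list[str], list[str]]:
    """Split selected MEMs into broad- and fine-scale groups.

    Default: MEMs in the first half of the retained spectrum (lower
    index = broader scale) are broad, the rest fine.  An explicit
    ``broad`` list overrides.
    """
    if broad is not None:
        return (
            [m for m in selected_mems if m in broad],
            [m for m in selected_mems if m not in broad],
        )
    half = {m for m in retained[: max(1, len(retained) // 2)]}
    return (
        [m for m in selected_mems if m in half],
        [m for m in selected_mems if m not in half],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    t0 = time.time()

    def record(stage: str, files: dict[str, Path], **extra) -> None:
        manifest["stages"][stage] = {
            "files": {k: str(p) for k, p in files.items()},
            "sha256": {k: _sha256(p) for k, p in files.items()},
            "elapsed_s": round(time.time() - t0, 3),
            **extra,
        }

    def run(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, exc) from exc

    # 1. inputs -------------------------------------------------------------
    def _inputs():
        if config.simulate:
            scenario = default_scenario(seed=config.seed)
            taxonomy = gen_taxonomy(scenario)
            stations = gen_stations_env(scenario)
            community, _ = gen_communities(taxonomy, stations, scenario)
        else:
            taxonomy, community, stations = read_inputs(config)
        files = {
            "taxonomy": out / "taxonomy.csv",
            "occurrence": out / "occurrence.csv",
            "stations": out / "stations.csv",
        }
        taxonomy.to_csv(files["taxonomy"], index=False)
        community.to_csv(files["occurrence"])
        stations.to_csv(files["stations"])
        record("inputs", files, n_stations=len(community), n_species=community.shape[1])
        return taxonomy, community, stations

    taxonomy, community, stations = run("inputs", _inputs)

    # 2. path lengths -------------------------------------------------------
    def _paths():
        omega = path_lengths(taxonomy, config.step_weights)
        f = {"omega": out / "path_lengths.csv"}
        write_square_matrix(omega.to_frame(), f["omega"])
        record("path_lengths", f)
        return omega

    omega = run("path_lengths", _paths)

    # 3. distinctness + funnels --------------------------------------------
    def _distinct():
        table = distinctness_table(community, omega)
        m_grid = config.funnel_m_grid
        if m_grid is None:
            richness = sorted(set(table["S"][table["S"] >= 2].astype(int)))
            m_grid = sorted(set(richness) | {2, len(omega.species)})
        funnels = {}
        labels = {}
        for stat, offset in (("delta_plus", "funnel_delta"), ("lambda_plus", "funnel_lambda")):
            funnels[stat] = build_funnel(
                omega,
                statistic=stat,
                m_grid=m_grid,
                n_sim=config.funnel_n_sim,
                alpha=config.funnel_alpha,
                seed=config.seed + SEED_OFFSETS[offset],
            )
            labels[stat] = classify_stations(table, funnels[stat])
        result = table.join(
            pd.DataFrame(
                {f"{s}_funnel": lab for s, lab in labels.items()}
            )
        )
        files = {
            "distinctness": out / "distinctness.csv",
            "funnel_delta": out / "funnel_delta_plus.csv",
            "funnel_lambda": out / "funnel_lambda_plus.csv",
        }
        result.to_csv(files["distinctness"])
        funnels["delta_plus"].to_frame().to_csv(files["funnel_delta"], index=False)
        funnels["lambda_plus"].to_frame().to_csv(files["funnel_lambda"], index=False)
        record(
            "distinctness",
            files,
            n_sim=config.funnel_n_sim,
            alpha=config.funnel_alpha,
        )
        return result

    run("distinctness", _distinct)

    # 4. theta dissimilarity ------------------------------------------------
    def _theta():
        theta = theta_matrix(community, omega, form=config.theta_form)
        f = {"theta": out / "theta_plus.csv"}
        write_square_matrix(theta, f["theta"])
        record("theta", f)
        return theta

    theta = run("theta", _theta)

    # 5. distance decay -----------------------------------------------------
    def _decay():
        geo = geo_distance_matrix(stations)
        fit = fit_decay(theta, geo)
        fit = bootstrap_decay(
            fit, theta, geo,
            n_boot=config.decay_n_boot,
            seed=config.seed + SEED_OFFSETS["bootstrap"],
        )
        files = {
            "geo": out / "geo_distances.csv",
            "pairs": out / "decay_pairs.csv",
            "decay": out / "decay_fit.json",
        }
        write_square_matrix(geo, files["geo"])
        pairs_long_form(theta, geo).to_csv(files["pairs"], index=False)
        files["decay"].write_text(
            json.dumps(
                {
                    "a": fit.a,
                    "b": fit.b,
                    "ci_a": fit.ci_a,
                    "ci_b": fit.ci_b,
                    "n_boot": fit.n_boot,
                    "seed": fit.seed,
                    "n_degenerate_redraws": fit.n_degenerate_redraws,
                },
                indent=2,
            )
        )
        record("decay", files, n_boot=config.decay_n_boot)
        return geo, fit

    geo, decay_fit = run("decay", _decay)

    # 6. assemblages --------------------------------------------------------
    def _assemblages():
        clustering = ward_cluster(theta, method=config.ward_method)
        k_range = (
            range(config.k_range[0], config.k_range[1] + 1)
            if config.k_range
            else None
        )
        clustering = choose_k(clustering, theta, k_range)
        res_pairwise = pairwise_anosim(
            theta,
            clustering.labels,
            n_perm=config.n_perm,
            seed=config.seed + SEED_OFFSETS["anosim"],
        )
        counts = clustering.labels.value_counts()
        big = counts[counts >= 2].index
        testable = clustering.labels[clustering.labels.isin(big)]
        overall = None
        if len(big) >= 2:
            overall = anosim(
                theta.loc[testable.index, testable.index],
                testable,
                n_perm=config.n_perm,
                seed=config.seed + SEED_OFFSETS["anosim"],
            )
        else:
            log.warning("fewer than two non-singleton clusters; ANOSIM skipped")
        files = {
            "labels": out / "clusters.csv",
            "dendrogram": out / "dendrogram.nwk",
            "anosim": out / "anosim.csv",
        }
        clustering.labels.rename("cluster").to_csv(files["labels"])
        files["dendrogram"].write_text(to_newick(clustering))
        header = (
            pd.DataFrame(
                [("all", "all", overall.R, overall.p, overall.n_perm)],
                columns=["group_a", "group_b", "R", "p", "n_perm"],
            )
            if overall is not None
            else pd.DataFrame(columns=["group_a", "group_b", "R", "p", "n_perm"])
        )
        table = pd.concat([header, res_pairwise])
        table.to_csv(files["anosim"], index=False)
        record(
            "assemblages", files, k=clustering.k, n_perm=config.n_perm,
            silhouette={str(k): v for k, v in clustering.silhouette_by_k.items()},
        )
        return clustering

    clustering = run("assemblages", _assemblages)

    # 7. dbMEM + forward selection -----------------------------------------
    def _spatial():
        basis = build_dbmem(stations, truncation=config.dbmem_truncation)
        env_cols = [c for c in stations.columns if c not in ("latitude", "longitude")]
        env = stations[env_cols]
        env_z = (env - env.mean()) / env.std(ddof=0).replace(0, 1)
        sel_env = forward_select(
            theta, env_z,
            alpha=config.selection_alpha, n_perm=config.n_perm,
            seed=config.seed + SEED_OFFSETS["select_env"],
        )
        sel_mem = forward_select(
            theta, basis.retained_vectors(),
            alpha=config.selection_alpha, n_perm=config.n_perm,
            seed=config.seed + SEED_OFFSETS["select_mem"],
        )
        files = {
            "mem": out / "dbmem.csv",
            "selection": out / "forward_selection.csv",
        }
        basis.vectors.to_csv(files["mem"])
        parts = [
            t.assign(block=b)
            for t, b in ((sel_env.table, "environment"), (sel_mem.table, "dbmem"))
            if len(t)
        ]
        sel = (
            pd.concat(parts)
            if parts
            else pd.DataFrame(
                columns=["variable", "r2_cum", "adj_r2_cum", "p", "block"]
            )
        )
        sel.to_csv(files["selection"], index=False)
        record(
            "dbmem_selection", files,
            truncation_km=basis.truncation_km,
            retained=basis.retained,
            selected_env=sel_env.selected,
            selected_mem=sel_mem.selected,
            n_perm=config.n_perm,
        )
        return basis, env_z, sel_env, sel_mem

    basis, env_z, sel_env, sel_mem = run("dbmem_selection", _spatial)

    # 8. dbRDA --------------------------------------------------------------
    def _dbrda():
        constraints = pd.concat(
            [env_z[sel_env.selected], basis.vectors[sel_mem.selected]], axis=1
        )
        if constraints.shape[1] == 0:
            log.warning("no variables selected; using all env + retained MEMs")
            constraints = pd.concat([env_z, basis.retained_vectors()], axis=1)
        ord_res = dbrda(theta, constraints, n_perm=config.n_perm, seed=config.seed)
        files = {
            "sites": out / "dbrda_site_scores.csv",
            "biplot": out / "dbrda_biplot_scores.csv",
            "axes": out / "dbrda_axes.csv",
        }
        ord_res.site_scores.to_csv(files["sites"])
        ord_res.biplot_scores.to_csv(files["biplot"])
        pd.DataFrame(
            {
                "axis": [f"dbRDA{i + 1}" for i in range(len(ord_res.eigenvalues))],
                "eigenvalue": ord_res.eigenvalues,
                "percent_total": ord_res.axis_percent,
            }
        ).to_csv(files["axes"], index=False)
        record(
            "dbrda", files, r2=ord_res.r2, adj_r2=ord_res.adj_r2,
            p=ord_res.p, n_perm=config.n_perm,
        )
        return ord_res

    run("dbrda", _dbrda)

    # 9. variation partitioning --------------------------------------------
    def _partition():
        coords = stations[["longitude", "latitude"]]
        coords = coords - coords.mean()
        broad, fine = split_broad_fine(
            sel_mem.selected, basis.retained, config.broad_mems
        )
        blocks = {
            "env": env_z[sel_env.selected] if sel_env.selected else env_z,
            "coords": coords,
        }
        if broad:
            blocks["broad_mem"] = basis.vectors[broad]
        if fine:
            blocks["fine_mem"] = basis.vectors[fine]
        part = variation_partition(
            theta, blocks,
            n_perm=config.n_perm,
            seed=config.seed + SEED_OFFSETS["partition"],
        )
        files = {"partition": out / "variation_partition.csv"}
        part.fractions.to_csv(files["partition"])
        record(
            "partition", files,
            blocks={k: list(v.columns) for k, v in blocks.items()},
            n_perm=config.n_perm,
        )
        return part

    run("partition", _partition)

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
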