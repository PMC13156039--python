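"""End-to-end orchestration with a reproducible provenance manifest.

Stages run in order simulate -> qc -> de -> interactome -> module-score ->
compose. A single master seed (``PipelineParams.seed``) drives every source
of randomness through per-stage child streams, all tabular outputs are
written with fixed column order and 9-significant-digit floats, and the
manifest records a config snapshot plus a SHA-256 digest of every output,
so re-running with the same configuration reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import __version__
from . import composition as comp
from . import de as de_mod
from . import interactome as lr
from . import modules as mod_stats
from . import qc as qc_mod
from . import simulate as sim
from ._seeding import stage_rng
from .io import read_dataset
from .params import PipelineParams

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "de", "interactome", "module-score", "compose")

FLOAT_FORMAT = "%.9g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    params: PipelineParams | None = None,
    sim_config: sim.SimulationConfig | None = None,
    input_dir: str | Path | None = None,
    outdir: str | Path = "drgcomm_out",
    stages: tuple[str, ...] = ALL_STAGES,
    lr_reference: str | Path | None = None,
    modules_file: str | Path | None = None,
    interactome_timepoint: float = 0.5,
) -> dict:
    """Run the pipeline and return the manifest (also written to disk).

    Either ``sim_config`` (with the ``simulate`` stage) or ``input_dir``
    (an existing fixture directory) must provide the dataset. When
    simulating, a ligand-receptor reference and the planted module are
    derived from the ground truth unless files are given.
    """
    params = params or PipelineParams()
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture_dir = outdir / "fixture"

    simulate = "simulate" in stages
    if not simulate and input_dir is None and not fixture_dir.exists():
        raise ValueError("need either the simulate stage or an input_dir")
    # fail fast on missing inputs before any computation
    if "interactome" in stages and not simulate and lr_reference is None:
        src = Path(input_dir) if input_dir is not None else fixture_dir
        if not (src / "lr_reference.tsv").exists() and not (src / "truth.json").exists():
            raise ValueError(
                "interactome stage enabled but no ligand-receptor reference available"
            )

    manifest: dict = {
        "package": "drgcomm",
        "version": __version__,
        "seed": params.seed,
        "params": params.to_dict(),
        "sim_config": None,
        "stages": [],
    }
    outputs_of: dict[str, list[Path]] = {}

    def record(stage: str, paths: list[Path]) -> None:
        outputs_of[stage] = paths
        manifest["stages"].append(
            {"name": stage, "outputs": {p.name: _sha256(p) for p in sorted(paths)}}
        )

    truth: sim.GroundTruth | None = None
    adata: ad.AnnData

    if simulate:
        try:
            config = sim_config or sim.default_config()
            config = dataclasses.replace(config, seed=params.seed)
            manifest["sim_config"] = _config_snapshot(config)
            adata, truth = sim.simulate_dataset(config)
            paths = sim.write_fixture(adata, truth, fixture_dir, force=True)
            ref = sim.decoy_lr_reference(
                adata, truth, stage_rng(params.seed, "lr_reference")
            )
            ref_path = fixture_dir / "lr_reference.tsv"
            ref.to_csv(ref_path, sep="\t", index=False)
            paths.append(ref_path)
            record("simulate", paths)
        except Exception as e:  # noqa: BLE001 - stage-named propagation
            raise StageError("simulate", e) from e
    else:
        src = Path(input_dir) if input_dir is not None else fixture_dir
        adata = read_dataset(src)
        if (src / "truth.json").exists():
            truth = sim.read_truth(src)
        if lr_reference is None and (src / "lr_reference.tsv").exists():
            lr_reference = src / "lr_reference.tsv"

    if "qc" in stages:
        try:
            qc_table = qc_mod.compute_qc(adata, params)
            qc_path = outdir / "qc.tsv"
            qc_table.to_csv(qc_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
            control = adata[adata.obs["timepoint"].astype(float) == 0.0]
            clf = qc_mod.fit_prototype_classifier(control, params=params)
            labels = qc_mod.assign_labels(clf, adata, params)
            lab_path = outdir / "labels.tsv"
            labels.to_csv(lab_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
            record("qc", [qc_path, lab_path])
        except Exception as e:
            raise StageError("qc", e) from e

    de_tables: dict[tuple[str, float], pd.DataFrame] = {}
    if "de" in stages or "interactome" in stages:
        try:
            timepoints = sorted(t for t in adata.obs["timepoint"].astype(float).unique() if t > 0)
            cell_types = sorted(adata.obs["cell_type"].unique())
            de_timepoints = (
                timepoints if "de" in stages else [float(interactome_timepoint)]
            )
            frames = []
            for tp in de_timepoints:
                for ct in cell_types:
                    tab = de_mod.de_table(adata, ct, tp, 0.0, params)
                    de_tables[(ct, tp)] = tab
                    frames.append(tab)
            frames = [f for f in frames if len(f)]
            de_all = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            if len(de_all):
                de_all["selected_pseudobulk"] = de_all["adj_p"] < params.pseudobulk_adj_p_max
                de_all["selected_lr_candidate"] = (
                    (de_all["fold_change"] > params.lr_fold_min)
                    & (de_all["pct_expr_group"] > params.lr_pct_min)
                    & (de_all["p_value"] < params.lr_p_max)
                )
            if "de" in stages:
                de_path = outdir / "de_table.csv"
                _write_csv(de_all, de_path)
                record("de", [de_path])
        except Exception as e:
            raise StageError("de", e) from e

    if "interactome" in stages:
        try:
            if lr_reference is not None:
                ref = lr.read_lr_reference(lr_reference)
            elif truth is not None:
                ref = lr.validate_lr_reference(
                    sim.decoy_lr_reference(adata, truth, stage_rng(params.seed, "lr_reference"))
                )
            else:
                raise ValueError("no ligand-receptor reference available")
            tp = float(interactome_timepoint)
            tables_at_tp = {c: f for (c, t2), f in de_tables.items() if t2 == tp}
            activities = lr.score_timepoint(
                adata,
                tp,
                ref,
                params,
                stage_rng(params.seed, "interactome"),
                de_tables=tables_at_tp or None,
            )
            table = lr.interactome_table(activities)
            int_path = outdir / "interactome.csv"
            _write_csv(table, int_path)
            sankey = lr.sankey_export(activities)
            sankey_path = outdir / "sankey.json"
            sankey_path.write_text(json.dumps(sankey, indent=1, sort_keys=True))
            record("interactome", [int_path, sankey_path])
        except Exception as e:
            raise StageError("interactome", e) from e

    if "module-score" in stages:
        try:
            if modules_file is not None:
                modules = mod_stats.read_modules(modules_file)
            elif truth is not None and truth.module_genes:
                modules = [mod_stats.GeneModule(truth.module_name or "module", truth.module_genes)]
            else:
                modules = []
            rng = stage_rng(params.seed, "modules")
            perm_rng = stage_rng(params.seed, "permutation")
            score_rows, test_rows = [], []
            for mod in modules:
                scores = mod_stats.module_score(adata, mod, params, rng)
                scores.insert(1, "module", mod.name)
                score_rows.append(scores)
                groups = (
                    adata.obs["timepoint"].astype(float).to_numpy() > 0
                ).astype(int)
                if 0 < groups.sum() < groups.size:
                    vals = scores["scaled_score"].to_numpy()
                    obs_stat = abs(vals[groups == 1].mean() - vals[groups == 0].mean())
                    p = mod_stats.permutation_test(
                        vals, groups, params.n_permutations, perm_rng, params
                    )
                    test_rows.append(
                        (mod.name, int((groups == 0).sum()), int((groups == 1).sum()), obs_stat, p)
                    )
            scores_path = outdir / "module_scores.csv"
            _write_csv(
                pd.concat(score_rows, ignore_index=True)
                if score_rows
                else pd.DataFrame(columns=["cell_id", "module", "raw_score", "scaled_score"]),
                scores_path,
            )
            tests_path = outdir / "module_tests.csv"
            _write_csv(
                pd.DataFrame(
                    test_rows,
                    columns=["module", "n_control", "n_case", "observed_statistic", "p_value"],
                ),
                tests_path,
            )
            record("module-score", [scores_path, tests_path])
        except Exception as e:
            raise StageError("module-score", e) from e

    if "compose" in stages:
        try:
            table = comp.composition_table(adata.obs, "immune")
            comp_path = outdir / "composition.csv"
            _write_csv(table, comp_path)
            fc_rows = []
            for ct in sorted(table["cell_type"].unique()):
                for tp in sorted(table["timepoint"].unique()):
                    if tp == 0:
                        continue
                    try:
                        fc = comp.composition_fold_change(table, ct, tp, 0.0)
                    except ValueError:
                        continue
                    fc_rows.append(dataclasses.asdict(fc))
            fc_path = outdir / "fold_changes.csv"
            _write_csv(
                pd.DataFrame(
                    fc_rows,
                    columns=[
                        "cell_type", "timepoint", "reference_timepoint", "fraction",
                        "reference_fraction", "ratio", "ci_low", "ci_high",
                    ],
                ),
                fc_path,
            )
            record("compose", [comp_path, fc_path])
        except Exception as e:
            raise StageError("compose", e) from e

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_snapshot(config: sim.SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("module_program") is not None:
        d["module_program"] = dataclasses.asdict(config.module_program)
    d["planted_interactions"] = [dataclasses.asdict(pi) for pi in config.planted_interactions]
    return json.loads(json.dumps(d))
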