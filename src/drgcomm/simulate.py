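"""Synthetic DRG time-course scRNA-seq generator with planted effects.

Emulates the structure of a dorsal-root-ganglion single-cell time course
after autoantibody challenge: ~15 neuronal / non-neuronal / immune cell
types sampled at days 0, 0.25, 0.5, 1, 2, 12, 33 and 63, with

* gene-wise negative-binomial counts (log-normal gene-mean prior, shared
  dispersion, per-cell library-size factor),
* planted sender->receiver communication programs (ligand upregulated in the
  sender, receptor constitutively detectable in the receiver, target program
  upregulated in the receiver at the active timepoints),
* a transient interferon-stimulated-gene-like module induced in configured
  cell types at early timepoints,
* a monocyte influx among immune cells (baseline ~3.5% of immune cells,
  peaking at ~65% at 6-12 h),
* mitochondrial genes (``mt-`` prefix) plus a configurable fraction of
  damaged, high-mitochondrial-content cells for QC testing.

Every run emits a :class:`GroundTruth` record so downstream stages can be
tested for recovery without any external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as dio
from ._seeding import stage_rng

# (name, compartment); ordered so that truncated rosters stay useful:
# the first six types cover all three compartments and both monocyte and
# macrophage lineages.
CELL_TYPE_ROSTER: tuple[tuple[str, str], ...] = (
    ("Fibroblast", "non_neuronal"),
    ("Monocyte", "immune"),
    ("Macrophage", "immune"),
    ("Endothelial", "non_neuronal"),
    ("PEP1", "neuronal"),
    ("SatelliteGlia", "non_neuronal"),
    ("Tcell", "immune"),
    ("NP1", "neuronal"),
    ("Pericyte", "non_neuronal"),
    ("SchwannMyel", "non_neuronal"),
    ("Bcell", "immune"),
    ("NFH", "neuronal"),
    ("VSMC", "non_neuronal"),
    ("NK", "immune"),
    ("SchwannNonMyel", "non_neuronal"),
)

GLIAL_TYPES = {"SatelliteGlia", "SchwannMyel", "SchwannNonMyel"}

DEFAULT_TIMEPOINTS = (0.0, 0.25, 0.5, 1.0, 2.0, 12.0, 33.0, 63.0)


@dataclass(frozen=True)
class PlantedInteraction:
    """One sender->receiver communication program planted in the simulation."""

    sender: str
    receiver: str
    ligand: str
    receptor: str
    targets: tuple[str, ...]
    fold: float
    timepoints: tuple[float, ...]


@dataclass(frozen=True)
class ModuleProgram:
    """A transient gene module induced in given cell types and timepoints."""

    name: str
    genes: tuple[str, ...]
    fold: float
    timepoints: tuple[float, ...]
    cell_types: tuple[str, ...]


@dataclass
class SimulationConfig:
    """Stated world of the generator; defaults mirror the modeled study design."""

    n_cell_types: int = 15
    cells_per_type_per_timepoint: int = 40
    n_genes: int = 2000
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    baseline_mean_log: float = -0.5
    baseline_sigma_log: float = 1.5
    nb_dispersion: float = 2.0
    library_size_spread: tuple[float, float] = (0.5, 2.0)
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    module_program: ModuleProgram | None = None
    monocyte_fraction_baseline: float = 0.035
    monocyte_fraction_peak: float = 0.65
    monocyte_peak_timepoints: tuple[float, ...] = (0.25, 0.5)
    mito_gene_fraction: float = 0.05
    high_mito_cell_fraction: float = 0.05
    mito_boost: float = 30.0
    receptor_floor_mean: float = 1.0
    markers_per_type: int = 10
    marker_fold: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "monocyte_fraction_baseline",
            "monocyte_fraction_peak",
            "mito_gene_fraction",
            "high_mito_cell_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if 0.0 not in [float(t) for t in self.timepoints]:
            raise ValueError("timepoints must contain the control timepoint 0")
        if self.n_cell_types < 1 or self.cells_per_type_per_timepoint < 1:
            raise ValueError("n_cell_types and cells_per_type_per_timepoint must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.library_size_spread
        if not (0 < lo <= hi):
            raise ValueError("library_size_spread must satisfy 0 < lo <= hi")
        for pi in self.planted_interactions:
            if pi.fold <= 0:
                raise ValueError(f"planted fold must be > 0 ({pi.ligand})")
        if self.module_program is not None and self.module_program.fold <= 0:
            raise ValueError("module fold must be > 0")
        self._check_role_collisions()

    def _check_role_collisions(self) -> None:
        """A gene may carry at most one planted role."""
        roles: dict[str, str] = {}

        def claim(gene: str, role: str) -> None:
            prev = roles.get(gene)
            if prev is not None and prev != role:
                raise ValueError(f"gene {gene!r} planted as both {prev} and {role}")
            roles[gene] = role

        for pi in self.planted_interactions:
            claim(pi.ligand, "ligand")
            claim(pi.receptor, "receptor")
            for t in pi.targets:
                claim(t, "target")
        if self.module_program is not None:
            for g in self.module_program.genes:
                claim(g, "module")

    @property
    def cell_types(self) -> list[tuple[str, str]]:
        roster = list(CELL_TYPE_ROSTER)
        for i in range(len(roster), self.n_cell_types):
            roster.append((f"Type{i:02d}", "non_neuronal"))
        return roster[: self.n_cell_types]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery tests."""

    planted_interactions: tuple[PlantedInteraction, ...]
    module_name: str | None
    module_genes: tuple[str, ...]
    module_cell_ids: list[str]
    composition_table: pd.DataFrame  # timepoint, cell_type, compartment, fraction
    de_genes: dict[str, list[tuple[str, float, float]]]  # gene -> (cell_type, tp, fold)

    def to_dict(self) -> dict:
        return {
            "planted_interactions": [dataclasses.asdict(pi) for pi in self.planted_interactions],
            "module_name": self.module_name,
            "module_genes": list(self.module_genes),
            "module_cell_ids": list(self.module_cell_ids),
            "composition_table": self.composition_table.to_dict(orient="records"),
            "de_genes": {g: [list(e) for e in v] for g, v in self.de_genes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_interactions=tuple(
                PlantedInteraction(
                    sender=pi["sender"],
                    receiver=pi["receiver"],
                    ligand=pi["ligand"],
                    receptor=pi["receptor"],
                    targets=tuple(pi["targets"]),
                    fold=float(pi["fold"]),
                    timepoints=tuple(float(t) for t in pi["timepoints"]),
                )
                for pi in d["planted_interactions"]
            ),
            module_name=d.get("module_name"),
            module_genes=tuple(d.get("module_genes", ())),
            module_cell_ids=list(d["module_cell_ids"]),
            composition_table=pd.DataFrame(d["composition_table"]),
            de_genes={g: [(e[0], float(e[1]), float(e[2])) for e in v] for g, v in d["de_genes"].items()},
        )


def _gene_universe(config: SimulationConfig) -> pd.DataFrame:
    """Gene table: markers, mitochondrial genes, planted genes, then filler."""
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    names: list[str] = ["Rbfox3", "Apoe"]
    names += [f"mt-{i + 1}" for i in range(n_mito)]
    planted: list[str] = []
    for pi in config.planted_interactions:
        planted += [pi.ligand, pi.receptor, *pi.targets]
    if config.module_program is not None:
        planted += list(config.module_program.genes)
    for g in planted:
        if g not in names:
            names.append(g)
    if len(names) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {len(names)} named/planted genes"
        )
    i = 0
    while len(names) < config.n_genes:
        cand = f"Gene{i:05d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return pd.DataFrame(
        {
            "gene_id": [f"ENSMUSG{i:08d}" for i in range(config.n_genes)],
            "gene_symbol": names,
            "is_mito": [n.startswith("mt-") for n in names],
        }
    )


def _expected_fractions(config: SimulationConfig, timepoint: float) -> pd.DataFrame:
    """Planted within-compartment cell-type fractions at one timepoint."""
    types = config.cell_types
    rows = []
    by_comp: dict[str, list[str]] = {}
    for name, comp in types:
        by_comp.setdefault(comp, []).append(name)
    for comp, members in by_comp.items():
        if comp == "immune" and "Monocyte" in members and len(members) > 1:
            peak = float(timepoint) in [float(t) for t in config.monocyte_peak_timepoints]
            mono = config.monocyte_fraction_peak if peak else config.monocyte_fraction_baseline
            rest = (1.0 - mono) / (len(members) - 1)
            for name in members:
                rows.append((timepoint, name, comp, mono if name == "Monocyte" else rest))
        else:
            for name in members:
                rows.append((timepoint, name, comp, 1.0 / len(members)))
    return pd.DataFrame(rows, columns=["timepoint", "cell_type", "compartment", "fraction"])


def _marker_genes(config: SimulationConfig, gene_index: pd.Index) -> dict[str, list[str]]:
    """Disjoint per-type marker gene sets, drawn from the generic filler genes.

    Constitutively overexpressed (``marker_fold``) in their own type at every
    timepoint; they give each cell type the distinct identity program that
    label transfer relies on.
    """
    claimed = {g for pi in config.planted_interactions for g in (pi.ligand, pi.receptor, *pi.targets)}
    if config.module_program is not None:
        claimed |= set(config.module_program.genes)
    pool = [g for g in gene_index if g.startswith("Gene") and g not in claimed]
    m = config.markers_per_type
    markers: dict[str, list[str]] = {}
    for k, (name, _comp) in enumerate(config.cell_types):
        markers[name] = pool[k * m : (k + 1) * m]
    return markers


def _group_means(
    config: SimulationConfig,
    base_means: np.ndarray,
    gene_index: pd.Index,
    cell_type: str,
    compartment: str,
    timepoint: float,
    markers: dict[str, list[str]] | None = None,
) -> np.ndarray:
    """NB mean vector for one (cell type, timepoint) group before library scaling."""
    m = base_means.copy()
    gi = {g: i for i, g in enumerate(gene_index)}
    if markers:
        for g in markers.get(cell_type, ()):
            m[gi[g]] *= config.marker_fold
    # marker structure: Rbfox3 marks neurons; Apoe is high in glia, absent in neurons
    m[gi["Rbfox3"]] = 5.0 if compartment == "neuronal" else 0.01
    if cell_type in GLIAL_TYPES:
        m[gi["Apoe"]] = 8.0
    elif cell_type == "Macrophage":
        m[gi["Apoe"]] = 4.0
    elif compartment == "neuronal":
        m[gi["Apoe"]] = 0.05
    else:
        m[gi["Apoe"]] = 0.5
    tp = float(timepoint)
    for pi in config.planted_interactions:
        if pi.receiver == cell_type:
            j = gi[pi.receptor]
            m[j] = max(m[j], config.receptor_floor_mean)
        if tp in [float(t) for t in pi.timepoints]:
            if pi.sender == cell_type:
                m[gi[pi.ligand]] *= pi.fold
            if pi.receiver == cell_type:
                for t in pi.targets:
                    m[gi[t]] *= pi.fold
    mod = config.module_program
    if (
        mod is not None
        and cell_type in mod.cell_types
        and tp in [float(t) for t in mod.timepoints]
    ):
        for g in mod.genes:
            m[gi[g]] *= mod.fold
    return m


def simulate_dataset(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw one dataset plus its ground truth. Identical seeds, identical output."""
    rng = stage_rng(config.seed, "simulate")
    genes = _gene_universe(config)
    gene_index = dio._deduplicate_symbols(genes["gene_symbol"])
    base_means = rng.lognormal(config.baseline_mean_log, config.baseline_sigma_log, config.n_genes)
    mito_idx = np.flatnonzero(genes["is_mito"].to_numpy())
    theta = config.nb_dispersion
    lo, hi = config.library_size_spread

    types = config.cell_types
    markers = _marker_genes(config, gene_index) if config.markers_per_type > 0 else {}
    blocks: list[sp.csr_matrix] = []
    obs_rows: list[tuple[str, str, str, float, str]] = []
    comp_rows: list[pd.DataFrame] = []
    module_cells: list[str] = []
    counter = 0
    for tp in config.timepoints:
        tp = float(tp)
        frac = _expected_fractions(config, tp)
        comp_rows.append(frac)
        # realized counts: non-immune types are fixed-size; immune types are a
        # multinomial draw over the planted fractions (binomial sampling error
        # is part of the stated world)
        n_by_type: dict[str, int] = {}
        immune = [n for n, c in types if c == "immune"]
        for name, comp in types:
            if comp != "immune" or len(immune) <= 1 or "Monocyte" not in immune:
                n_by_type[name] = config.cells_per_type_per_timepoint
        if len(immune) > 1 and "Monocyte" in immune:
            total_immune = config.cells_per_type_per_timepoint * len(immune)
            probs = (
                frac.set_index("cell_type").loc[immune, "fraction"].to_numpy()
            )
            draws = rng.multinomial(total_immune, probs / probs.sum())
            for name, k in zip(immune, draws):
                n_by_type[name] = int(k)
        for name, comp in types:
            n_cells = n_by_type[name]
            if n_cells == 0:
                continue
            m = _group_means(config, base_means, gene_index, name, comp, tp, markers)
            lib = np.exp(rng.uniform(np.log(lo), np.log(hi), n_cells))
            mu = np.outer(lib, m)
            if config.high_mito_cell_fraction > 0 and len(mito_idx):
                high = rng.random(n_cells) < config.high_mito_cell_fraction
                if high.any():
                    mu[np.ix_(high, mito_idx)] *= config.mito_boost
            counts = rng.negative_binomial(theta, theta / (theta + mu))
            blocks.append(sp.csr_matrix(counts))
            cond = "control" if tp == 0.0 else "arthritis"
            mod = config.module_program
            in_module = (
                mod is not None
                and name in mod.cell_types
                and tp in [float(t) for t in mod.timepoints]
            )
            for _ in range(n_cells):
                cid = f"cell{counter:06d}"
                obs_rows.append((cid, name, comp, tp, cond))
                if in_module:
                    module_cells.append(cid)
                counter += 1

    X = sp.vstack(blocks, format="csr")
    cells = pd.DataFrame(
        obs_rows, columns=["cell_id", "cell_type", "compartment", "timepoint", "condition"]
    )
    adata = dio.make_dataset(X, genes, cells)
    dio.log_normalize(adata)

    de_genes: dict[str, list[tuple[str, float, float]]] = {}
    for pi in config.planted_interactions:
        for tp in pi.timepoints:
            de_genes.setdefault(pi.ligand, []).append((pi.sender, float(tp), pi.fold))
            for t in pi.targets:
                de_genes.setdefault(t, []).append((pi.receiver, float(tp), pi.fold))
    if config.module_program is not None:
        for g in config.module_program.genes:
            for ct in config.module_program.cell_types:
                for tp in config.module_program.timepoints:
                    de_genes.setdefault(g, []).append((ct, float(tp), config.module_program.fold))

    truth = GroundTruth(
        planted_interactions=tuple(config.planted_interactions),
        module_name=None if config.module_program is None else config.module_program.name,
        module_genes=()
        if config.module_program is None
        else tuple(config.module_program.genes),
        module_cell_ids=module_cells,
        composition_table=pd.concat(comp_rows, ignore_index=True),
        de_genes=de_genes,
    )
    return adata, truth


def write_fixture(
    adata: ad.AnnData, truth: GroundTruth, directory: str | Path, force: bool = False
) -> list[Path]:
    """Write matrix.mtx + genes.tsv + cells.tsv + truth.json."""
    directory = Path(directory)
    truth_path = directory / dio.TRUTH_FILE
    if truth_path.exists() and not force:
        raise FileExistsError(f"refusing to overwrite {truth_path.name}; pass force=True")
    paths = dio.write_dataset(adata, directory, force=force)
    with open(truth_path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths + [truth_path]


def read_truth(directory: str | Path) -> GroundTruth:
    with open(Path(directory) / dio.TRUTH_FILE) as fh:
        return GroundTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# canned configurations


def default_config(**overrides) -> SimulationConfig:
    """The full stated world: three planted cytokine programs at 12 h, a
    transient ISG-like module at 6 h - 1 d, and the monocyte influx."""
    n_targets = 15
    targets = [[f"Tgt{k}_{j:02d}" for j in range(n_targets)] for k in range(3)]
    planted = (
        PlantedInteraction("Fibroblast", "Macrophage", "Il6", "Il6ra", tuple(targets[0]), 5.0, (0.5,)),
        PlantedInteraction("Macrophage", "PEP1", "Il1b", "Il1r1", tuple(targets[1]), 5.0, (0.5,)),
        PlantedInteraction("Endothelial", "Monocyte", "Csf1", "Csf1r", tuple(targets[2]), 5.0, (0.5,)),
    )
    module = ModuleProgram(
        name="ISG",
        genes=tuple(f"Isg{j:02d}" for j in range(15)),
        fold=4.0,
        timepoints=(0.25, 0.5, 1.0),
        cell_types=("Fibroblast", "Monocyte", "Macrophage", "Endothelial", "SatelliteGlia"),
    )
    cfg = dict(planted_interactions=planted, module_program=module)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def null_config(**overrides) -> SimulationConfig:
    """No planted effects anywhere: flat means over time, no composition shift."""
    cfg = dict(
        planted_interactions=(),
        module_program=None,
        monocyte_fraction_peak=0.035,
        high_mito_cell_fraction=0.0,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def decoy_lr_reference(
    adata: ad.AnnData,
    truth: GroundTruth,
    rng: np.random.Generator,
    n_receptors_per_ligand: int = 8,
    targets_per_pair: int = 15,
    n_random_ligands: int = 0,
) -> pd.DataFrame:
    """Ligand-receptor reference combining the planted pairs with decoys.

    For every planted ligand the true (receptor, target-program) entry is
    emitted plus decoy entries pairing the ligand with broadly detected
    receptor genes and target sets drawn uniformly from the gene universe —
    mimicking a public ligand-receptor resource, where most annotated pairs
    are inactive in any given tissue and target programs are arbitrary
    genes. ``n_random_ligands`` adds entries for ligands that were never
    planted (useful on null simulations, where nothing was planted at all).
    Columns: ligand, receptor, targets (semicolon-separated).
    """
    planted_genes = {
        g for pi in truth.planted_interactions for g in (pi.ligand, pi.receptor, *pi.targets)
    }
    genes = np.asarray(adata.var_names)
    special = planted_genes | {"Rbfox3", "Apoe"}
    ordinary = np.array(
        [g for g in genes if g not in special and not g.startswith("mt-")]
    )
    detected = np.asarray((adata.X > 0).mean(axis=0)).ravel()
    det_of = dict(zip(genes, detected))
    receptor_pool = np.array([g for g in ordinary if det_of[g] > 0.2])

    def decoy_entries(ligand: str, n: int) -> list[tuple[str, str, str]]:
        receptors = rng.choice(receptor_pool, size=min(n, receptor_pool.size), replace=False)
        rows = []
        for rec in receptors:
            tgt = rng.choice(ordinary, size=targets_per_pair, replace=False)
            rows.append((ligand, rec, ";".join(tgt)))
        return rows

    rows: list[tuple[str, str, str]] = []
    for pi in truth.planted_interactions:
        rows.append((pi.ligand, pi.receptor, ";".join(pi.targets)))
        rows += decoy_entries(pi.ligand, n_receptors_per_ligand)
    if n_random_ligands > 0:
        ligands = rng.choice(ordinary, size=n_random_ligands, replace=False)
        for lig in ligands:
            rows += decoy_entries(lig, n_receptors_per_ligand)
    ref = pd.DataFrame(rows, columns=["ligand", "receptor", "targets"])
    return ref.drop_duplicates(subset=["ligand", "receptor"], keep="first").reset_index(drop=True)
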