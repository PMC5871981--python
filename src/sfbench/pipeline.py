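"""End-to-end orchestration of similarity-cutoff benchmark runs.

A run is described by a :class:`RunConfig` (YAML-loadable) and proceeds
through fixed stages: load or generate the benchmark, compute descriptor
tables for every scheme in the scoring-function roster, build the nested
training sets, fit the learning curve, and write the outputs (long-form
and summary learning-curve CSVs, partition report, stability report and a
self-describing manifest).  Everything is a pure function of
(config, seed), so reruns are byte-identical.

The default roster mirrors the canonical comparison: a classical
MLR-based scoring function on four energy-like terms ("X-Score analog"),
the same four features under a random forest ("RF::X-Score"), the
36-count contact scoring function ("RF-Score"), and the 42-feature
variant with the six empirical terms appended ("RF-Score-v3").
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .descriptors import (
    DescriptorTable,
    RF_V1_FEATURES,
    SCHEME_FEATURES,
    rf_v3_descriptors,
    xscore_like_terms,
    write_descriptor_table,
)
from .evaluate import (
    CurveInputs,
    LearningCurveTable,
    build_learning_curve,
    gap_ratio,
)
from .partition import (
    CutoffSchedule,
    SimilarityMatrix,
    STRUCTURAL_SCHEDULE,
    build_nested_sets,
    partition_report,
)
from .regress import ModelSpec
from .structio import read_ligand_sdf, read_protein_pdb
from .synthdata import SyntheticConfig, make_benchmark

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SFConfig", "default_roster", "run", "load_config",
            "compute_descriptor_tables", "PipelineError"]

CONFIG_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass(frozen=True)
class SFConfig:
    """One scoring function of the roster: name, descriptor scheme, model."""

    name: str
    scheme: str
    spec: ModelSpec


def default_roster(base_seed: int = 0, n_repeats: int = 10, n_trees: int = 500) -> list[SFConfig]:
    rf = dict(n_trees=n_trees, n_repeats=n_repeats, base_seed=base_seed)
    return [
        SFConfig("X-Score", "xscore4", ModelSpec("MLR", n_repeats=n_repeats, base_seed=base_seed)),
        SFConfig("RF::X-Score", "xscore4", ModelSpec("RF", **rf)),
        SFConfig("RF-Score", "rf_v1", ModelSpec("RF", **rf)),
        SFConfig("RF-Score-v3", "rf_v3", ModelSpec("RF", **rf)),
    ]


@dataclass
class RunConfig:
    """Everything one run needs; serialisable into the manifest."""

    mode: str = "synthetic"  # "synthetic" | "files"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # files mode inputs
    structures_dir: str | None = None
    affinities_csv: str | None = None
    similarity_csv: str | None = None
    include_cofactors: bool = False
    schedule: CutoffSchedule = STRUCTURAL_SCHEDULE
    similarity_kind: str = "structural"
    roster: list[SFConfig] | None = None
    out_dir: str = "sfbench_run"
    write_plot: bool = False

    def resolved_roster(self) -> list[SFConfig]:
        return self.roster if self.roster is not None else default_roster(base_seed=self.seed)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.resolved_roster():
            raise ValueError("empty scoring-function roster")
        if self.mode == "files":
            for label, path in (("structures_dir", self.structures_dir),
                                ("affinities_csv", self.affinities_csv),
                                ("similarity_csv", self.similarity_csv)):
                if path is None or not Path(path).exists():
                    raise ValueError(f"files mode requires existing {label}, got {path!r}")


def load_config(path) -> RunConfig:
    """Read a YAML run configuration (versioned schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version}")
    kwargs: dict = {}
    for key in ("mode", "seed", "structures_dir", "affinities_csv", "similarity_csv",
                "include_cofactors", "similarity_kind", "out_dir", "write_plot"):
        if key in raw:
            kwargs[key] = raw[key]
    if "synthetic" in raw:
        kwargs["synthetic"] = SyntheticConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["synthetic"].items()
        })
    if "schedule" in raw:
        kwargs["schedule"] = CutoffSchedule(tuple(raw["schedule"]))
    if "roster" in raw:
        roster = []
        for entry in raw["roster"]:
            spec_kwargs = {k: entry[k] for k in
                           ("n_trees", "features_per_split", "n_repeats", "base_seed")
                           if k in entry}
            spec_kwargs.setdefault("base_seed", raw.get("seed", 0))
            roster.append(SFConfig(entry["name"], entry["scheme"],
                                   ModelSpec(entry["kind"], **spec_kwargs)))
        kwargs["roster"] = roster
    config = RunConfig(**kwargs)
    config.validate()
    return config


def compute_descriptor_tables(
    complexes: dict,
    ids: list[str],
    schemes: set[str],
    affinities: pd.Series | None = None,
    rf_cutoff: float = 12.0,
) -> dict[str, DescriptorTable]:
    """Build one descriptor table per scheme over the given complex ids.

    The 36 pair counts are computed once as part of the 42-feature table
    and sliced for the rf_v1 scheme, so each structure pair is visited at
    most twice (contact terms + classical terms) regardless of how many
    schemes the roster uses.
    """
    tables: dict[str, DescriptorTable] = {}
    aff = {i: float(affinities.loc[i]) for i in ids} if affinities is not None else None
    if schemes & {"rf_v1", "rf_v3", "vina6"}:
        vecs = [rf_v3_descriptors(complexes[i].protein, complexes[i].ligand, rf_cutoff)
                for i in ids]
        full = DescriptorTable.from_vectors(ids, vecs, aff)
        if "rf_v3" in schemes:
            tables["rf_v3"] = full
        if "rf_v1" in schemes:
            cols = list(RF_V1_FEATURES) + (["affinity"] if full.has_affinity else [])
            tables["rf_v1"] = DescriptorTable(full.frame[cols], "rf_v1")
        if "vina6" in schemes:
            cols = list(SCHEME_FEATURES["vina6"]) + (["affinity"] if full.has_affinity else [])
            tables["vina6"] = DescriptorTable(full.frame[cols], "vina6")
    if "xscore4" in schemes:
        vecs = [xscore_like_terms(complexes[i].protein, complexes[i].ligand) for i in ids]
        tables["xscore4"] = DescriptorTable.from_vectors(ids, vecs, aff)
    return tables


@dataclass
class _LoadedData:
    complexes: dict
    train_ids: list[str]
    test_ids: list[str]
    similarity: SimilarityMatrix
    affinities: pd.Series


def _load_files_mode(config: RunConfig) -> _LoadedData:
    from .synthdata import ComplexRecord  # local: avoids a cycle at import time

    root = Path(config.structures_dir)
    aff = pd.read_csv(config.affinities_csv, float_precision="round_trip").set_index("id")
    with open(config.similarity_csv) as fh:
        similarity = SimilarityMatrix.from_csv(fh)
    train_ids = similarity.train_ids
    test_ids = similarity.test_ids
    complexes = {}
    for cid in train_ids + test_ids:
        with open(root / "proteins" / f"{cid}.pdb") as fh:
            protein = read_protein_pdb(fh, include_cofactors=config.include_cofactors)
        with open(root / "ligands" / f"{cid}.sdf") as fh:
            ligand = read_ligand_sdf(fh)
        family = str(aff.loc[cid, "family"]) if "family" in aff.columns else "unknown"
        complexes[cid] = ComplexRecord(cid, protein, ligand, float(aff.loc[cid, "affinity"]), family)
    return _LoadedData(complexes, train_ids, test_ids, similarity,
                       aff["affinity"].astype(float))


def _stage(name: str):
    logger.info("stage: %s", name)
    return name


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a result bundle and writes files.

    Output files under ``config.out_dir``: ``learning_curve_long.csv``,
    ``learning_curve_summary.csv``, ``partition_report.csv``,
    ``stability_report.json``, ``manifest.json`` and (optionally) a
    learning-curve plot.  Any stage error aborts the run with the stage
    name; the manifest is then marked incomplete.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster = config.resolved_roster()
    manifest = {
        "sfbench_version": __version__,
        "config_schema_version": CONFIG_SCHEMA_VERSION,
        "mode": config.mode,
        "seed": config.seed,
        "similarity_kind": config.similarity_kind,
        "schedule": list(config.schedule),
        "roster": [
            {"name": sf.name, "scheme": sf.scheme, **dataclasses.asdict(sf.spec)}
            for sf in roster
        ],
        "complete": False,
    }
    stage = "init"
    try:
        stage = _stage("load-benchmark")
        if config.mode == "synthetic":
            bench = make_benchmark(config.synthetic, config.seed)
            data = _LoadedData(bench.complexes, bench.train_ids, bench.test_ids,
                               bench.similarity,
                               bench.affinity_series(bench.train_ids + bench.test_ids))
            manifest["synthetic_config"] = dataclasses.asdict(config.synthetic)
        else:
            data = _load_files_mode(config)
        manifest["n_train"] = len(data.train_ids)
        manifest["n_test"] = len(data.test_ids)
        logger.info("benchmark: %d training / %d test complexes",
                    len(data.train_ids), len(data.test_ids))

        stage = _stage("descriptors")
        schemes = {sf.scheme for sf in roster}
        rf_cutoff = config.synthetic.rf_cutoff if config.mode == "synthetic" else 12.0
        train_tables = compute_descriptor_tables(
            data.complexes, data.train_ids, schemes, data.affinities, rf_cutoff)
        test_tables = compute_descriptor_tables(
            data.complexes, data.test_ids, schemes, data.affinities, rf_cutoff)
        for scheme, table in train_tables.items():
            with open(out / f"descriptors_train_{scheme}.csv", "w") as fh:
                write_descriptor_table(table, fh)
        for scheme, table in test_tables.items():
            with open(out / f"descriptors_test_{scheme}.csv", "w") as fh:
                write_descriptor_table(table, fh)
        logger.info("descriptors computed for schemes: %s", sorted(schemes))

        stage = _stage("partition")
        partition = build_nested_sets(data.similarity, config.schedule)
        report = partition_report(partition, len(data.train_ids))
        report.to_csv(out / "partition_report.csv", index=False)
        logger.info("nested sets: %s", partition.sizes())

        stage = _stage("learning-curve")
        inputs = CurveInputs(
            train_tables=train_tables,
            test_tables=test_tables,
            y_train=data.affinities.loc[data.train_ids],
            y_test=data.affinities.loc[data.test_ids],
        )
        curve = build_learning_curve(inputs, partition,
                                     [(sf.name, sf.scheme, sf.spec) for sf in roster])
        curve.to_long_frame().to_csv(out / "learning_curve_long.csv", index=False)
        curve.to_summary_frame().to_csv(out / "learning_curve_summary.csv", index=False)

        stage = _stage("stability-report")
        stability = _stability_report(curve, roster, config.schedule)
        with open(out / "stability_report.json", "w") as fh:
            json.dump(stability, fh, indent=2)

        if config.write_plot:
            stage = _stage("plot")
            from .evaluate import plot_learning_curve
            plot_learning_curve(curve, out / "learning_curve.png")

        manifest["complete"] = True
        return {"curve": curve, "partition": partition, "stability": stability,
                "manifest": manifest, "out_dir": str(out)}
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _stability_report(curve: LearningCurveTable, roster: list[SFConfig],
                      schedule: CutoffSchedule) -> dict:
    """Stochastic-variability summary at the largest cutoff.

    For each stochastic scoring function: the repeat range of its test Rp
    and, when a deterministic comparator is in the roster, the ratio of
    the median-Rp gap to that range.
    """
    top = max(schedule)
    mlr = next((sf for sf in roster if sf.spec.kind == "MLR"), None)
    mlr_rp = None
    if mlr is not None:
        row = curve.row(mlr.name, top)
        if row.trainable:
            mlr_rp = row.median_rp
    report: dict = {"cutoff": top, "comparator": mlr.name if mlr else None}
    for sf in roster:
        if sf.spec.kind != "RF":
            continue
        row = curve.row(sf.name, top)
        if not row.trainable:
            report[sf.name] = {"trainable": False}
            continue
        entry = {
            "n_train": row.n_train,
            "median_rp": round(row.median_rp, 3),
            "range_rp": round(row.range_rp, 3),
        }
        if mlr_rp is not None and row.range_rp > 0:
            entry["gap_ratio_vs_" + mlr.name] = round(
                gap_ratio(row.median_rp, mlr_rp, row.range_rp), 1)
        report[sf.name] = entry
    return report
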