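"""Table I/O, Newick serialization, configuration and the pipeline driver.

Formats: CSV (series, dose tables, column effluents; comma, UTF-8, "."
decimal, header mandatory), TSV (OTU tables, taxonomy, registries), Newick
(dendrograms), YAML (configuration), JSON (manifest).  Identical
configuration and seeds produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
import yaml
from skbio import TreeNode

from . import __version__
from .columns import CalibrationCurve, ColumnSpec, compute_roip, percent_roip
from .ecology import bray_curtis_matrix, shannon_index, upgma_tree
from .response import BiomassDose, fit_ols
from .simulate import (
    FlowSchedule,
    NoiseSpec,
    default_params,
    generate_column_dataset,
    generate_dose_response,
    generate_otu_counts,
    simulate_batch,
    simulate_chemostat,
)

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "RunManifest",
    "read_table",
    "write_newick",
    "read_newick",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table failed schema validation; message lists every offender."""


def read_table(
    path: str | Path,
    schema: Mapping[str, type],
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited table and validate it against a column->type schema.

    Missing columns and non-coercible cells are aggregated into one
    :class:`SchemaError`.  Extra columns are preserved untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty and df.columns.empty:
        raise SchemaError(f"{path}: empty input")
    problems: list[str] = []
    missing = [c for c in schema if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
    for col, typ in schema.items():
        if col in missing:
            continue
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            if bad:
                problems.append(f"column {col!r}: non-numeric rows {bad}")
            else:
                df[col] = coerced.astype(typ if typ is float else "Int64")
        else:
            df[col] = df[col].astype(str)
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a dendrogram to Newick with branch lengths."""
    if tree.count(tips=True) < 1:
        raise ValueError("cannot serialize an empty tree")
    try:
        tree.write(str(path), format="newick")
    except OSError as exc:
        raise OSError(f"failed writing Newick to {path}: {exc}") from exc


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the synthetic demo pipeline needs, with defaults throughout."""

    out_dir: Path
    seed: int = 1
    kinetics_file: Path | None = None  # optional external kinetic parameter YAML
    calib_slope: float = 2.0  # A600 per (mL oil / mL solvent)
    calib_intercept: float = 0.02
    dose_slope: float = 11.2  # %ROIP per OD600, nitrate condition
    dose_intercept: float = 8.3
    dose_sigma: float = 0.5
    n_doses: int = 50
    otu_profile: Mapping[str, float] = field(
        default_factory=lambda: {
            "Thauera": 0.529,
            "Pseudomonas": 0.078,
            "Acetoanaerobium": 0.15,
            "Desulfuromonas": 0.13,
            "Sphaerochaeta": 0.113,
        }
    )
    otu_depth: int = 20000
    otu_overdispersion: float = 0.02
    n_otu_samples: int = 6
    decimals: int = 2  # presentation rounding policy

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.kinetics_file is not None:
            kf = Path(self.kinetics_file)
            object.__setattr__(self, "kinetics_file", kf)
            if not kf.exists():
                raise FileNotFoundError(f"kinetics file not found: {kf}")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        d = {k: (str(v) if isinstance(v, Path) else v)
             for k, v in self.__dict__.items()}
        d["otu_profile"] = dict(d["otu_profile"])
        return json.dumps(d, sort_keys=True)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    input_checksums: dict[str, str]
    stages: dict[str, dict]  # name -> {"status": ..., "seconds": ..., "outputs": [...]}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, decimals: int) -> None:
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] | None = None
) -> RunManifest:
    """Run the synthetic demo pipeline and write outputs plus a manifest.

    Stages (in dependency order): batch, chemostat, doses, otu, columns,
    metrics.  A stage failure halts downstream stages; the manifest records
    partial status.  Identical config and seed give byte-identical outputs.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    if config.kinetics_file is not None:
        checksums[str(config.kinetics_file)] = _sha256(config.kinetics_file)
        with open(config.kinetics_file) as fh:
            params = default_params(**(yaml.safe_load(fh)["kinetics"]))
    else:
        params = default_params()

    calib = CalibrationCurve(config.calib_slope, config.calib_intercept)
    seed = int(config.seed)
    state: dict = {}

    def stage_batch() -> list[Path]:
        sim = simulate_batch(params, nitrate0=10.0, t_end=12.0)
        p = out / "batch_series.csv"
        _write_csv(sim.to_frame().iloc[::10], p, 4)
        return [p]

    def stage_chemostat() -> list[Path]:
        sched = FlowSchedule(steps=[(0, 0.0), (9, 0.1), (29, 0.2)])
        sim = simulate_chemostat(params, sched, t_end=70.0)
        p = out / "chemostat_series.csv"
        _write_csv(sim.to_frame().iloc[::10], p, 4)
        return [p]

    def stage_doses() -> list[Path]:
        rng_od = [round(0.05 + 1.75 * i / (config.n_doses - 1), 3)
                  for i in range(config.n_doses)]
        df = generate_dose_response(
            config.dose_slope, config.dose_intercept, config.dose_sigma,
            rng_od, seed=seed + 11,
        )
        p = out / "doses.csv"
        _write_csv(df, p, 4)
        state["doses"] = df
        return [p]

    def stage_otu() -> list[Path]:
        table, tax = generate_otu_counts(
            config.otu_profile, config.otu_depth, config.otu_overdispersion,
            config.n_otu_samples, seed=seed + 23,
        )
        p1, p2 = out / "otu_table.tsv", out / "taxonomy.tsv"
        table.to_tsv(p1)
        tax.to_tsv(p2)
        state["otu"] = (table, tax)
        return [p1, p2]

    def stage_columns() -> list[Path]:
        spec = ColumnSpec(id="demo", PV=35.0, oil_injected=33.0)
        samples = generate_column_dataset(
            spec, true_roip=17.0, waterflood_profile=None, meor_percent=16.0,
            calib=calib, noise=NoiseSpec(sigma={"a600": 0.005}, seed=seed + 37),
        )
        wf = [s for s in samples if s.stage == "waterflood"]
        meor = [s for s in samples if s.stage == "MEOR"]
        result = percent_roip(compute_roip(spec, wf, calib), meor, calib)
        df = pd.DataFrame(
            [
                {
                    "column_id": spec.id,
                    "stage": s.stage,
                    "cum_pv": s.cumulative_PV_injected,
                    "aq_ml": s.aqueous_volume,
                    "a600": s.extract_A600,
                    "solvent_ml": s.solvent_volume,
                    "nitrate_mM": s.nitrate_mM,
                    "nitrite_mM": s.nitrite_mM,
                }
                for s in samples
            ]
        )
        p = out / "column_effluents.csv"
        _write_csv(df, p, 4)
        state["column_result"] = result
        return [p]

    def stage_metrics() -> list[Path]:
        table, tax = state["otu"]
        shannon = {
            s: shannon_index(table.counts[s].values) for s in table.samples
        }
        dm = bray_curtis_matrix(table)
        tree = upgma_tree(dm)
        doses = state["doses"]
        fit = fit_ols(
            [BiomassDose(r.od600, r.percent_roip, bool(r.nitrate_present))
             for r in doses.itertuples()]
        )
        res = state["column_result"]
        p1 = out / "diversity.csv"
        _write_csv(
            pd.DataFrame(
                {"sample": list(shannon), "shannon_nats": list(shannon.values())}
            ),
            p1, 4,
        )
        p2 = out / "dendrogram.nwk"
        write_newick(tree, p2)
        p3 = out / "summary.json"
        with open(p3, "w") as fh:
            json.dump(
                {
                    "dose_fit": {
                        "slope": round(fit.slope, 3),
                        "intercept": round(fit.intercept, 3),
                        "r2": round(fit.r2, 4),
                        "n": fit.n,
                    },
                    "column": {
                        "ROIP_mL": round(res.ROIP, 2),
                        "roip_pv_fraction": round(res.roip_pv_fraction, 2),
                        "percent_roip": round(res.percent_roip, 1),
                    },
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        return [p1, p2, p3]

    all_stages: dict[str, Callable[[], list[Path]]] = {
        "batch": stage_batch,
        "chemostat": stage_chemostat,
        "doses": stage_doses,
        "otu": stage_otu,
        "columns": stage_columns,
        "metrics": stage_metrics,
    }
    selected = list(all_stages) if stages is None else list(stages)
    unknown = set(selected) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest = RunManifest(
        config_hash=hashlib.sha256(config.canonical().encode()).hexdigest(),
        version=__version__,
        input_checksums=checksums,
        stages={},
    )
    failed = False
    for name in selected:
        if failed:
            manifest.stages[name] = {"status": "skipped", "seconds": 0.0, "outputs": []}
            continue
        t0 = time.perf_counter()
        try:
            outputs = all_stages[name]()
            manifest.stages[name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": [p.name for p in outputs],
            }
        except Exception as exc:  # noqa: BLE001 - recorded, then halt downstream
            manifest.stages[name] = {
                "status": f"failed: {exc}",
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": [],
            }
            failed = True
    manifest.write(out / "manifest.json")
    return manifest
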