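"""End-to-end orchestration: simulate -> derive -> evaluate -> report.

A :class:`RunConfig` drives the whole run from one seed; the output
directory receives the dataset CSVs, the derived-status table, the
evaluation tables, a calibration report and a manifest recording the
configuration, software version and a content hash of every artifact,
so a rerun with the same configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .enhancement import derive_all
from .records import ALL_METHODS, CORE_METHODS, LinkedDataset, Method, write_dataset
from .synthetic import GeneratorConfig, SimulatedTruth, calibration_report, simulate
from .validity import evaluate_table, format_table2

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compare_methods", "plot_tradeoff"]


def resolve_methods(spec: str | Sequence[str]) -> list[Method]:
    """Interpret a method selection: "core", "all", or explicit names."""
    if isinstance(spec, str):
        if spec == "core":
            return list(CORE_METHODS)
        if spec == "all":
            return list(ALL_METHODS)
        spec = [s for s in spec.split(",") if s]
    return [Method(s) for s in spec]


class RunConfig(BaseModel):
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    methods: str = "core"
    mode: str = "all_records"
    output_dir: Path = Path("linkenhance-run")
    seed: Optional[int] = None  # overrides generator.seed when given

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write the artifact bundle.

    Returns a manifest dict: configuration, seed, version and the
    written files with content hashes.  Any stage failure aborts with
    the stage name in the exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    if config.seed is not None:
        gen = gen.model_copy(update={"seed": config.seed})
    methods = resolve_methods(config.methods)

    stages: dict[str, float] = {}
    files: dict[str, str] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # annotate with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            stages[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: %.2fs", name, stages[name])
            return result

        return wrap

    ds_truth = stage("simulate")(lambda: simulate(gen))
    ds, truth = ds_truth

    def write_inputs():
        write_dataset(ds, out / "records.csv", out / "reference.csv")
        truth.table.to_csv(out / "truth.csv", index=False)

    stage("write_dataset")(write_inputs)

    derived = stage("derive")(lambda: derive_all(ds, methods))
    stage("write_derived")(
        lambda: derived.to_csv(out / "derived.csv", index=False)
    )

    table = stage("evaluate")(lambda: evaluate_table(ds, derived, methods, config.mode))

    def write_eval():
        table.to_csv(out / "evaluation.csv", index=False)
        (out / "evaluation.txt").write_text(format_table2(table) + "\n")
        calibration_report(ds, gen, truth).to_csv(out / "calibration.csv", index=False)
        compare_methods(table).to_csv(out / "ranking.csv", index=False)

    stage("report")(write_eval)

    for f in ("records.csv", "reference.csv", "truth.csv", "derived.csv",
              "evaluation.csv", "evaluation.txt", "calibration.csv", "ranking.csv"):
        files[f] = _sha256(out / f)

    manifest = {
        "version": __version__,
        "seed": gen.seed,
        "generator": json.loads(gen.model_dump_json()),
        "methods": [m.value for m in methods],
        "mode": config.mode,
        "stage_seconds": stages,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def verify_manifest(output_dir) -> bool:
    """Re-hash every artifact listed in the manifest; True if all match."""
    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(_sha256(out / f) == h for f, h in manifest["files"].items())


def compare_methods(table: pd.DataFrame) -> pd.DataFrame:
    """Rank methods by total F score within each evaluated source.

    Ties at two-decimal display precision are flagged in a ``tied``
    column (the published comparison reports equal F scores as ties).
    """
    total = table[table["age_group"] == "total"]
    if total["method"].nunique() < 1:
        raise ValueError("ranking needs evaluation results for at least one method")
    rows = []
    for src in ("APDC", "EDDC"):
        col = f"{src}_f_score"
        if col not in total.columns:
            continue
        sub = total[["method", col]].copy()
        sub["f_display"] = sub[col].round(2)
        sub = sub.sort_values([col, "method"], ascending=[False, True], kind="stable")
        sub["rank"] = range(1, len(sub) + 1)
        dup = sub["f_display"].duplicated(keep=False)
        for _, r in sub.iterrows():
            rows.append({
                "source": src, "rank": int(r["rank"]), "method": r["method"],
                "f_score": r[col], "tied": bool(dup.loc[r.name]),
            })
    return pd.DataFrame(rows)


def plot_tradeoff(table: pd.DataFrame, path) -> None:
    """Sensitivity vs PPV trade-off chart for the total rows."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    total = table[table["age_group"] == "total"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, src in zip(axes, ("APDC", "EDDC")):
        ax.scatter(total[f"{src}_sensitivity"], total[f"{src}_ppv"])
        for _, r in total.iterrows():
            ax.annotate(r["method"], (r[f"{src}_sensitivity"], r[f"{src}_ppv"]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
        ax.set_xlabel("sensitivity (%)")
        ax.set_title(src)
    axes[0].set_ylabel("PPV (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
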