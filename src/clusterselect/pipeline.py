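"""End-to-end orchestration of the four selection stages.

characterize -> derive/choose requirements -> match & down-select ->
evaluate the selected subset -> recommend. Every stage's output is written
to the output directory, together with a manifest of seeds and thresholds,
so a rerun with the same config reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import characterize as ch
from . import evaluate as ev
from . import preprocess as pp
from .select import RequirementSet, SelectionResult, get_preset
from .select import select as run_selection
from .select import _support_level
from .dataset import DatasetMatrix
from .kb import AlgorithmKB, load_kb
from .runners import AlgorithmSpec
from .synth import get_archetype


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    data:
        A DatasetMatrix, a CSV path, or an archetype preset name.
    preprocessing:
        "emsc" (spectra with a wavenumber axis), "standardize", or "none".
    requirements:
        A RequirementSet or the name of a scenario preset.
    k:
        Target cluster count; defaults to the labelled class count.
    """

    data: object
    preprocessing: str = "none"
    requirements: object = "classic_ml"
    k: int | None = None
    seed: int = 0
    thresholds: ch.Thresholds = field(default_factory=ch.Thresholds)
    noise_convention: str = "cluster"
    kb_path: str | None = None
    out_dir: str | None = None


@dataclass
class PipelineReport:
    dataset: DatasetMatrix
    characteristics: ch.DatasetCharacteristics
    structure: ch.ClusterStructure
    selection: SelectionResult
    evaluation: ev.EvaluationTable
    recommended: list


def _load_data(cfg: PipelineConfig) -> DatasetMatrix:
    if isinstance(cfg.data, DatasetMatrix):
        return cfg.data
    data = str(cfg.data)
    if data.endswith(".csv"):
        return DatasetMatrix.from_csv(data)
    return get_archetype(data, seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full selection workflow and (optionally) write reports."""
    m = _load_data(cfg)

    if cfg.preprocessing == "emsc":
        m, _ = pp.emsc_fit_correct(m)
    elif cfg.preprocessing == "standardize":
        m = pp.standardize(m)
    elif cfg.preprocessing != "none":
        raise ValueError(f"unknown preprocessing {cfg.preprocessing!r}")

    # Stage 1: characterization
    dc = ch.characterize_dataset(m, cfg.thresholds)
    k = cfg.k or m.n_classes
    if k is None:
        raise ValueError("unlabelled data needs an explicit k")
    if m.labels is not None:
        cs = ch.characterize_clusters(m, thresholds=cfg.thresholds)
    else:
        cs = ch.estimate_structure_unlabelled(m, k, cfg.thresholds)

    # Stages 2-3: requirements, matching, down-selection
    req = (
        cfg.requirements
        if isinstance(cfg.requirements, RequirementSet)
        else get_preset(str(cfg.requirements))
    )
    kb = load_kb(cfg.kb_path)
    selection = run_selection(kb, req)

    # Stage 4: quantitative evaluation of the selected subset only
    specs = [
        AlgorithmSpec(name, seed=cfg.seed, target_k=k) for name in selection.selected
    ]
    table = ev.evaluate_grid(
        specs, [m], groups={"all": [m.name]}, noise_convention=cfg.noise_convention
    )
    col = table.scores[m.name]
    best = col.max()
    recommended = (
        [name for name in col.index if col[name] == best] if col.notna().any() else []
    )

    report = PipelineReport(
        dataset=m,
        characteristics=dc,
        structure=cs,
        selection=selection,
        evaluation=table,
        recommended=recommended,
    )
    if cfg.out_dir is not None:
        _write_bundle(cfg, report)
    return report


def selection_to_frame(selection: SelectionResult):
    import pandas as pd

    rows = []
    for r in selection.ranked:
        rows.append(
            {
                "algorithm": r.algorithm,
                "score": r.score,
                "max_score": r.max_score,
                "satisfied": ";".join(sorted(c.value for c in r.satisfied)),
                "violated": ";".join(sorted(c.value for c in r.violated)),
                "unknown": ";".join(sorted(c.value for c in r.unknown)),
                "passed_hard_constraints": r.passed_hard_constraints,
                "selected": r.algorithm in selection.selected,
            }
        )
    return pd.DataFrame(rows)


def render_matrix(kb: AlgorithmKB, req: RequirementSet) -> str:
    """Text comparative matrix restricted to the requirement's columns."""
    cols = sorted(c.value for c in req.soft) or ["(hard constraints only)"]
    widths = [max(len(c), 3) for c in cols]
    name_w = max(len(p.name) for p in kb)
    lines = [
        " ".join([f"{'algorithm':<{name_w}}"] + [f"{c:>{w}}" for c, w in zip(cols, widths)])
    ]
    mark = {"yes": "Y", "no": "N", "unknown": "?"}
    for p in kb:
        cells = []
        for c, w in zip(sorted(req.soft, key=lambda c: c.value), widths):
            level = _support_level(p, c)
            cells.append(f"{mark[level]:>{w}}")
        lines.append(" ".join([f"{p.name:<{name_w}}"] + cells))
    return "\n".join(lines)


def _write_bundle(cfg: PipelineConfig, report: PipelineReport) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "characterization.json", "w") as fh:
        json.dump(
            {
                "dataset": report.dataset.name,
                "characteristics": report.characteristics.to_dict(),
                "structure": report.structure.to_dict(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    selection_to_frame(report.selection).to_csv(out / "selection.csv", index=False)
    report.evaluation.to_csv(out / "evaluation.csv")
    with open(out / "annotations.json", "w") as fh:
        json.dump(
            {f"{a}|{d}": msgs for (a, d), msgs in report.evaluation.annotations.items()},
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(out / "summary.md", "w") as fh:
        fh.write(f"# Selection report: {report.dataset.name}\n\n")
        fh.write(f"Selected algorithms: {', '.join(report.selection.selected)}\n\n")
        scores = report.evaluation.scores[report.dataset.name]
        for name in report.selection.selected:
            fh.write(f"- {name}: V = {scores[name]:.3f}\n")
        fh.write(f"\nRecommended: {', '.join(report.recommended) or 'none'}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "preprocessing": cfg.preprocessing,
                "k": cfg.k,
                "noise_convention": cfg.noise_convention,
                "thresholds": vars(cfg.thresholds),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
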