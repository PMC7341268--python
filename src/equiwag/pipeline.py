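"""End-to-end run: simulate/load -> validate -> score -> aggregate ->
describe -> report bundle.

A run writes a deterministic bundle of CSV and Markdown artifacts plus a
manifest (seed, config hash, package version, record counts).  Timestamps
are deliberately absent so two runs with the same seed and configuration
produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .aggregation import (
    DEFAULT_MIN_STRATUM_N,
    DEFAULT_THRESHOLD_PCT,
    driver_report,
    grade_matrix,
    response_table,
)
from .class_description import describe_class, render_class_description
from .errors import ConfigError
from .schema import CATEGORIES, RecordSet, load_records, load_schema, default_schema, records_frame, write_records
from .scoring import DEFAULT_SCALE, ScoreConfig, score_records
from .synth import SynthConfig, generate_population, study_mimic_config, with_seed


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one input source."""

    input_path: Optional[str] = None
    synth: Optional[SynthConfig] = None  # or use_study_mimic
    use_study_mimic: bool = False
    schema_path: Optional[str] = None
    score: ScoreConfig = field(default_factory=ScoreConfig)
    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    min_stratum_n: int = DEFAULT_MIN_STRATUM_N
    alpha: float = 0.05
    bh: bool = False
    class_question: str = "handler_interaction"
    seed: int = 0
    outdir: str = "equiwag_run"


def _config_hash(cfg: RunConfig) -> str:
    payload = asdict(cfg)
    payload.pop("outdir", None)
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _markdown_table(frame: pd.DataFrame) -> str:
    """Minimal GitHub-style table renderer (index becomes first column)."""
    flat = frame.reset_index()
    cols = [str(c) for c in flat.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in flat.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _acquire_records(cfg: RunConfig) -> RecordSet:
    sources = sum([cfg.input_path is not None, cfg.synth is not None, cfg.use_study_mimic])
    if sources != 1:
        raise ConfigError("input", "exactly one of input_path / synth / use_study_mimic required")
    schema = load_schema(cfg.schema_path) if cfg.schema_path else default_schema()
    if cfg.input_path:
        return load_records(cfg.input_path, schema)
    synth_cfg = cfg.synth if cfg.synth is not None else study_mimic_config(schema=schema)
    return generate_population(with_seed(synth_cfg, cfg.seed), schema)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the in-memory results and the output paths.
    """
    rs = _acquire_records(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # (a) validated record echo
    write_records(rs, outdir / "records.csv")

    # (b) per-individual category scores
    scores = score_records(rs, cfg.score)
    score_rows = []
    for cat in CATEGORIES:
        for cs in scores[cat]:
            score_rows.append(
                {
                    "equid_id": cs.equid_id,
                    "category": cat,
                    "score": "" if cs.score is None else cs.score,
                    "grade": "" if cs.score is None else DEFAULT_SCALE.grade_of(cs.score),
                    "complete": cs.complete,
                    "alternates_used": ";".join(f"{m}->{a}" for m, a in cs.alternates_used),
                }
            )
    pd.DataFrame(score_rows).to_csv(outdir / "scores.csv", index=False)

    # (c) stratified grade matrix
    gm = grade_matrix(
        rs, cfg.score, DEFAULT_SCALE, cfg.threshold_pct, cfg.min_stratum_n
    )
    gm.frame.to_csv(outdir / "grade_matrix.csv")
    (outdir / "grade_matrix.md").write_text(
        "# Population welfare grades by stratum\n\n" + _markdown_table(gm.frame),
        encoding="utf-8",
    )

    # (d) poor-welfare drivers per category
    drivers = {}
    for cat in CATEGORIES:
        dr = driver_report(rs, cat, cfg.score)
        dr.frame.to_csv(outdir / f"drivers_{cat}.csv")
        drivers[cat] = dr

    # (e) response tables, one file per category
    for cat in CATEGORIES:
        parts = []
        for q in rs.schema:
            if q.category != cat:
                continue
            if not any(r.responses.get(q.question_id) for r in rs):
                continue
            tbl = response_table(rs, q.question_id)
            tbl = tbl.assign(question=q.prompt).set_index("question", append=True)
            parts.append(tbl.reorder_levels(["question", "response"]))
        if parts:
            pd.concat(parts).to_csv(outdir / f"responses_{cat}.csv")

    # (f) class description of handler attitude
    entries = describe_class(
        rs, cfg.class_question, alpha=cfg.alpha, bh=cfg.bh
    )
    pd.DataFrame([asdict(e) for e in entries]).to_csv(outdir / "class_description.csv", index=False)
    (outdir / "class_description.md").write_text(
        "# Handler-attitude class description\n\n" + render_class_description(entries, rs),
        encoding="utf-8",
    )

    # (g) manifest
    manifest = {
        "package": "equiwag",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_records": len(rs),
        "n_kilns": len({r.kiln_id for r in rs}),
        "n_handlers": len({r.handler_id for r in rs}),
        "n_class_description_entries": len(entries),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    return {
        "records": rs,
        "scores": scores,
        "grade_matrix": gm,
        "drivers": drivers,
        "class_description": entries,
        "manifest": manifest,
        "outdir": str(outdir),
    }
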