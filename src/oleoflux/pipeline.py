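"""End-to-end run orchestration: screen → classify → FSEOF → gene mapping.

:func:`run_pipeline` composes the stage modules over one model and one
phenotype plate, writes all stage tables plus a machine-readable manifest
into the output directory, and is bit-reproducible: rerunning the same
configuration yields identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .fba_engine import ACTIVITY_EPSILON, GROWTH_THRESHOLD
from .fseof_scan import aggregate_fseof, map_targets_to_genes, run_fseof
from .model_io import read_model, read_plate
from .phenotype_screen import (
    DEFAULT_FREE_EXCHANGES,
    MediumSpec,
    classify_reaction_activity,
    default_source_to_exchange,
    mean_active_reactions,
    screen_carbon_sources,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure with stage name and context."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one end-to-end run depends on, thresholds included."""

    model_path: str
    plate_path: str
    output_dir: str
    product_reaction: str | None = None
    free_exchange_ids: tuple[str, ...] = DEFAULT_FREE_EXCHANGES
    carbon_uptake_bound: float = 10.0
    growth_threshold: float = GROWTH_THRESHOLD
    activity_epsilon: float = ACTIVITY_EPSILON
    activity_thresholds: tuple[float, float] = (0.10, 0.90)
    fseof_min_sources: int = 5
    fseof_slope_threshold: float = 2.0
    fseof_n_steps: int = 10
    fseof_max_fraction: float = 0.9
    min_positive_replicates: int = 2
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or YAML (by suffix)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for key in ("free_exchange_ids", "activity_thresholds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _write_tsv(df, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and return the run directory.

    Writes ``concordance.tsv``, ``activity.tsv``, ``fseof_slopes.tsv``,
    ``fseof_targets.tsv`` and ``manifest.json``.  Any stage error aborts
    with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        model = read_model(config.model_path)
    except Exception as exc:
        raise PipelineError("load_model", str(exc)) from exc
    try:
        plate = read_plate(config.plate_path)
    except Exception as exc:
        raise PipelineError("load_plate", str(exc)) from exc

    medium = MediumSpec(
        free_exchange_ids=tuple(config.free_exchange_ids),
        carbon_uptake_bound=config.carbon_uptake_bound,
    )

    try:
        concordance, solutions = screen_carbon_sources(
            model,
            plate,
            medium_template=medium,
            growth_threshold=config.growth_threshold,
            min_positive=config.min_positive_replicates,
        )
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc
    concordance_df = concordance.to_dataframe().sort_values("source")
    _write_tsv(concordance_df, out / "concordance.tsv")

    feasible = {
        src: sol for src, sol in solutions.items() if sol.optimal
    }
    try:
        profile = classify_reaction_activity(
            list(feasible.values()),
            thresholds=config.activity_thresholds,
            activity_epsilon=config.activity_epsilon,
        )
    except Exception as exc:
        raise PipelineError("classify_activity", str(exc)) from exc
    activity_df = profile.to_dataframe().sort_values("reaction")
    _write_tsv(activity_df, out / "activity.tsv")

    scans = []
    if config.product_reaction:
        growing = sorted(
            src
            for src, sol in feasible.items()
            if sol.objective_value > config.growth_threshold
        )
        for src in growing:
            exchange_id = default_source_to_exchange(src)
            try:
                from .phenotype_screen import configure_medium

                configured = configure_medium(model, medium.with_carbon(exchange_id))
                scan = run_fseof(
                    configured,
                    product_rxn=config.product_reaction,
                    n_steps=config.fseof_n_steps,
                    max_fraction=config.fseof_max_fraction,
                    carbon_source=src,
                    growth_threshold=config.growth_threshold,
                    activity_epsilon=config.activity_epsilon,
                )
            except Exception as exc:
                raise PipelineError("fseof", f"source {src!r}: {exc}") from exc
            if not scan.reason:
                scans.append(scan)
    if scans:
        try:
            targets = aggregate_fseof(
                scans,
                min_sources=config.fseof_min_sources,
                slope_threshold=config.fseof_slope_threshold,
            )
            targets = map_targets_to_genes(targets, model)
        except Exception as exc:
            raise PipelineError("aggregate_fseof", str(exc)) from exc
        _write_tsv(targets.long_table(), out / "fseof_slopes.tsv")
        _write_tsv(targets.target_table(), out / "fseof_targets.tsv")
        fseof_summary = {
            "n_sources_scanned": len(scans),
            "n_reactions_reported": len(targets.slopes),
            "n_reactions_retained": len(targets.retained),
            "n_genes": len(targets.gene_set),
            "orphan_reactions": sorted(targets.orphan_reactions),
        }
    else:
        fseof_summary = {"n_sources_scanned": 0}

    manifest = {
        "tool": "oleoflux",
        "version": __version__,
        "config": asdict(config),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
        "screen": {
            "n_sources": len(plate),
            "counts": {
                "both_growth": concordance.both_growth,
                "both_no_growth": concordance.both_no_growth,
                "false_no_growth": concordance.false_no_growth,
                "false_growth": concordance.false_growth,
            },
            "agreement_percent": round(concordance.agreement_percent, 2),
            "n_feasible_solutions": len(feasible),
            "mean_active_reactions": (
                round(mean_active_reactions(list(feasible.values())), 2)
                if feasible
                else None
            ),
        },
        "activity": {
            "always_active": len(profile.always_active),
            "active_at_least_once": len(profile.active_at_least_once),
            "never_active": len(profile.never_active),
            "auxiliary_shares_percent": [
                round(s, 2) for s in profile.auxiliary_shares
            ],
        },
        "fseof": fseof_summary,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return out
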