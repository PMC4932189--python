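"""End-to-end orchestration: events -> MDE -> smoothing -> bias cut -> change points.

`run_pipeline` composes the full meta-analysis with the published defaults
(70 Ma span, 1-Myr slices, 5-Myr smoothing window, 500 permutations,
significance 0.05, minimum segment 5, moment index 1.0, avian recency-bias
truncation on) and writes, per requested stratum: the raw and smoothed MDE
series as TSV, the change-point result as JSON, and a run log recording
every parameter actually used.  The run is deterministic given the config
and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import yaml

from .changepoint import ChangePointResult, EDivisiveParams, e_divisive
from .events import EventTable, read_events
from .mde import (
    MDESeries,
    TimeGrid,
    avian_bias_cutoff,
    avian_nonavian_split,
    compute_mde,
    smooth_series,
    stratified_mde,
    truncate_series,
)

logger = logging.getLogger("mdeflux")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "plot_series"]


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on, round-trippable through YAML."""

    events_path: str
    out_dir: str
    t_max: int = 70
    window_myr: int = 5
    bias_correct: bool = True
    strata: tuple[str, ...] = ("pooled", "direction")
    changepoint_stage: Literal["raw", "smoothed"] = "smoothed"
    n_permutations: int = 500
    sig_level: float = 0.05
    min_size: int = 5
    alpha: float = 1.0
    seed: int | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        cfg["strata"] = tuple(cfg.get("strata", ("pooled", "direction")))
        return cls(**cfg)


@dataclass
class PipelineResult:
    """In-memory bundle mirroring what `run_pipeline` writes to disk."""

    config: PipelineConfig
    truncation_age: int
    raw: dict[str, MDESeries]
    smoothed: dict[str, MDESeries]
    change_points: dict[str, ChangePointResult]


def _series_for_strata(
    table: EventTable, grid: TimeGrid, strata: tuple[str, ...]
) -> dict[str, MDESeries]:
    out: dict[str, MDESeries] = {}
    for spec in strata:
        if spec == "pooled":
            out["pooled"] = compute_mde(table, grid, label="pooled")
        elif spec == "direction":
            out.update(stratified_mde(table, grid, by="direction"))
        elif spec == "taxon":
            out.update(stratified_mde(table, grid, by="taxon"))
        else:
            raise ValueError(
                f"unknown stratum request {spec!r} "
                "(expected 'pooled', 'direction' or 'taxon')"
            )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the result bundle to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config: %s", json.dumps(asdict(config), sort_keys=True))
        try:
            table = read_events(config.events_path)
        except Exception as exc:
            raise RuntimeError(
                f"stage events_io failed on {config.events_path!r}: {exc}"
            ) from exc
        logger.info("read %d events from %s", len(table), config.events_path)

        grid = TimeGrid(config.t_max)
        raw = _series_for_strata(table, grid, config.strata)
        smoothed = {
            lab: smooth_series(s, config.window_myr) for lab, s in raw.items()
        }

        cutoff = 0
        if config.bias_correct:
            avian, non_avian = avian_nonavian_split(table, grid, config.window_myr)
            cutoff = avian_bias_cutoff(avian, non_avian)
            logger.info("avian/non-avian intersection: truncating below %d Ma", cutoff)
        if cutoff:
            raw = {lab: truncate_series(s, cutoff) for lab, s in raw.items()}
            smoothed = {lab: truncate_series(s, cutoff) for lab, s in smoothed.items()}

        params = EDivisiveParams(
            n_permutations=config.n_permutations,
            sig_level=config.sig_level,
            min_size=config.min_size,
            alpha=config.alpha,
            seed=config.seed,
        )
        source = smoothed if config.changepoint_stage == "smoothed" else raw
        change_points: dict[str, ChangePointResult] = {}
        for lab, series in source.items():
            if len(series.values) < 2 * config.min_size:
                logger.warning(
                    "stratum %s: series too short for change-point analysis", lab
                )
                continue
            try:
                change_points[lab] = e_divisive(series, params)
            except Exception as exc:
                raise RuntimeError(
                    f"stage changepoint failed on stratum {lab!r}: {exc}"
                ) from exc
            logger.info(
                "stratum %s: %d change point(s) at %s Ma",
                lab,
                len(change_points[lab].change_points),
                change_points[lab].ages(),
            )

        for lab in raw:
            raw[lab].to_dataframe().to_csv(
                out_dir / f"mde_raw_{lab}.tsv", sep="\t", index=False
            )
            smoothed[lab].to_dataframe().to_csv(
                out_dir / f"mde_smoothed_{lab}.tsv", sep="\t", index=False
            )
        bundle = {
            "truncation_age_ma": cutoff,
            "params": {
                "t_max": config.t_max,
                "window_myr": config.window_myr,
                "bias_correct": config.bias_correct,
                "changepoint_stage": config.changepoint_stage,
                "n_permutations": config.n_permutations,
                "sig_level": config.sig_level,
                "min_size": config.min_size,
                "alpha": config.alpha,
                "seed": config.seed,
            },
            "change_points": {
                lab: [cp._asdict() for cp in res.change_points]
                for lab, res in change_points.items()
            },
        }
        with open(out_dir / "changepoints.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        return PipelineResult(
            config=config,
            truncation_age=cutoff,
            raw=raw,
            smoothed=smoothed,
            change_points=change_points,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def plot_series(
    result: PipelineResult, out_dir: str | Path | None = None
) -> list[Path]:
    """One figure per stratum: MDE against age with change points marked.

    The age axis is reversed (present on the right), the palaeo convention.
    Plot failures warn and continue; this never aborts a pipeline run.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out = Path(out_dir or result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for lab, series in result.smoothed.items():
        try:
            fig, ax = plt.subplots(figsize=(7, 3.5))
            raw = result.raw.get(lab)
            if raw is not None:
                ax.step(raw.ages, raw.values, where="mid", color="0.75",
                        lw=0.8, label="raw MDE")
            ax.plot(series.ages, series.values, color="tab:blue", lw=1.6,
                    label="smoothed MDE")
            cps = result.change_points.get(lab)
            if cps is not None:
                top = max(float(series.values.max()), 1.0)
                for cp in cps.change_points:
                    ax.annotate(
                        "",
                        xy=(cp.age_ma, top * 1.02),
                        xytext=(cp.age_ma, top * 1.18),
                        arrowprops=dict(arrowstyle="-|>", color="black"),
                    )
            ax.set_xlim(series.ages.max(), series.ages.min())
            ax.set_xlabel("age (Ma)")
            ax.set_ylabel("MDE (events / Myr)")
            ax.set_title(lab)
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            path = out / f"mde_{lab}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("plotting stratum %s failed: %s", lab, exc)
    return written
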