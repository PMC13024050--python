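"""End-to-end experiment orchestration.

One call runs the full chain — simulate (or load) chamber and plant
traces, construct environment-defined labels, window into features,
decode valence / arousal / quadrant with the linear readout and the
ESN, run circular-shift nulls — and writes a report bundle: metrics
JSON, per-task confusion CSVs, the valence-arousal trajectory table and
a log.

A hard provenance guard enforces the study's central constraint: no
environmental channel may ever enter the decoder feature set.  Labels
come from the environment; features come only from internal plant
signals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoders import ESNWindowDecoder, RidgeWindowDecoder
from .errors import ConfigError
from .esn import ReservoirConfig
from .evaluation import MetricsReport, evaluate_pipeline
from .features import WindowSpec, WindowTable, make_windows, window_starts
from .io import read_trace_csv, write_trace_csv
from .labels import AffectLabels, LabelConfig, build_labels
from .nullcontrol import NullSpec, run_null
from .synthetic import (
    ChamberConfig,
    CouplingConfig,
    EnvironmentTrace,
    PlantTrace,
    simulate_environment,
    simulate_plant,
)

__all__ = ["RunConfig", "run_experiment", "trajectory_table", "check_feature_provenance"]

log = logging.getLogger(__name__)

#: channels that must never appear among decoder features
ENV_CHANNELS = frozenset(
    {"temperature", "humidity", "light", "infrared", "heater", "fan"}
)


@dataclass
class RunConfig:
    """Complete, serialisable description of one experiment run."""

    chamber: ChamberConfig = field(default_factory=ChamberConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    label: LabelConfig = field(default_factory=LabelConfig)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)
    valence_window: WindowSpec = field(default_factory=lambda: WindowSpec(20.0, 15.0))
    arousal_window: WindowSpec = field(default_factory=lambda: WindowSpec(1.0, 1.0))
    quadrant_window: WindowSpec = field(default_factory=lambda: WindowSpec(1.0, 1.0))
    trajectory_window_min: float = 7.0
    n_splits: int = 5
    ridge_penalty: float = 1.0
    feature_channels: tuple[str, ...] = PlantTrace.CHANNELS
    valence_null: NullSpec | None = field(
        default_factory=lambda: NullSpec(min_shift=360.0, n_permutations=20, scope="v")
    )
    arousal_null: NullSpec | None = field(
        default_factory=lambda: NullSpec(min_shift=60.0, n_permutations=20, scope="a")
    )
    env_csv: str | None = None
    plant_csv: str | None = None
    run_id: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        check_feature_provenance(self.feature_channels)

    def reseed(self, seed: int) -> "RunConfig":
        """Derive all sub-seeds from one global seed."""
        import dataclasses

        return dataclasses.replace(
            self,
            seed=seed,
            chamber=dataclasses.replace(self.chamber, seed=seed),
            coupling=dataclasses.replace(self.coupling, seed=seed + 1),
            reservoir=dataclasses.replace(self.reservoir, seed=seed + 2),
            valence_null=(
                dataclasses.replace(self.valence_null, seed=seed + 3)
                if self.valence_null
                else None
            ),
            arousal_null=(
                dataclasses.replace(self.arousal_null, seed=seed + 4)
                if self.arousal_null
                else None
            ),
        )


def check_feature_provenance(channels) -> None:
    """Refuse any feature channel that is (or names) an environmental one."""
    offending = sorted(set(c.lower() for c in channels) & ENV_CHANNELS)
    if offending:
        raise ConfigError(
            f"environmental channels {offending} may not be decoder features; "
            "the decoder must only ever observe internal plant signals"
        )


def trajectory_table(
    labels: AffectLabels, window_min: float = 7.0
) -> pd.DataFrame:
    """Non-overlapping aggregated (V, A) windows for the affective-space
    trajectory: one row per window, ordered by window index."""
    period = float(labels.timestamps[1] - labels.timestamps[0])
    wlen = max(1, int(round(window_min * 60.0 / period)))
    starts = window_starts(len(labels), wlen, wlen)
    rows = []
    for idx, s in enumerate(starts):
        sl = slice(s, s + wlen)
        rows.append(
            {
                "window_index": idx,
                "t_start": labels.timestamps[s],
                "V": float(np.mean(labels.V_smooth[sl])),
                "A": float(np.mean(labels.A_smooth[sl])),
                "valid_fraction": float(np.mean(labels.valid[sl])),
            }
        )
    return pd.DataFrame(rows)


def _prepare_traces(cfg: RunConfig) -> tuple[EnvironmentTrace, PlantTrace]:
    if cfg.env_csv:
        env = read_trace_csv(cfg.env_csv, "environment")
    else:
        env = simulate_environment(cfg.chamber)
    if cfg.plant_csv:
        plant = read_trace_csv(cfg.plant_csv, "plant")
    else:
        plant = simulate_plant(env, cfg.coupling)
    return env, plant


def run_experiment(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full decoding experiment; return (and write) the report.

    Sections: valence (20/15 min linear), arousal (1 min linear),
    quadrant via combined binaries, quadrant via ESN, plus the
    circular-shift nulls and the trajectory table.
    """
    check_feature_provenance(cfg.feature_channels)
    env, plant = _prepare_traces(cfg)
    labels = build_labels(env, cfg.label)
    log.info(
        "run %s: %d samples, %.0f%% valid after dead-zone/IR masking",
        cfg.run_id, len(labels), 100.0 * labels.valid.mean(),
    )

    tables: dict[str, WindowTable] = {
        "valence": make_windows(plant, labels, cfg.valence_window),
        "arousal": make_windows(plant, labels, cfg.arousal_window),
        "quadrant": make_windows(plant, labels, cfg.quadrant_window),
    }
    for name, table in tables.items():
        check_feature_provenance(
            n.split("_", 1)[1] for n in table.feature_names
        )
        log.info("%s windows: %d rows", name, len(table))

    ridge = lambda: RidgeWindowDecoder(cfg.ridge_penalty)  # noqa: E731
    esn = lambda: ESNWindowDecoder(cfg.reservoir)  # noqa: E731

    reports: dict[str, MetricsReport] = {
        "valence": evaluate_pipeline(
            tables["valence"], ridge, target="v", n_splits=cfg.n_splits
        ),
        "arousal": evaluate_pipeline(
            tables["arousal"], ridge, target="a", n_splits=cfg.n_splits
        ),
        "quadrant_combined": evaluate_pipeline(
            tables["quadrant"], ridge, target="q", n_splits=cfg.n_splits
        ),
        "quadrant_esn": evaluate_pipeline(
            tables["quadrant"], esn, target="q", n_splits=cfg.n_splits
        ),
    }

    nulls = {}
    if cfg.valence_null:
        nulls["valence_null"] = run_null(
            tables["valence"], ridge, cfg.valence_null, n_splits=cfg.n_splits
        )
    if cfg.arousal_null:
        nulls["arousal_null"] = run_null(
            tables["arousal"], ridge, cfg.arousal_null, n_splits=cfg.n_splits
        )

    traj = trajectory_table(labels, cfg.trajectory_window_min)

    report = {
        "run_id": cfg.run_id,
        "seed": cfg.seed,
        "n_samples": len(labels),
        "quadrant_chance_level": 0.25,
        "metrics": {k: r.to_dict() for k, r in reports.items()},
        "nulls": {k: r.to_dict() for k, r in nulls.items()},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "metrics.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        for k, r in reports.items():
            pd.DataFrame(
                r.pooled_confusion.astype(int),
                index=[f"true_{c}" for c in r.classes],
                columns=[f"pred_{c}" for c in r.classes],
            ).to_csv(outdir / f"confusion_{k}.csv")
        traj.to_csv(outdir / "trajectory.csv", index=False)
        if not cfg.env_csv:
            write_trace_csv(env, outdir / "environment.csv")
        if not cfg.plant_csv:
            write_trace_csv(plant, outdir / "plant.csv")
        log.info("report bundle written to %s", outdir)

    report["_reports"] = reports
    report["_nulls"] = nulls
    report["_trajectory"] = traj
    return report
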