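"""End-to-end pipeline: read -> blank-correct -> metrics -> calibrate/fitness.

The pipeline is configured by one mapping (usually a YAML file)::

    channels:                 # one wide CSV per channel
      OD600: od600.csv
      red: red.csv
    layout: layout.yaml
    blank: true               # blank-correct before metrics
    blank_mode: per_timepoint
    out_dir: results
    seed: 0                   # recorded in the run log
    calibrate:                # optional stage
      od_channel: OD600
      fluo_channel: red
      method: ols
      average_replicates: false
    fitness:                  # optional stage
      focal: Pe_red
      channel: red
      monoculture_condition: monoculture
      all_pairs: false

Outputs are CSV files plus a ``run_log.txt`` recording the package version,
seed and parameters.  Content is fully determined by the config (and seed):
no wall-clock state leaks into any output.  On failure partial outputs are
removed and the stage's error propagates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .calibration import correlation_grid
from .errors import ConfigurationError, FluoGrowthError
from .fitness import fitness_from_metrics
from .metrics import metrics_table
from .platedata import read_layout, read_plate_timeseries, write_plate_timeseries
from .preprocess import blank_correct

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    channels: dict[str, str]
    layout: str
    out_dir: str
    blank: bool = True
    blank_mode: str = "per_timepoint"
    time_unit: str = "h"
    seed: int = 0
    calibrate: dict | None = None
    fitness: dict | None = None

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        try:
            cfg = cls(
                channels=dict(doc["channels"]),
                layout=str(doc["layout"]),
                out_dir=str(doc["out_dir"]),
                blank=bool(doc.get("blank", True)),
                blank_mode=str(doc.get("blank_mode", "per_timepoint")),
                time_unit=str(doc.get("time_unit", "h")),
                seed=int(doc.get("seed", 0)),
                calibrate=doc.get("calibrate"),
                fitness=doc.get("fitness"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"pipeline config missing key {exc}") from exc
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        missing = [p for p in [self.layout, *self.channels.values()]
                   if not os.path.isfile(p)]
        if missing:
            raise ConfigurationError(f"missing input file(s): {missing}")


def run_pipeline(config: PipelineConfig | dict | str) -> list[str]:
    """Run the configured stages; return the list of files written.

    Accepts a :class:`PipelineConfig`, a config mapping, or a path to a
    YAML config.  Raises (after removing partial outputs) on any stage
    error.
    """
    if isinstance(config, (str, os.PathLike)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []

    def out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        written.append(path)
        return path

    try:
        layout = read_layout(config.layout)
        ts = None
        for channel in sorted(config.channels):
            frag = read_plate_timeseries(
                config.channels[channel],
                channel,
                time_unit=config.time_unit,
                layout_ref=layout.plate_id,
                n_rows=layout.n_rows,
                n_cols=layout.n_cols,
            )
            ts = frag if ts is None else ts.merge(frag)
        if ts is None:
            raise ConfigurationError("no channel files configured")

        if config.blank:
            for channel in sorted(config.channels):
                ts, report = blank_correct(
                    ts, layout, channel, mode=config.blank_mode
                )
                report.to_frame().to_csv(
                    out(f"correction_{channel}.csv"), index=False
                )
                write_plate_timeseries(ts, channel, out(f"corrected_{channel}.csv"))

        metrics = metrics_table(ts, layout)
        metrics.to_csv(out("metrics.csv"), index=False)

        if config.calibrate:
            cal = dict(config.calibrate)
            grid = correlation_grid(
                metrics,
                od_channel=cal["od_channel"],
                fluo_channel=cal["fluo_channel"],
                method=cal.get("method", "ols"),
                average_replicates=bool(cal.get("average_replicates", False)),
            )
            grid.to_frame().to_csv(out("calibration.csv"), index=False)

        if config.fitness:
            fit = dict(config.fitness)
            _, anova, table = fitness_from_metrics(
                metrics,
                focal_strain=fit["focal"],
                channel=fit["channel"],
                monoculture_condition=fit["monoculture_condition"],
                all_pairs=bool(fit.get("all_pairs", False)),
            )
            table.to_csv(out("fitness.csv"), index=False)
            if anova is not None:
                anova_rows = [
                    {
                        "term": "one_way_anova",
                        "group_a": "",
                        "group_b": "",
                        "statistic": anova.f_statistic,
                        "df_between": anova.df_between,
                        "df_within": anova.df_within,
                        "raw_p": anova.p_value,
                        "bonferroni_p": "",
                    }
                ] + [
                    {
                        "term": "posthoc_t",
                        "group_a": a,
                        "group_b": b,
                        "statistic": "",
                        "df_between": "",
                        "df_within": "",
                        "raw_p": raw,
                        "bonferroni_p": bonf,
                    }
                    for (a, b), raw, bonf in anova.posthoc
                ]
                pd.DataFrame(anova_rows).to_csv(out("anova.csv"), index=False)

        with open(out("run_log.txt"), "w", encoding="utf-8") as fh:
            fh.write(f"fluogrowth {__version__}\n")
            fh.write(f"seed: {config.seed}\n")
            fh.write(f"layout: {config.layout}\n")
            fh.write(f"channels: {config.channels}\n")
            fh.write(f"blank: {config.blank} mode: {config.blank_mode}\n")
    except Exception:
        for path in written:
            if os.path.isfile(path):
                os.unlink(path)
        raise
    return written
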