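"""Config-driven orchestration: simulate -> ERP stats -> decoding -> behavior.

Stages stream one participant at a time (a full experiment's epochs would
not fit in memory at once) and every stage draws from substreams derived
from the global seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    condition_matrix_from_table,
    friedman_kendall_w,
    pairwise_battery,
    rm_anova_gg,
)
from .decoding import (
    DecoderConfig,
    decode_cross_phase,
    decode_within_phase,
    decoding_cluster_test,
    stack_timecourses,
)
from .erp import ClusterTestConfig, ErpMatrix, cluster_permutation_test, condition_erp
from .scheduler import schedule_to_tsv
from .synth import GeneratorParams, SyntheticExperiment

CROSS_PHASE_WINDOWS_MS = {
    "encoding": (0.0, 500.0),
    "wm": (300.0, 800.0),
    "retrieval": (500.0, 1000.0),
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    experiment: int = 1
    generator: GeneratorParams | None = None
    cluster: ClusterTestConfig | None = None
    decoder: DecoderConfig | None = None
    stages: tuple = ("simulate", "erp", "decode", "behavior")
    erp_contrasts: tuple | None = None  # default: all condition pairs
    decode_time_step: int = 4  # decode every k-th sample (within-phase)
    decode_phases: tuple = ("encoding",)
    cross_phase_pairs: tuple = ()  # e.g. (("encoding", "retrieval"),)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.experiment not in (1, 2):
            raise ConfigError("experiment must be 1 or 2")
        unknown = set(self.stages) - {"simulate", "erp", "decode", "behavior"}
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.generator is None:
            self.generator = GeneratorParams(experiment=self.experiment, seed=self.seed)
        if self.generator.experiment != self.experiment:
            raise ConfigError("generator.experiment disagrees with experiment")
        if self.cluster is None:
            self.cluster = ClusterTestConfig(seed=self.seed + 101)
        if self.decoder is None:
            self.decoder = DecoderConfig(seed=self.seed + 202)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a validated config from a plain (YAML-loaded) mapping."""
    raw = dict(raw)
    try:
        for key, cls in (
            ("generator", GeneratorParams),
            ("cluster", ClusterTestConfig),
            ("decoder", DecoderConfig),
        ):
            if isinstance(raw.get(key), dict):
                raw[key] = cls(**raw[key])
        for key in ("stages", "erp_contrasts", "decode_phases", "cross_phase_pairs"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        return PipelineConfig(**raw)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


@dataclass
class RunReport:
    config: dict
    version: str
    outputs: dict = field(default_factory=dict)  # stage -> {name: path}
    summaries: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)


def _retrieval_erp_matrix(exp: SyntheticExperiment, window=(0.0, 1200.0)) -> ErpMatrix:
    """Participant-by-participant condition ERPs (memory-bounded)."""
    from .preprocess import baseline_correct

    mats = []
    conditions = None
    times = None
    for p in range(exp.params.n_participants):
        ep = baseline_correct(exp.epochs(p, "retrieval"))
        m = condition_erp([ep], window=window)
        if conditions is None:
            conditions, times = m.conditions, m.times
        mats.append(m.values[0])
    return ErpMatrix(
        values=np.stack(mats), times=times, conditions=conditions,
        analysis_window=tuple(window),
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=_config_echo(config), version=__version__)

    exp = SyntheticExperiment(config.generator)
    behavior_table = None

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                paths = {}
                for name, sched in (
                    ("encoding", exp.encoding), ("wm", exp.wm), ("retrieval", exp.retrieval),
                ):
                    path = out / f"schedule_{name}.tsv"
                    schedule_to_tsv(sched, path)
                    paths[f"schedule_{name}"] = str(path)
                behavior_table = exp.behavior_table()
                bpath = out / "behavior.csv"
                behavior_table.to_csv(bpath, index=False)
                paths["behavior"] = str(bpath)
                report.outputs[stage] = paths
                report.summaries[stage] = {
                    "n_objects": len(exp.objects),
                    "n_trials": {
                        "encoding": exp.encoding.n_trials,
                        "wm": exp.wm.n_trials,
                        "retrieval": exp.retrieval.n_trials,
                    },
                    "n_participants": config.generator.n_participants,
                }
            elif stage == "erp":
                erp = _retrieval_erp_matrix(exp)
                contrasts = config.erp_contrasts
                if contrasts is None:
                    from itertools import combinations

                    contrasts = tuple(combinations(erp.conditions, 2))
                results = {}
                paths = {}
                for a, b in contrasts:
                    res = cluster_permutation_test(erp, a, b, config.cluster)
                    key = f"{a}_vs_{b}"
                    path = out / f"erp_clusters_{key}.json"
                    res.to_json(path)
                    paths[key] = str(path)
                    results[key] = {
                        "significant_clusters_ms": [
                            [c[0], c[1]] for c in res.significant_clusters
                        ],
                        "size_threshold": res.size_threshold,
                    }
                report.outputs[stage] = paths
                report.summaries[stage] = results
            elif stage == "decode":
                paths = {}
                summaries = {}
                for phase in config.decode_phases:
                    tcs = []
                    for p in range(config.generator.n_participants):
                        ep = exp.epochs(p, phase)
                        step = max(1, config.decode_time_step)
                        idx = np.arange(0, len(ep.times), step)
                        tcs.append(
                            decode_within_phase(ep, config.decoder, time_indices=idx)
                        )
                    group = stack_timecourses(tcs)
                    res = decoding_cluster_test(group, config.cluster)
                    df = pd.DataFrame(group.accuracy, columns=[f"{t:.0f}" for t in group.times])
                    path = out / f"decoding_within_{phase}.csv"
                    df.to_csv(path, index_label="participant")
                    paths[f"within_{phase}"] = str(path)
                    jpath = out / f"decoding_within_{phase}_clusters.json"
                    res.to_json(jpath)
                    paths[f"within_{phase}_clusters"] = str(jpath)
                    summaries[f"within_{phase}"] = {
                        "chance_level": group.chance_level,
                        "mean_peak_accuracy": float(group.accuracy.mean(axis=0).max()),
                        "significant_clusters_ms": [
                            [c[0], c[1]] for c in res.significant_clusters
                        ],
                    }
                for pair in config.cross_phase_pairs:
                    a, b = pair
                    tcs = []
                    for p in range(config.generator.n_participants):
                        tcs.append(
                            decode_cross_phase(
                                exp.epochs(p, a), CROSS_PHASE_WINDOWS_MS[a],
                                exp.epochs(p, b), CROSS_PHASE_WINDOWS_MS[b],
                                config.decoder,
                            )
                        )
                    group = stack_timecourses(tcs)
                    res = decoding_cluster_test(group, config.cluster)
                    key = f"cross_{a}_{b}"
                    path = out / f"decoding_{key}.csv"
                    pd.DataFrame(
                        group.accuracy, columns=[f"{t:.0f}" for t in group.times]
                    ).to_csv(path, index_label="participant")
                    paths[key] = str(path)
                    summaries[key] = {
                        "chance_level": group.chance_level,
                        "mean_accuracy": float(group.accuracy.mean()),
                        "significant_clusters_relms": [
                            [c[0], c[1]] for c in res.significant_clusters
                        ],
                    }
                report.outputs[stage] = paths
                report.summaries[stage] = summaries
            elif stage == "behavior":
                if behavior_table is None:
                    behavior_table = exp.behavior_table()
                summaries = {}
                paths = {}
                for value in ("accuracy", "rt"):
                    cm = condition_matrix_from_table(behavior_table, value=value)
                    omni = rm_anova_gg(cm)
                    chi2, p_fried, w = friedman_kendall_w(cm)
                    pw = pairwise_battery(cm)
                    path = out / f"behavior_pairwise_{value}.csv"
                    pw.to_csv(path, index=False)
                    paths[value] = str(path)
                    summaries[value] = {
                        "condition_means": {
                            c: float(cm.column(c).mean()) for c in cm.conditions
                        },
                        "anova_F": omni.F,
                        "anova_p_gg": omni.p_corrected,
                        "epsilon_gg": omni.epsilon_gg,
                        "partial_eta_sq": omni.partial_eta_sq,
                        "friedman_chi2": chi2,
                        "friedman_p": p_fried,
                        "kendall_w": w,
                        "n_significant_pairs_fdr": int((pw["p_adj"] < 0.05).sum()),
                    }
                report.outputs[stage] = paths
                report.summaries[stage] = summaries
        except Exception as err:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, err) from err
        report.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
    return report


def _config_echo(config: PipelineConfig) -> dict:
    echo = {
        "seed": config.seed,
        "out_dir": config.out_dir,
        "experiment": config.experiment,
        "stages": list(config.stages),
        "generator": asdict(config.generator),
        "cluster": asdict(config.cluster),
        "decoder": asdict(config.decoder),
        "decode_time_step": config.decode_time_step,
        "decode_phases": list(config.decode_phases),
        "cross_phase_pairs": [list(p) for p in config.cross_phase_pairs],
    }
    return echo


def write_report(report: RunReport, path) -> str:
    """Validate outputs and write the JSON master report."""
    for stage, files in report.outputs.items():
        for name, fpath in files.items():
            if not Path(fpath).exists():
                raise ValueError(f"stage {stage!r} claims missing output {name}: {fpath}")
    payload = {
        "schema_version": 1,
        "software_version": report.version,
        "config": report.config,
        "outputs": report.outputs,
        "summaries": report.summaries,
        "wall_clock_s": report.wall_clock_s,
    }
    text = json.dumps(payload, indent=2, default=float)
    with open(path, "w") as fh:
        fh.write(text)
    return text


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
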