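"""Validated configuration and the end-to-end pipeline runner."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from . import anomaly_detect, connectivity, io, s1h2

__all__ = ["PipelineConfig", "run_pipeline"]

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    """Stage parameters for a full connect -> embed -> (cv) -> detect run."""

    series: str = ""
    out_dir: str = "run_out"
    tau: float | None = None
    use_abs: bool = True
    grid_lo: float = connectivity.DEFAULT_GRID[0]
    grid_hi: float = connectivity.DEFAULT_GRID[1]
    grid_step: float = connectivity.DEFAULT_GRID[2]
    retention_fraction: float = connectivity.DEFAULT_RETENTION
    seed: int = 0
    cv_reps: int = 0  # 0 disables the reproducibility stage
    tail: float = anomaly_detect.DEFAULT_TAIL
    controls_dir: str | None = None
    detect_mode: str = "hyperbolic"
    exact_distance: bool = False
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.tau is not None and not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if not 0.0 < self.retention_fraction <= 1.0:
            raise ValueError("retention_fraction must lie in (0, 1]")
        if not 0.0 < self.tail < 0.5:
            raise ValueError("tail must lie in (0, 0.5)")
        if self.detect_mode not in ("hyperbolic", "correlation"):
            raise ValueError(f"unknown detect_mode {self.detect_mode!r}")
        if self.cv_reps < 0:
            raise ValueError("cv_reps must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the staged pipeline, writing artifacts and a run log.

    Stages: correlation + thresholding -> LCC -> disc embedding ->
    optional repeated-embedding CV -> optional anomaly detection against a
    directory of control disc files.  Any stage failure raises with the stage
    name; artifacts written so far stay on disk.
    """
    series_path = Path(config.series)
    if not series_path.exists():
        raise FileNotFoundError(f"input series not found: {series_path}")
    if config.controls_dir is not None and not Path(config.controls_dir).is_dir():
        raise FileNotFoundError(f"controls directory not found: {config.controls_dir}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config), "stages": {}}

    def stage(name: str, fn):
        t0 = time.monotonic()
        try:
            artifacts = fn()
        except Exception as exc:
            log["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "run_log.json").write_text(json.dumps(log, indent=2))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log["stages"][name] = {
            "status": "ok",
            "seconds": round(time.monotonic() - t0, 3),
            "artifacts": {p.name: _checksum(p) for p in artifacts},
        }
        return artifacts

    state: dict = {}

    def s_connect():
        ts = io.read_series(series_path)
        corr = connectivity.pearson_matrix(ts)
        if config.tau is None:
            window = connectivity.threshold_window(
                corr, config.grid_lo, config.grid_hi, config.grid_step,
                config.retention_fraction, seed=config.seed,
            )
            if window.window is None:
                raise ValueError("no admissible threshold window for this subject")
            tau = window.window[1]  # sparsest admissible network
        else:
            tau = config.tau
        graph = connectivity.threshold_graph(corr, tau, use_abs=config.use_abs)
        lcc, retention = connectivity.largest_component(graph)
        state.update(corr=corr, lcc=lcc, tau=tau, retention=retention)
        io.write_matrix(corr, out / "correlation.csv")
        io.write_edgelist(lcc, out / "graph.edgelist", out / "graph.labels.tsv")
        return [out / "correlation.csv", out / "graph.edgelist", out / "graph.labels.tsv"]

    def s_embed():
        disc = s1h2.embed(state["lcc"], seed=config.seed)
        state["disc"] = disc
        io.write_disc(disc, out / "disc.csv")
        return [out / "disc.csv"]

    def s_cv():
        report = anomaly_detect.repeat_embed_cv(
            state["lcc"], n_rep=config.cv_reps, base_seed=config.seed,
            beta=state["disc"].beta,
        )
        path = out / "cv_report.tsv"
        with path.open("w") as fh:
            fh.write("i\tj\tedge_cv\n")
            for (i, j), cv in zip(report.edges, report.edge_cv):
                fh.write(f"{i}\t{j}\t{cv:.12g}\n")
        return [path]

    def s_detect():
        controls = sorted(Path(config.controls_dir).glob("*.csv"))
        discs = [io.read_disc(p) for p in controls]
        mats = [
            s1h2.disc_distance_matrix(d, exact=config.exact_distance) for d in discs
        ]
        control = anomaly_detect.build_control(
            mats, tail=config.tail, normality=False,
            min_subjects=min(20, len(mats)),
        )
        test_d = s1h2.disc_distance_matrix(
            state["disc"], exact=config.exact_distance
        )
        report = anomaly_detect.flag_edges(test_d, control, tail=config.tail)
        path = out / "anomaly_report.tsv"
        with path.open("w") as fh:
            fh.write("i\tj\tvalue\tpercentile\tflag\n")
            for flag, pairs in (("long", report.long_edges), ("short", report.short_edges)):
                for i, j in pairs:
                    fh.write(
                        f"{i}\t{j}\t{test_d[i, j]:.12g}"
                        f"\t{report.percentile[i, j]:.6g}\t{flag}\n"
                    )
        return [path]

    stage("connect", s_connect)
    stage("embed", s_embed)
    if config.cv_reps:
        stage("cv", s_cv)
    if config.controls_dir is not None:
        stage("detect", s_detect)

    log["tau"] = float(state["tau"])
    log["retention"] = float(state["retention"])
    log["seed"] = config.seed
    log["numpy_version"] = np.__version__
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
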