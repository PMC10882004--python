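"""Run configuration, deterministic result serialization, and the
experiment driver behind the command-line interface.

A run is described by a YAML/JSON config with three sections::

    cohort:            # either generative parameters ...
      n_participants: 506
      gt_mean: 0.978
      gt_sd: 1.899
      gt_grid: 0.5
      pred_correlation: 0.601
      indices:
        - {name: adas_cog, correlation: 0.45, mean: 10.0, sd: 4.5}
      # ... or a CSV produced by this package:
      # csv: cohort.csv
    methods:
      - {tag: nonstratified}
      - {tag: ai, index: pred_change}          # interval/shift/min/max optional
    experiment:
      n: 500
      n_reps: 10000
      x_grid: [10, 20, 30, 38, 50]
      seed: 1
      r: 0.3             # PES half-width target for the samplesize stage

Everything is overridable from the CLI; the fully resolved config and seed
are echoed into the summary so a run is self-describing.  Randomness is
split from the single root seed as ``SeedSequence(seed,
spawn_key=(stage_id, method_index))``, so every stage/method pair has an
independent substream regardless of which stages actually run.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import estimate_bias_distribution, sae_reduction
from .cohort import Cohort, CohortParams, IndexSpec, generate_cohort
from .multiphase import PhaseConfig, success_rate
from .randomize import RandomizationMethod, StrataSpec
from .sample_size import build_sae_curve, default_grid, min_sample_size, sample_size_reduction
from .trial import detection_rates, pvalue_summary

__all__ = ["RunConfig", "load_config", "run_experiment", "write_json", "STAGES"]

STAGES = ("sae", "samplesize", "trial", "multiphase")
_STAGE_ID = {name: i for i, name in enumerate(STAGES)}


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


@dataclass
class RunConfig:
    """Fully resolved run description."""

    cohort_params: CohortParams | None
    cohort_csv: str | None
    methods: list[dict]
    n: int = 500
    n_reps: int = 10_000
    x_grid: tuple[float, ...] = tuple(range(10, 51, 2))
    seed: int = 0
    r: float = 0.3
    s_max: int = 3000
    phase: PhaseConfig = field(default_factory=PhaseConfig)

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(
            cohort_params=CohortParams(),
            cohort_csv=None,
            methods=[{"tag": "nonstratified"}, {"tag": "ai", "index": "pred_change"}],
        )

    def resolve_cohort(self) -> Cohort:
        if self.cohort_csv is not None:
            return Cohort.from_csv(self.cohort_csv)
        params = self.cohort_params or CohortParams()
        return generate_cohort(params)

    def resolve_methods(self, cohort: Cohort) -> list[RandomizationMethod]:
        out = []
        for i, m in enumerate(self.methods):
            if "tag" not in m:
                raise ConfigError(f"methods[{i}]: missing 'tag'")
            index = m.get("index")
            if index is None:
                out.append(RandomizationMethod(tag=m["tag"]))
                continue
            if {"minimum", "maximum"} <= m.keys():
                spec = StrataSpec(
                    index_name=index,
                    minimum=float(m["minimum"]),
                    maximum=float(m["maximum"]),
                    interval=float(m.get("interval", 0.5)),
                    shift=float(m.get("shift", 0.0)),
                )
            else:
                spec = StrataSpec.from_cohort(
                    cohort, index,
                    interval=float(m.get("interval", 0.5)),
                    shift=m.get("shift"),
                )
            out.append(RandomizationMethod(tag=m["tag"], strata_spec=spec))
        if not out:
            raise ConfigError("methods: at least one method required")
        return out

    def to_dict(self) -> dict:
        d = {
            "cohort": (asdict(self.cohort_params) if self.cohort_params else
                       {"csv": self.cohort_csv}),
            "methods": self.methods,
            "experiment": {
                "n": self.n,
                "n_reps": self.n_reps,
                "x_grid": list(self.x_grid),
                "seed": self.seed,
                "r": self.r,
                "s_max": self.s_max,
                "phase": asdict(self.phase),
            },
        }
        return d


def _require_mapping(obj: Any, key: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"section {key!r} must be a mapping, got {type(obj).__name__}")
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file; missing sections take defaults.

    ``overrides`` (e.g. from CLI flags) replace experiment-section entries.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping ({path})")

    csec = _require_mapping(raw.get("cohort"), "cohort")
    if "csv" in csec:
        cohort_params, cohort_csv = None, str(csec["csv"])
    else:
        try:
            specs = tuple(
                IndexSpec(
                    name=s["name"],
                    correlation=float(s["correlation"]),
                    mean=float(s.get("mean", 0.0)),
                    sd=float(s.get("sd", 1.0)),
                )
                for s in csec.get("indices", [])
            )
            cohort_params = CohortParams(
                n_participants=int(csec.get("n_participants", 506)),
                gt_mean=float(csec.get("gt_mean", 0.978)),
                gt_sd=float(csec.get("gt_sd", 1.899)),
                gt_grid=float(csec.get("gt_grid", 0.5)),
                pred_correlation=float(csec.get("pred_correlation", 0.601)),
                index_specs=specs,
                seed=int(csec.get("seed", 0)),
                exact_moments=bool(csec.get("exact_moments", True)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"cohort section: {exc}") from exc
        cohort_csv = None

    methods = raw.get("methods") or RunConfig.default().methods
    if not isinstance(methods, list):
        raise ConfigError("methods section must be a list")

    esec = _require_mapping(raw.get("experiment"), "experiment")
    esec = {**esec, **{k: v for k, v in (overrides or {}).items() if v is not None}}
    psec = _require_mapping(esec.get("phase"), "experiment.phase")
    try:
        return RunConfig(
            cohort_params=cohort_params,
            cohort_csv=cohort_csv,
            methods=methods,
            n=int(esec.get("n", 500)),
            n_reps=int(esec.get("n_reps", 10_000)),
            x_grid=tuple(float(v) for v in esec.get("x_grid", tuple(range(10, 51, 2)))),
            seed=int(esec.get("seed", 0)),
            r=float(esec.get("r", 0.3)),
            s_max=int(esec.get("s_max", 3000)),
            phase=PhaseConfig(**psec) if psec else PhaseConfig(),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"experiment section: {exc}") from exc


# --------------------------------------------------------------- serialization
def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(payload: dict, path: str | Path) -> None:
    """Canonical JSON: sorted keys, repr floats — byte-stable across reruns."""
    Path(path).write_text(
        json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def _stage_rng(seed: int, stage: str, method_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGE_ID[stage], method_index))
    )


# --------------------------------------------------------------------- driver
def run_experiment(
    config: RunConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = ("sae",),
) -> dict:
    """Run the requested stages and write results under ``out_dir``.

    Writes per-replicate bias CSVs (``biases_<tag>.csv``, sae stage), curve
    CSVs (samplesize stage), ``summary.json`` and ``log.txt``.  Identical
    config + seed give byte-identical CSV/JSON output; only the log carries
    timing.  Returns the summary dict.
    """
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    cohort = config.resolve_cohort()
    methods = config.resolve_methods(cohort)
    summary: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": list(stages),
        "cohort": {
            "n": cohort.n,
            "gt_mean": float(cohort.gt.mean()),
            "gt_sd": float(cohort.gt.std(ddof=1)),
            "gt_pred_correlation": float(np.corrcoef(cohort.gt, cohort.pred)[0, 1]),
        },
    }

    if "sae" in stages:
        sec: dict = {}
        ref_sae = None
        for j, method in enumerate(methods):
            dist = estimate_bias_distribution(
                cohort, method, n=config.n, n_reps=config.n_reps,
                rng=_stage_rng(config.seed, "sae", j),
            )
            pd.DataFrame({
                "replicate": np.arange(dist.n_reps),
                "bias": dist.biases,
                "bias_cohens_d": dist.biases_d,
            }).to_csv(out / f"biases_{method.tag}.csv", index=False)
            entry = dist.summary()
            if ref_sae is None:
                ref_sae = dist.sae
            else:
                entry["sae_reduction_pct_vs_" + methods[0].tag] = sae_reduction(
                    ref_sae, dist.sae
                )
            sec[method.tag] = entry
        summary["sae"] = sec

    if "samplesize" in stages:
        sec = {}
        grid = default_grid(s_max=config.s_max)
        ref_s = None
        for j, method in enumerate(methods):
            curve = build_sae_curve(
                cohort, method, grid=grid, n_reps=config.n_reps,
                rng=_stage_rng(config.seed, "samplesize", j),
            )
            pd.DataFrame({"s": curve.grid, "sae": curve.sae_at}).to_csv(
                out / f"sae_curve_{method.tag}.csv", index=False
            )
            s_hat = min_sample_size(curve, config.r)
            entry = {"r": config.r, "min_sample_size": s_hat, "n_reps": config.n_reps}
            if ref_s is None:
                ref_s = s_hat
            elif s_hat is not None and ref_s is not None:
                entry["sample_size_reduction_pct_vs_" + methods[0].tag] = (
                    sample_size_reduction(ref_s, s_hat)
                )
            sec[method.tag] = entry
        summary["samplesize"] = sec

    if "trial" in stages:
        sec = {}
        for j, method in enumerate(methods):
            rng = _stage_rng(config.seed, "trial", j)
            pv = pvalue_summary(
                cohort, method, config.n, np.asarray(config.x_grid),
                n_reps=config.n_reps, rng=rng,
            )
            rates = {
                str(x): asdict(detection_rates(
                    cohort, method, config.n, x, n_reps=config.n_reps, rng=rng,
                ))
                for x in config.x_grid
            }
            sec[method.tag] = {
                "pvalue_summary": pv.to_dict(orient="records"),
                "detection_rates": rates,
            }
        summary["trial"] = sec

    if "multiphase" in stages:
        sec = {}
        for j, method in enumerate(methods):
            df = success_rate(
                cohort, method, np.asarray(config.x_grid),
                n_reps=config.n_reps, config=config.phase,
                rng=_stage_rng(config.seed, "multiphase", j),
            )
            sec[method.tag] = df.to_dict(orient="records")
        summary["multiphase"] = sec

    write_json(summary, out / "summary.json")
    elapsed = time.perf_counter() - t0
    (out / "log.txt").write_text(
        f"stratrand {__version__}\n"
        f"python {platform.python_version()} numpy {np.__version__}\n"
        f"seed {config.seed}\nstages {list(stages)}\n"
        f"wall_time_s {elapsed:.2f}\n",
        encoding="utf-8",
    )
    return summary
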