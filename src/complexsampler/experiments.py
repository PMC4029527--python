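"""Experiment drivers: parameter sweeps, repeated runs, run manifests.

Sweeps follow the robustness-analysis protocol: a single sampler execution
per parameter value, each with a seed derived deterministically from the
base seed and the value, evaluated against a reference catalog at the
default overlap threshold.  ``repeat_predict`` reproduces the
mean +/- standard deviation reporting convention used for headline scores.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import config_to_dict
from .evaluation import DEFAULT_ETA, prf
from .network import ComplexCatalog, WeightedNetwork
from .sampler import PredictionResult, SamplerConfig, run

__all__ = [
    "RunManifest",
    "sweep_lambda",
    "sweep_iterations",
    "repeat_predict",
    "RepeatReport",
    "make_manifest",
    "file_digest",
]


def _derived_seed(base_seed: int, *entropy: int) -> int:
    """A stable sub-seed from a base seed plus integer tags, below 2^31."""
    ss = np.random.SeedSequence([int(base_seed), *[int(e) for e in entropy]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    """Everything needed to reproduce one prediction run exactly."""

    config: dict[str, Any]
    input_digests: dict[str, str]
    seed: int
    best_f: float
    g1: float
    g2: float
    g3: float
    best_iteration: int
    wall_clock_s: float
    output_path: str

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
        tmp.replace(path)  # atomic on POSIX


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _evaluate(result: PredictionResult, catalog: ComplexCatalog, eta: float) -> dict[str, float]:
    rep = prf(result.clusters, catalog, eta)
    return {
        "precision": rep.precision,
        "recall": rep.recall,
        "f_measure": rep.f_measure,
        "n_clusters": rep.n_clusters,
        "n_proteins": rep.n_proteins,
        "avg_size": rep.avg_size,
    }


def sweep_lambda(
    net: WeightedNetwork,
    base_config: SamplerConfig,
    values: Sequence[float],
    catalog: ComplexCatalog,
    eta: float = DEFAULT_ETA,
) -> pd.DataFrame:
    """One run per lambda value; returns a table of lambda, precision, recall, F."""
    if not len(values):
        raise ValueError("no lambda values given")
    rows = []
    for value in values:
        config = replace(
            base_config,
            score=replace(base_config.score, lam=float(value)),
            seed=_derived_seed(base_config.seed, int(round(value))),
        )
        result = run(net, config)
        rows.append({"lambda": float(value), **_evaluate(result, catalog, eta)})
    return pd.DataFrame(rows)


def sweep_iterations(
    net: WeightedNetwork,
    base_config: SamplerConfig,
    values: Sequence[int],
    catalog: ComplexCatalog,
    eta: float = DEFAULT_ETA,
) -> pd.DataFrame:
    """One run per iteration count L; returns a table of L, precision, recall, F."""
    if not len(values):
        raise ValueError("no iteration values given")
    rows = []
    for value in values:
        config = replace(
            base_config,
            L=int(value),
            seed=_derived_seed(base_config.seed, int(value)),
        )
        result = run(net, config)
        rows.append({"L": int(value), **_evaluate(result, catalog, eta)})
    return pd.DataFrame(rows)


@dataclass
class RepeatReport:
    """Mean +/- sd summary of repeated runs plus the per-run table."""

    table: pd.DataFrame  # one row per run
    mean: dict[str, float]
    sd: dict[str, float]
    results: list[PredictionResult]

    def format(self, field: str, digits: int = 2) -> str:
        """Render a field as 'mean +/- sd', e.g. '2009.90 +/- 0.30'."""
        return f"{self.mean[field]:.{digits}f} ± {self.sd[field]:.{digits}f}"


def repeat_predict(
    net: WeightedNetwork,
    config: SamplerConfig,
    n_runs: int,
    catalog: ComplexCatalog | None = None,
    eta: float = DEFAULT_ETA,
) -> RepeatReport:
    """Run the sampler ``n_runs`` times with distinct derived seeds.

    With a catalog, reports precision/recall/F as well as the prediction
    summary statistics (#cluster, #protein, average size); without one,
    only the summary statistics.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    results = []
    for i in range(n_runs):
        cfg = replace(config, seed=_derived_seed(config.seed, i))
        result = run(net, cfg)
        results.append(result)
        row: dict[str, float] = {
            "seed": cfg.seed,
            "n_clusters": len(result.clusters),
            "n_proteins": result.n_proteins,
            "avg_size": result.avg_size,
            "best_f": result.best_f,
        }
        if catalog is not None:
            rep = prf(result.clusters, catalog, eta)
            row.update(
                precision=rep.precision,
                recall=rep.recall,
                f_measure=rep.f_measure,
                npc=rep.npc,
                nkc=rep.nkc,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    numeric = table.drop(columns=["seed"])
    mean = numeric.mean().to_dict()
    sd = (numeric.std(ddof=1) if n_runs > 1 else numeric.mul(0.0).iloc[0]).to_dict()
    if n_runs == 1:
        sd = {k: 0.0 for k in mean}
    return RepeatReport(table=table, mean=mean, sd=sd, results=results)


def make_manifest(
    config: SamplerConfig,
    result: PredictionResult,
    inputs: dict[str, str | Path],
    output_path: str | Path,
    wall_clock_s: float,
) -> RunManifest:
    return RunManifest(
        config=config_to_dict(config),
        input_digests={name: file_digest(p) for name, p in inputs.items()},
        seed=config.seed,
        best_f=result.best_f,
        g1=result.g1,
        g2=result.g2,
        g3=result.g3,
        best_iteration=result.best_iteration,
        wall_clock_s=wall_clock_s,
        output_path=str(output_path),
    )
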