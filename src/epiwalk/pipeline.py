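"""End-to-end analysis of one or more genotype-fitness maps.

Per dataset, :func:`run_analysis` fits the scale, decomposes epistasis, builds
the truncation series, computes trajectory probabilities, the variance
partition (phi) and trajectory divergence (theta) with resampling-based
confidence intervals and noise-only p-values, the ancestral-reference
prediction-overlap grid, and edge marginals for external renderers.  Outputs
are flat CSV files plus a single JSON manifest; every file carries the config
hash so identical configs yield identical, diffable outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import EpistasisRemover
from .map_io import GenotypeFitnessMap, read_map_json
from .resampling import (
    confidence_interval,
    estimate_mode,
    experimental_distribution,
    null_distribution,
    p_value,
)
from .trajectories import (
    EvolutionParams,
    NoAccessibleTrajectoriesError,
    edge_marginals,
    theta,
    trajectory_probabilities,
)

__all__ = ["RunConfig", "run_analysis", "sensitivity_sweep", "overlap_grid"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    inputs: list[str]
    out_dir: str
    basis: str = "global"
    orders: list[int] | None = None  # default: 1..L per map
    popsize: float = 1e6
    lethal_threshold: float = 0.0
    n_pseudoreplicates: int = 10_000
    seed: int = 0
    theta_variant: str = "tv"
    std_floor: str | float | None = "auto"
    confidence_level: float = 0.95

    def params(self) -> EvolutionParams:
        return EvolutionParams(N=self.popsize, lethal_threshold=self.lethal_threshold)

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, written: list[Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)
    written.append(path)


def _write_json(doc: dict, path: Path, cfg_hash: str, written: list[Path]) -> None:
    doc = {"config_hash": cfg_hash, **doc}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=_jsonable)
        fh.write("\n")
    written.append(path)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def overlap_grid(
    gmap: GenotypeFitnessMap,
    params: EvolutionParams,
    max_order: int | None = None,
    max_length: int | None = None,
) -> pd.DataFrame:
    """Prediction-overlap percentages on an orders x lengths grid.

    Rows are truncation orders of the ancestral-reference (local) model,
    columns trajectory lengths; entries the percent overlap between k-step
    trajectory distributions of the truncated and original maps.  An order
    whose truncated map leaves no accessible k-step trajectory scores 0.
    """
    L = gmap.n_sites
    max_order = max_order or L
    max_length = max_length or L
    rows = []
    rem = EpistasisRemover(basis="local").fit(gmap)
    for order in range(1, max_order + 1):
        tmap = rem.truncated_map(order)
        for length in range(1, max_length + 1):
            d_true = trajectory_probabilities(gmap, params, length)
            try:
                d_trunc = trajectory_probabilities(tmap, params, length)
                ov = 100.0 * (1.0 - theta(d_true, d_trunc))
            except NoAccessibleTrajectoriesError:
                ov = 0.0
            rows.append({"max_order": order, "length": length, "overlap_percent": ov})
    return pd.DataFrame(rows)


def _analyze_one(
    gmap: GenotypeFitnessMap,
    config: RunConfig,
    out: Path,
    cfg_hash: str,
    written: list[Path],
    manifest: dict,
) -> None:
    params = config.params()
    L = gmap.n_sites
    orders = config.orders or list(range(1, L + 1))
    tag = gmap.name or "map"
    stage_times: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage):
        nonlocal t0
        stage_times[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    # scale + decomposition
    rem = EpistasisRemover(basis=config.basis).fit(gmap)
    _write_json(
        {**rem.scale_.params_.to_dict(), "rss": rem.scale_.rss_},
        out / f"{tag}_scale.json",
        cfg_hash,
        written,
    )
    coeff = pd.DataFrame(
        {
            "basis": rem.coefficients_.basis,
            "subset": ["-".join(map(str, s)) for s in rem.coefficients_.subsets],
            "order": rem.coefficients_.orders,
            "beta": rem.coefficients_.beta,
        }
    )
    _write_csv(coeff, out / f"{tag}_coefficients.csv", cfg_hash, written)
    tick("decomposition")

    # resampling per order >= 2: phi/theta CIs and p-values
    phi_point = rem.phi_profile()
    phi_rows, theta_rows = [], []
    full = trajectory_probabilities(rem.truncated_map(L), params)
    for order in orders:
        row = {"dataset": tag, "order": order, "phi": phi_point[order - 1]}
        trow = None
        if order >= 2:
            d_lo = trajectory_probabilities(rem.truncated_map(order - 1), params)
            d_hi = trajectory_probabilities(rem.truncated_map(order), params)
            th = theta(d_lo, d_hi, variant=config.theta_variant)
            exp = experimental_distribution(
                gmap, order, config.n_pseudoreplicates, config.seed,
                params, config.std_floor,
            )
            null = null_distribution(
                gmap, order, config.n_pseudoreplicates, config.seed + 1,
                params, config.std_floor,
            )
            lo, hi = confidence_interval(exp.phi, config.confidence_level)
            row.update({"ci_low": lo, "ci_high": hi})
            tlo, thi = confidence_interval(exp.theta, config.confidence_level)
            trow = {
                "dataset": tag,
                "order_pair": f"{order - 1}->{order}",
                "theta": th,
                "theta_mode": estimate_mode(exp.theta),
                "ci_low": tlo,
                "ci_high": thi,
                "p_value": p_value(exp, null),
                "n_samples": exp.n_samples,
                "n_failed": exp.n_failed + null.n_failed,
                "seed": config.seed,
            }
        else:
            row.update({"ci_low": np.nan, "ci_high": np.nan})
        phi_rows.append(row)
        if trow:
            theta_rows.append(trow)
    _write_csv(pd.DataFrame(phi_rows), out / f"{tag}_phi.csv", cfg_hash, written)
    if theta_rows:
        _write_csv(pd.DataFrame(theta_rows), out / f"{tag}_theta.csv", cfg_hash, written)
    tick("resampling")

    # full-length trajectory table per truncation order
    traj_frames = []
    for order in orders:
        d_trunc = trajectory_probabilities(rem.truncated_map(order), params)
        df = full.to_frame().rename(columns={"probability": "probability_original"})
        df["max_order"] = order
        df["probability_truncated"] = d_trunc.probabilities
        df["abs_difference"] = np.abs(
            df["probability_original"] - df["probability_truncated"]
        )
        traj_frames.append(df)
    _write_csv(
        pd.concat(traj_frames, ignore_index=True),
        out / f"{tag}_trajectories.csv",
        cfg_hash,
        written,
    )
    tick("trajectories")

    # prediction-overlap grid (local basis, ancestral reference)
    grid = overlap_grid(gmap, params)
    grid.insert(0, "dataset", tag)
    _write_csv(grid, out / f"{tag}_overlap_grid.csv", cfg_hash, written)
    tick("overlap_grid")

    # edge marginals of the original map, CSV + DOT
    edges, visits = edge_marginals(full, gmap)
    _write_csv(edges, out / f"{tag}_edge_marginals.csv", cfg_hash, written)
    dot_lines = [f'digraph "{tag}" {{']
    for _, e in edges.iterrows():
        dot_lines.append(
            f'  "{e["from"]}" -> "{e["to"]}" [penwidth={max(0.1, 6 * e["probability"]):.3f}];'
        )
    dot_lines.append("}")
    (out / f"{tag}_edges.dot").write_text("\n".join(dot_lines) + "\n")
    written.append(out / f"{tag}_edges.dot")
    tick("edge_marginals")

    manifest["datasets"][tag] = {
        "n_sites": L,
        "stage_seconds": stage_times,
        "n_clipped_backtransforms": rem.n_clipped_,
    }


def run_analysis(config: RunConfig, maps: dict[str, GenotypeFitnessMap] | None = None) -> dict:
    """Run the full pipeline; returns the manifest.

    ``maps`` may be passed directly (e.g. synthetic maps); otherwise
    ``config.inputs`` are read as map JSON files.  Any stage failure removes
    the partial outputs and re-raises with the dataset and stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    if maps is None:
        maps = {}
        for p in config.inputs:
            if not Path(p).exists():
                raise FileNotFoundError(f"input map {p} does not exist")
            m = read_map_json(p)
            maps[m.name] = m
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "epiwalk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "datasets": {},
        "warnings": [],
    }
    written: list[Path] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            for name, gmap in maps.items():
                try:
                    _analyze_one(gmap, config, out, cfg_hash, written, manifest)
                except Exception as exc:
                    raise RuntimeError(f"dataset {name!r} failed: {exc}") from exc
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
    manifest["warnings"] = sorted({str(w.message) for w in caught})
    _write_json(manifest, out / "manifest.json", cfg_hash, written)
    return manifest


def sensitivity_sweep(
    config: RunConfig,
    N_values: list[float],
    maps: dict[str, GenotypeFitnessMap] | None = None,
) -> pd.DataFrame:
    """Recompute theta and overlap across population sizes.

    Returns a long frame (dataset, N, statistic, value) plus, per statistic,
    the max absolute deviation across the sweep (in the ``max_abs_deviation``
    attribute-style companion frame returned by ``.attrs``).
    """
    if not N_values:
        raise ValueError("N_values must be non-empty")
    if maps is None:
        maps = {Path(p).stem: read_map_json(p) for p in config.inputs}
    rows = []
    for name, gmap in maps.items():
        L = gmap.n_sites
        rem = EpistasisRemover(basis=config.basis).fit(gmap)
        tmaps = {k: rem.truncated_map(k) for k in range(1, L + 1)}
        for N in N_values:
            params = EvolutionParams(N=N, lethal_threshold=config.lethal_threshold)
            dists = {k: trajectory_probabilities(m, params) for k, m in tmaps.items()}
            for k in range(2, L + 1):
                rows.append(
                    {
                        "dataset": name,
                        "N": N,
                        "statistic": f"theta_{k - 1}->{k}",
                        "value": theta(dists[k - 1], dists[k], config.theta_variant),
                    }
                )
            grid = overlap_grid(gmap, params)
            for _, g in grid.iterrows():
                rows.append(
                    {
                        "dataset": name,
                        "N": N,
                        "statistic": f"overlap_o{int(g['max_order'])}_k{int(g['length'])}",
                        "value": g["overlap_percent"],
                    }
                )
    df = pd.DataFrame(rows)
    dev = (
        df.groupby(["dataset", "statistic"])["value"]
        .agg(lambda v: np.max(np.abs(v - v.iloc[0])))
        .rename("max_abs_deviation")
        .reset_index()
    )
    df.attrs["max_abs_deviation"] = dev
    return df
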