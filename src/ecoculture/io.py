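"""File output with provenance: CSV results, JSON metadata and a checksummed
manifest.

Every run directory contains the result files, a ``metadata.json`` holding
the full configuration (round-trippable through
:func:`ecoculture.config.config_from_dict`), the package version, seed and
warning counts, and a ``manifest.json`` listing each written file with its
SHA-256 checksum.  Timestamps live only in the metadata file so result files
are byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .ensemble import EnsembleSummary, SweepGrid
from .model import Trajectory
from .phase_sync import PhaseSyncResult

__all__ = ["write_outputs", "read_trajectory_csv"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_trajectory(traj: Trajectory, out_dir: Path) -> list[Path]:
    path = out_dir / "trajectory.csv"
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")
    return [path]


def _write_ensemble(summary: EnsembleSummary, out_dir: Path) -> list[Path]:
    path = out_dir / "ensemble.csv"
    df = pd.DataFrame(
        {
            "member": np.arange(summary.n_members),
            "seed": summary.member_seeds,
            "mean_rho": summary.per_member_means["rho"],
            "mean_c": summary.per_member_means["c"],
            "mean_K": summary.per_member_means["K"],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    pooled = out_dir / "ensemble_pooled.json"
    pooled.write_text(
        json.dumps(
            {
                "n_members": summary.n_members,
                "burn_in": summary.burn_in,
                "E_rho": summary.E_rho,
                "E_c": summary.E_c,
                "E_K": summary.E_K,
            },
            indent=2,
        )
    )
    return [path, pooled]


def _write_sweep(grid: SweepGrid, out_dir: Path) -> list[Path]:
    path = out_dir / "sweep.csv"
    grid.to_frame().to_csv(path, index=False, float_format="%.17g")
    return [path]


def _sync_result_dict(res: PhaseSyncResult) -> dict:
    return {
        "variable": res.variable_name,
        "n_bins": res.n_bins,
        "rel_std_pct": res.rel_std_pct,
        "ks_statistic": res.ks_statistic,
        "ks_pvalue": res.ks_pvalue,
        "rejection_confidence_pct": res.rejection_confidence_pct,
        "edge_fraction_discarded": res.edge_fraction_discarded,
        "decimation_stride": res.decimation_stride,
    }


def _write_sync(results: dict, out_dir: Path) -> list[Path]:
    report = out_dir / "report.json"
    report.write_text(
        json.dumps(
            {name: _sync_result_dict(r) for name, r in results.items()},
            indent=2,
        )
    )
    hist_path = out_dir / "histograms.csv"
    frames = []
    for name, r in results.items():
        frames.append(
            pd.DataFrame(
                {
                    "variable": name,
                    "bin_left": r.histogram.edges[:-1],
                    "bin_right": r.histogram.edges[1:],
                    "probability": r.histogram.probabilities,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        hist_path, index=False, float_format="%.17g"
    )
    return [report, hist_path]


def write_outputs(results, config: RunConfig, out_dir: str | Path) -> dict:
    """Write a result object plus metadata and a checksummed manifest.

    ``results`` may be a :class:`Trajectory`, an :class:`EnsembleSummary`,
    a :class:`SweepGrid` or a ``{name: PhaseSyncResult}`` mapping.  Returns
    the manifest as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    extra_meta: dict = {}
    if isinstance(results, Trajectory):
        files = _write_trajectory(results, out_dir)
        extra_meta = {
            "warnings": results.warnings,
            "exhausted_steps": results.exhausted_steps,
        }
    elif isinstance(results, EnsembleSummary):
        files = _write_ensemble(results, out_dir)
    elif isinstance(results, SweepGrid):
        files = _write_sweep(results, out_dir)
    elif isinstance(results, dict) and all(
        isinstance(v, PhaseSyncResult) for v in results.values()
    ):
        files = _write_sync(results, out_dir)
    else:
        raise TypeError(f"cannot write results of type {type(results)!r}")

    from . import __version__

    metadata = {
        "config": config.to_dict(),
        "seed": config.model.seed,
        "package": "ecoculture",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **extra_meta,
    }
    meta_path = out_dir / "metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2))

    manifest = {
        "files": [
            {"name": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in files + [meta_path]
        ]
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Load a trajectory written by :func:`write_outputs` (params not
    recoverable from the CSV alone; ``params`` is left None)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"t", "rho", "c", "K", "K0", "per_capita", "xi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return Trajectory(
        t=df["t"].to_numpy(),
        rho=df["rho"].to_numpy(),
        c=df["c"].to_numpy(),
        K=df["K"].to_numpy(),
        K0_t=df["K0"].to_numpy(),
        per_capita=df["per_capita"].to_numpy(),
        xi=df["xi"].to_numpy()[1:],
        warnings=0,
    )
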