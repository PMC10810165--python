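"""End-to-end orchestration: stacks in, tidy records and group stats out.

A run delineates islets in every input stack, optionally separates touching
islets, applies the configured exclusion list, detects stain per marker,
measures per-islet morphometry, and finally compares the morphometric
readouts across condition labels.  Everything a run reports is recomputable
from (inputs, resolved config, seed); reports embed the resolved config and
content digests of file inputs for provenance.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .imageio import ChannelMap, PipelineConfig, VoxelGrid, read_stack
from .morphometry import measure_islet
from .segmentation import delineate_islets, detect_stain, split_touching
from .stats import (
    CorrelationResult,
    GroupComparison,
    compare_groups,
    one_way_anova,
    pearson_correlation,
)

__all__ = ["StackInput", "RunReport", "PipelineError", "run_pipeline", "make_figures"]

#: metric columns compared across conditions, per marker where defined
_METRICS = ["volume_fraction_pct", "mean_intensity_au", "node_count", "hole_fraction_pct"]


class PipelineError(RuntimeError):
    """Raised when a run produces no successfully measured islet."""


@dataclass
class StackInput:
    """One input acquisition: an in-memory grid or a TIFF path plus its map."""

    grid: VoxelGrid | None = None
    path: str | Path | None = None
    channel_map: ChannelMap | None = None
    condition: str = ""
    name: str = ""

    def load(self, config: PipelineConfig) -> tuple[VoxelGrid, str]:
        if self.grid is not None:
            digest = hashlib.sha256(self.grid.data.tobytes()).hexdigest()
            return self.grid, digest
        if self.path is None or self.channel_map is None:
            raise ValueError("a StackInput needs either a grid or a path with a channel map")
        digest = hashlib.sha256(Path(self.path).read_bytes()).hexdigest()
        grid = read_stack(self.path, self.channel_map, voxel_size=config.voxel_size_override)
        return grid, digest


@dataclass
class RunReport:
    """Everything one pipeline run computed, plus its provenance."""

    config: dict
    records: pd.DataFrame
    comparisons: list[GroupComparison] = field(default_factory=list)
    comparison_labels: list[str] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    anova_volume: GroupComparison | None = None
    failures: list[dict] = field(default_factory=list)
    input_digests: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def stats_dict(self) -> dict:
        def _cmp(c: GroupComparison) -> dict:
            return {
                "groups": list(c.group_names),
                "n": list(c.n),
                "means": list(c.means),
                "sds": list(c.sds),
                "transform": c.transform,
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "significant": c.significant,
            }

        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "input_digests": self.input_digests,
            "comparisons": {
                lbl: _cmp(c) for lbl, c in zip(self.comparison_labels, self.comparisons)
            },
            "anova_islet_volume": _cmp(self.anova_volume) if self.anova_volume else None,
            "correlations": [
                {"variables": list(c.variables), "n": c.n, "r": c.r, "p_value": c.p_value}
                for c in self.correlations
            ],
            "failures": self.failures,
        }

    def write(self, out_dir: str | Path) -> Path:
        """Write records.csv, stats.json and the resolved config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        with open(out / "stats.json", "w") as fh:
            json.dump(self.stats_dict(), fh, indent=2, sort_keys=True)
        import yaml

        with open(out / "config.yml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)
        return out


def _excluded(config: PipelineConfig, stack_name: str, islet_id: int) -> bool:
    for entry in config.exclude_islets:
        if isinstance(entry, int) and entry == islet_id:
            return True
        if isinstance(entry, str) and entry == f"{stack_name}:{islet_id}":
            return True
    return False


def run_pipeline(
    config: PipelineConfig,
    inputs: Sequence[StackInput],
    compute_stats: bool = True,
) -> RunReport:
    """Run the full analysis over a set of input stacks.

    Per-stack and per-islet failures are recorded and do not abort the
    remaining islets; a run with zero successfully measured islets raises
    :class:`PipelineError`.
    """
    if not inputs:
        raise ValueError("run_pipeline needs at least one input stack")
    rows: list[dict] = []
    failures: list[dict] = []
    digests: dict[str, str] = {}
    global_id = 0
    for k, item in enumerate(inputs):
        name = item.name or f"stack{k}"
        try:
            grid, digest = item.load(config)
            digests[name] = digest
            labeling = delineate_islets(grid, config)
            if config.split_touching:
                labeling = split_touching(labeling, grid, config)
            markers = [m for m in grid.channel_map.markers if m != "nuclei"]
            stains = {m: detect_stain(grid, m, config.marker_params(m)) for m in markers}
        except Exception as exc:  # noqa: BLE001 — isolate per-stack failures
            failures.append({"stack": name, "stage": "segmentation", "error": str(exc)})
            continue
        for islet_id in labeling.islet_ids:
            if _excluded(config, name, islet_id):
                continue
            try:
                recs = measure_islet(
                    grid,
                    labeling,
                    islet_id,
                    stains,
                    condition=item.condition,
                    min_node_volume_um3=config.min_node_volume_um3,
                    min_hole_volume_um3=config.min_hole_volume_um3,
                    boundary_margin_um=config.boundary_margin_um,
                )
            except Exception as exc:  # noqa: BLE001
                failures.append(
                    {"stack": name, "islet": islet_id, "stage": "morphometry", "error": str(exc)}
                )
                continue
            global_id += 1
            for r in recs:
                row = r.as_row()
                row["islet_id"] = global_id
                row["stack"] = name
                rows.append(row)
    if not rows:
        raise PipelineError(f"no islet was successfully measured ({len(failures)} failures)")
    records = pd.DataFrame(rows)
    report = RunReport(
        config=config.to_dict(),
        records=records,
        failures=failures,
        input_digests=digests,
        seed=config.seed,
    )
    if compute_stats:
        _add_stats(report, config)
    return report


def _metric_series(df: pd.DataFrame, marker: str, metric: str) -> pd.Series | None:
    sub = df[df["marker"] == marker]
    if sub.empty or metric not in sub:
        return None
    vals = sub.set_index("condition")[metric].dropna()
    return vals if len(vals) else None


def _add_stats(report: RunReport, config: PipelineConfig) -> None:
    df = report.records
    conditions = [c for c in df["condition"].unique() if c]
    if len(conditions) < 2:
        return
    for marker in sorted(df["marker"].unique()):
        for metric in _METRICS:
            vals = _metric_series(df, marker, metric)
            if vals is None:
                continue
            for ca, cb in itertools.combinations(conditions, 2):
                a = vals.loc[vals.index == ca].to_numpy(dtype=float)
                b = vals.loc[vals.index == cb].to_numpy(dtype=float)
                if len(a) < 2 or len(b) < 2:
                    continue
                try:
                    cmp_res = compare_groups(
                        a, b, names=(ca, cb), alpha=config.alpha, pooled=config.pooled_variance
                    )
                except ValueError as exc:
                    report.failures.append(
                        {"stage": "stats", "comparison": f"{marker}.{metric}", "error": str(exc)}
                    )
                    continue
                report.comparisons.append(cmp_res)
                report.comparison_labels.append(f"{marker}.{metric}.{ca}_vs_{cb}")
    # islet volume is reported once per islet; ANOVA across all conditions
    vol = df.drop_duplicates("islet_id").set_index("condition")["islet_volume_um3"]
    groups = [vol.loc[vol.index == c].to_numpy(dtype=float) for c in conditions]
    if all(len(g) >= 2 for g in groups):
        try:
            report.anova_volume = one_way_anova(groups, names=tuple(conditions), alpha=config.alpha)
        except ValueError as exc:
            report.failures.append({"stage": "stats", "comparison": "islet_volume.anova", "error": str(exc)})
    # associations with islet size
    lam = df[df["marker"] == "laminin"].dropna(subset=["node_count"])
    if len(lam) >= 3 and lam["node_count"].nunique() > 1 and lam["islet_volume_um3"].nunique() > 1:
        report.correlations.append(
            pearson_correlation(
                lam["node_count"], lam["islet_volume_um3"], ("node_count", "islet_volume_um3")
            )
        )
    ecad = df[df["marker"] == "ecadherin"].dropna(subset=["hole_fraction_pct"])
    if (
        len(ecad) >= 3
        and ecad["hole_fraction_pct"].nunique() > 1
        and ecad["islet_volume_um3"].nunique() > 1
    ):
        hole_um3 = ecad["hole_fraction_pct"] / 100.0 * ecad["islet_volume_um3"]
        report.correlations.append(
            pearson_correlation(hole_um3, ecad["islet_volume_um3"], ("hole_volume_um3", "islet_volume_um3"))
        )


def make_figures(
    report: RunReport,
    out_dir: str | Path,
    grids: Sequence[tuple[str, VoxelGrid]] | None = None,
) -> list[Path]:
    """Dot plots per marker metric (one dot per islet, group-mean bar),
    an islet-volume plot, and optional mid-islet cross-section panels with
    per-channel display ranges held constant across conditions.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = report.records
    if df.empty:
        raise ValueError("cannot plot an empty report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    conditions = list(dict.fromkeys(df["condition"]))

    def dotplot(values_by_cond: dict[str, np.ndarray], title: str, ylabel: str, fname: str):
        fig, ax = plt.subplots(figsize=(4, 3.2))
        for i, cond in enumerate(conditions):
            v = values_by_cond.get(cond)
            if v is None or len(v) == 0:
                continue
            x = np.linspace(i - 0.12, i + 0.12, len(v))
            ax.plot(x, v, "o", ms=4, alpha=0.8)
            ax.hlines(np.mean(v), i - 0.25, i + 0.25, color="k", lw=1.5)
        ax.set_xticks(range(len(conditions)), conditions)
        ax.set_title(title)
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        p = out / fname
        fig.savefig(p, dpi=120, metadata={"Software": None})
        plt.close(fig)
        written.append(p)

    for marker in sorted(df["marker"].unique()):
        for metric, ylabel in (
            ("volume_fraction_pct", "% of islet volume"),
            ("mean_intensity_au", "mean intensity (AU)"),
            ("node_count", "nodes per islet"),
            ("hole_fraction_pct", "holes, % of islet volume"),
        ):
            sub = df[df["marker"] == marker].dropna(subset=[metric])
            if sub.empty or sub[metric].nunique() <= 0:
                continue
            if metric in ("node_count",) and marker != "laminin":
                continue
            if metric in ("hole_fraction_pct",) and marker != "ecadherin":
                continue
            dotplot(
                {c: sub[sub["condition"] == c][metric].to_numpy(float) for c in conditions},
                f"{marker}: {metric.replace('_', ' ')}",
                ylabel,
                f"{marker}_{metric}.png",
            )
    voldf = df.drop_duplicates("islet_id")
    dotplot(
        {c: voldf[voldf["condition"] == c]["islet_volume_um3"].to_numpy(float) for c in conditions},
        "islet volume",
        "volume (µm³)",
        "islet_volume.png",
    )

    if grids:
        # consistent per-marker display ranges across all conditions
        vmax: dict[str, float] = {}
        for _, g in grids:
            for m in g.channel_map.markers:
                vmax[m] = max(vmax.get(m, 0.0), float(g.channel(m).max()))
        for cond, g in grids:
            markers = g.channel_map.markers
            fig, axes = plt.subplots(1, len(markers), figsize=(3 * len(markers), 3))
            mid = g.shape[0] // 2
            for ax, m in zip(np.atleast_1d(axes), markers):
                ax.imshow(g.channel(m)[mid], cmap="magma", vmin=0, vmax=vmax[m] or 1)
                ax.set_title(f"{cond}: {m}", fontsize=9)
                ax.axis("off")
            fig.tight_layout()
            p = out / f"sections_{cond}.png"
            fig.savefig(p, dpi=120, metadata={"Software": None})
            plt.close(fig)
            written.append(p)
    return written
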