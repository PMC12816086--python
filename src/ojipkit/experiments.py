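"""Experiment pipelines: V_J heat-map grids and V_J(') time courses.

Two analysis patterns recur when evaluating the V_J redox proxy: a matrix of
pulse intensities crossed with culture densities (where the proxy degrades at
low intensity and high density, leaving missing cells with recorded reasons),
and repeated measurements at fixed intervals after a treatment, summarized as
replicate mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureConfig, TransientFeatures, extract_features
from .transients import OJIPTransient

__all__ = ["GridResult", "TimecourseResult", "vj_grid", "vj_timecourse",
           "render_grid_outputs", "render_timecourse_outputs"]


@dataclass
class GridResult:
    """V_J over an SP-intensity x culture-density matrix with missing cells.

    ``vj[i, j]`` corresponds to ``sp_axis[i]`` and ``density_axis[j]``; missing
    entries are NaN and carry a non-empty entry in the parallel ``reasons``
    matrix.
    """

    sp_axis: list[float]
    density_axis: list[float]
    vj: np.ndarray
    reasons: np.ndarray  # object array of "" or the exclusion reason string
    features: list[TransientFeatures] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = (len(self.sp_axis), len(self.density_axis))
        if self.vj.shape != expected or self.reasons.shape != expected:
            raise ValueError("matrix dimensions must match the axes")
        missing = np.isnan(self.vj)
        has_reason = self.reasons != ""
        if not np.array_equal(missing, has_reason):
            raise ValueError("every missing cell needs a reason and vice versa")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.vj).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vj,
            index=pd.Index(self.sp_axis, name="sp_intensity"),
            columns=pd.Index(self.density_axis, name="chl_conc"),
        )


@dataclass
class TimecourseResult:
    """Replicate mean ± SD of V_J(') along a treatment time course.

    ``sd_vj`` uses the sample (n-1) convention and is NaN where fewer than two
    non-excluded replicates remain; ``mean_vj`` is NaN where none remain.
    """

    times_s: np.ndarray
    mean_vj: np.ndarray
    sd_vj: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        lens = {len(self.times_s), len(self.mean_vj), len(self.sd_vj), len(self.n)}
        if len(lens) != 1:
            raise ValueError("timecourse arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times_s, "mean_vj": self.mean_vj,
             "sd_vj": self.sd_vj, "n": self.n}
        )


def vj_grid(
    transients: Iterable[OJIPTransient], config: FeatureConfig | None = None
) -> GridResult:
    """Extract V_J per grid cell; QC-excluded cells become missing with reasons.

    Grid coordinates are taken from each trace's metadata
    (``meta.sp_intensity``, ``sample.chl_conc``); duplicates are an error.
    """
    config = config if config is not None else FeatureConfig()
    cells: dict[tuple[float, float], TransientFeatures] = {}
    for tr in transients:
        key = (float(tr.meta.sp_intensity), float(tr.sample.chl_conc))
        if key in cells:
            raise ValueError(f"duplicate grid coordinates {key}")
        cells[key] = extract_features(tr, config)
    sp_axis = sorted({k[0] for k in cells})
    density_axis = sorted({k[1] for k in cells})
    for sp in sp_axis:
        for c in density_axis:
            if (sp, c) not in cells:
                raise ValueError(f"missing grid cell for coordinates ({sp}, {c})")
    vj = np.full((len(sp_axis), len(density_axis)), np.nan)
    reasons = np.full(vj.shape, "", dtype=object)
    feats = []
    for i, sp in enumerate(sp_axis):
        for j, c in enumerate(density_axis):
            f = cells[(sp, c)]
            feats.append(f)
            if f.qc.excluded or f.VJ is None:
                reasons[i, j] = ";".join(f.qc.reasons) or "no_inflection_in_window"
            else:
                vj[i, j] = f.VJ
    return GridResult(sp_axis, density_axis, vj, reasons, feats)


def vj_timecourse(
    groups: Sequence[tuple[float, Sequence[OJIPTransient]]],
    config: FeatureConfig | None = None,
) -> TimecourseResult:
    """Per-timepoint mean and sample SD of V_J(') over non-excluded replicates.

    A timepoint whose replicates are all excluded is reported as missing
    (NaN mean, n = 0), not as an error. Replicate groups must carry distinct
    timepoints.
    """
    config = config if config is not None else FeatureConfig()
    times = [float(t) for t, _ in groups]
    if len(set(times)) != len(times):
        raise ValueError("replicate groups carry duplicate timepoints")
    means, sds, ns = [], [], []
    for _, replicates in groups:
        vals = []
        for tr in replicates:
            f = extract_features(tr, config)
            if not f.qc.excluded and f.VJ is not None:
                vals.append(f.VJ)
        ns.append(len(vals))
        means.append(float(np.mean(vals)) if vals else np.nan)
        sds.append(float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan)
    return TimecourseResult(
        times_s=np.asarray(times), mean_vj=np.asarray(means),
        sd_vj=np.asarray(sds), n=np.asarray(ns, dtype=int),
    )


def render_grid_outputs(result: GridResult, csv_path: str | Path,
                        fig_path: str | Path | None = None) -> list[Path]:
    """Write the grid as a CSV matrix and optionally a heat map.

    Missing cells stay empty in the CSV and are drawn in a distinct color in
    the figure; the density axis is log-scaled, matching how such grids are
    usually displayed.
    """
    paths = [Path(csv_path)]
    result.to_frame().to_csv(paths[0], float_format="%.10g")
    if fig_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        masked = np.ma.masked_invalid(result.vj)
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("lightgrey")
        dens = np.asarray(result.density_axis, dtype=float)
        sp = np.asarray(result.sp_axis, dtype=float)
        mesh = ax.pcolormesh(dens, sp, masked, cmap=cmap, shading="nearest",
                             vmin=0.0, vmax=1.0)
        ax.set_xscale("log")
        ax.set_xlabel("culture density (mg Chl a L$^{-1}$)")
        ax.set_ylabel("SP intensity (µmol photons m$^{-2}$ s$^{-1}$)")
        fig.colorbar(mesh, ax=ax, label="V$_J$")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
        paths.append(Path(fig_path))
    return paths


def render_timecourse_outputs(result: TimecourseResult, csv_path: str | Path,
                              fig_path: str | Path | None = None) -> list[Path]:
    """Write the time course as CSV and optionally a mean ± SD line plot."""
    paths = [Path(csv_path)]
    result.to_frame().to_csv(paths[0], index=False, float_format="%.10g")
    if fig_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.errorbar(result.times_s, result.mean_vj, yerr=result.sd_vj,
                    marker="o", capsize=3)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("V$_J$ / V$_J'$")
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
        paths.append(Path(fig_path))
    return paths
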