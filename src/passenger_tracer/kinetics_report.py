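"""Per-timepoint passenger kinetics and the exponential decay fit.

Aggregates the classifier's species fractions, the rescue summary and the
QC'd cell profiles into one row per co-culture condition, then fits the
decay law

    p(t) = p0 * 2**(-t / h)

to the passenger read fraction (human-classified reads plus reporter hits,
as a share of all reads) across the post-exposure timepoints. The control
condition has no co-culture time and is excluded from the fit; it is shown
as baseline. The fitted half-life quantifies the qualitative observation
that internalized apoptotic-cell RNA peaks early and dissipates within
hours; it is a construct of this pipeline, not a literature estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .unaligned_rescue import RescueSummary

REPORT_INPUTS = ("species_fractions.tsv", "rescue_summary.tsv")


@dataclass
class DecayFit:
    """Least-squares fit of p(t) = p0 * 2**(-t/h)."""

    p0_hat: float
    half_life_hat: float  # hours; NaN when degenerate
    fit_sse: float
    n_points: int
    degenerate: bool = False  # all-zero fractions: nothing to fit


def build_kinetics(
    species_fractions: pd.DataFrame,
    rescue_summaries: Sequence[RescueSummary],
    profiles_by_condition: Mapping[str, pd.DataFrame],
    condition_times: Mapping[str, float | None],
) -> pd.DataFrame:
    """Join the three per-condition sources into the kinetics table.

    All inputs must cover the identical set of condition labels; a mismatch
    aborts. Rows are ordered control (no co-culture time) first, then by
    increasing time. ``fraction_passenger_free`` is computed over
    QC-passing cells only.
    """
    frac_conditions = set(species_fractions["condition"])
    rescue_map = {s.condition: s for s in rescue_summaries}
    sources = {
        "species fractions": frac_conditions,
        "rescue summary": set(rescue_map),
        "cell profiles": set(profiles_by_condition),
        "condition times": set(condition_times),
    }
    expected = sources["condition times"]
    for name, labels in sources.items():
        if labels != expected:
            raise ValueError(
                f"condition labels of {name} ({sorted(labels)}) do not match "
                f"expected {sorted(expected)}"
            )
    rows = []
    for cond in sorted(expected):
        frow = species_fractions.loc[species_fractions["condition"] == cond].iloc[0]
        rs = rescue_map[cond]
        profiles = profiles_by_condition[cond]
        passed = profiles[profiles["passed_qc"]]
        n_passed = len(passed)
        if n_passed and "passenger_free" in passed.columns:
            frac_free = float(passed["passenger_free"].mean())
        else:
            frac_free = math.nan
        total = int(frow["total_reads"])
        passenger_fraction = float(frow["fraction_human"]) + (
            rs.n_reporter_raw_hits / total if total else 0.0
        )
        t = condition_times[cond]
        rows.append(
            {
                "condition": cond,
                "t_hours": math.nan if t is None else float(t),
                "total_reads": total,
                "fraction_human_aligned": float(frow["fraction_human"]),
                "fraction_unaligned": float(frow["fraction_unaligned"]),
                "passenger_read_fraction": passenger_fraction,
                "n_reporter_hits_dedup": rs.n_reporter_hits_dedup,
                "n_passenger_cells": rs.n_passenger_cells,
                "n_cells_passed_qc": n_passed,
                "fraction_passenger_free": frac_free,
            }
        )
    table = pd.DataFrame(rows)
    # control (t undefined) first, then ascending time
    table = table.sort_values(
        "t_hours", na_position="first", kind="stable"
    ).reset_index(drop=True)
    return table


def _model(t: np.ndarray, p0: float, h: float) -> np.ndarray:
    return p0 * np.power(2.0, -t / h)


def fit_decay(table: pd.DataFrame) -> DecayFit:
    """Fit the decay law to post-exposure passenger read fractions.

    Deterministic: a grid over candidate half-lives (with the closed-form
    optimal p0 for each) seeds a bounded trust-region refinement. Requires
    at least two timed points; all-zero fractions return a degenerate fit
    (p0_hat = 0, half-life undefined) rather than an error.
    """
    timed = table[table["t_hours"].notna()]
    if len(timed) < 2:
        raise ValueError("decay fit requires >= 2 post-exposure timepoints")
    t = timed["t_hours"].to_numpy(dtype=float)
    y = timed["passenger_read_fraction"].to_numpy(dtype=float)
    if np.all(y == 0):
        return DecayFit(0.0, math.nan, 0.0, len(y), degenerate=True)

    def p0_given_h(h: float) -> float:
        w = np.power(2.0, -t / h)
        return float(np.clip(np.dot(w, y) / np.dot(w, w), 0.0, 1.0))

    grid = np.geomspace(0.05, 200.0, 600)
    sses = []
    for h in grid:
        p0 = p0_given_h(h)
        sses.append(float(np.sum((_model(t, p0, h) - y) ** 2)))
    h0 = float(grid[int(np.argmin(sses))])
    x0 = np.array([p0_given_h(h0), h0])
    res = least_squares(
        lambda x: _model(t, x[0], x[1]) - y,
        x0,
        bounds=([0.0, 1e-4], [1.0, 1e4]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    p0_hat, h_hat = float(res.x[0]), float(res.x[1])
    sse = float(np.sum(res.fun**2))
    return DecayFit(p0_hat, h_hat, sse, len(y), degenerate=False)


def write_report(
    kinetics: pd.DataFrame,
    fit: DecayFit,
    config: Mapping,
    outdir: str | Path,
    make_plots: bool = False,
) -> dict[str, Path]:
    """Emit kinetics.tsv, decay_fit.json and a plain-text run log.

    Output bytes depend only on the inputs (no timestamps), so reruns with
    the same seed and config are byte-identical. ``make_plots`` adds a
    per-condition bar chart of passenger read fractions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "kinetics": outdir / "kinetics.tsv",
        "fit": outdir / "decay_fit.json",
        "log": outdir / "run_log.txt",
    }
    kinetics.to_csv(paths["kinetics"], sep="\t", index=False)
    fit_payload = asdict(fit)
    fit_payload["half_life_hat"] = (
        None if math.isnan(fit.half_life_hat) else fit.half_life_hat
    )
    paths["fit"].write_text(json.dumps(fit_payload, indent=2, sort_keys=True) + "\n")
    from . import __version__

    lines = [f"passenger-tracer {__version__}", "configuration:"]
    lines += [f"  {key} = {config[key]}" for key in sorted(config)]
    paths["log"].write_text("\n".join(lines) + "\n")
    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.bar(kinetics["condition"], kinetics["passenger_read_fraction"], color="#4878a8")
        ax.set_ylabel("passenger read fraction")
        ax.set_title("Passenger RNA by co-culture condition")
        fig.tight_layout()
        fig.savefig(outdir / "kinetics.png", dpi=150)
        plt.close(fig)
        paths["plot"] = outdir / "kinetics.png"
    return paths


def load_report_inputs(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Load stage outputs for report assembly; abort naming any missing file."""
    indir = Path(indir)
    for name in REPORT_INPUTS:
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing pipeline output: {indir / name}")
    fractions = pd.read_csv(indir / "species_fractions.tsv", sep="\t")
    summary = pd.read_csv(indir / "rescue_summary.tsv", sep="\t")
    profiles = {}
    for cond in fractions["condition"]:
        path = indir / f"cell_profiles_{cond}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing pipeline output: {path}")
        profiles[cond] = pd.read_csv(path, sep="\t")
    return fractions, summary, profiles
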