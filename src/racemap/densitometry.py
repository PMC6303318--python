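"""Gel time-course quantification: normalization, 50%-decay time, fold change.

Band intensities arrive pre-measured in long format (species, time in
minutes, replicate, intensity) with a designated loading-control species
(e.g. an Actin band co-run in every lane). Each species' signal is
divided by the loading control in the same lane and then by its own
time-zero ratio, so every normalized series starts at exactly 1 and is
invariant to per-lane exposure. The time at which 50% of the RNA is
degraded is read off by log-linear interpolation between the two
sampled time points flanking 0.5 (an exponential-fit mode is available);
fold changes between conditions are tested with a two-sided two-sample
Student's t-test on control-normalized replicate values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("species", "time", "replicate", "intensity")


def read_table(path) -> pd.DataFrame:
    """Read a long-format densitometry TSV and validate its shape."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"densitometry table missing columns: {missing}")
    if (df["intensity"] < 0).any():
        raise ValueError("negative band intensities")
    return df


def normalize_timecourse(
    table: pd.DataFrame, control_species: str = "Actin"
) -> pd.DataFrame:
    """Per-replicate double normalization: loading control, then t = 0.

    s(t) = (I_species(t) / I_control(t)) / (I_species(0) / I_control(0)),
    so s(0) == 1 exactly for every species and replicate. Returns a long
    frame with a ``normalized`` column (control species excluded).
    """
    ctl = table[table["species"] == control_species]
    if ctl.empty:
        raise ValueError(f"loading control {control_species!r} absent from table")
    if (ctl["intensity"] <= 0).any():
        raise ValueError("loading-control intensity must be > 0 at every time point")
    ctl_lookup = ctl.set_index(["time", "replicate"])["intensity"]

    rows = []
    species_tbl = table[table["species"] != control_species]
    for (sp, rep), grp in species_tbl.groupby(["species", "replicate"], sort=False):
        grp = grp.sort_values("time")
        if 0 not in set(grp["time"]):
            raise ValueError(f"missing t=0 for species {sp!r} replicate {rep!r}")
        ratios = {}
        for t, inten in zip(grp["time"], grp["intensity"]):
            if (t, rep) not in ctl_lookup.index:
                raise ValueError(f"missing loading control at time {t}, replicate {rep!r}")
            ratios[t] = inten / ctl_lookup[(t, rep)]
        r0 = ratios[0]
        if r0 == 0:
            raise ValueError(f"zero t=0 signal for species {sp!r} replicate {rep!r}")
        for t in ratios:
            rows.append((sp, t, rep, ratios[t] / r0))
    return pd.DataFrame(rows, columns=["species", "time", "replicate", "normalized"])


def summarize_timecourse(normalized: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and standard error per (species, time)."""
    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    out = (
        normalized.groupby(["species", "time"], sort=True)["normalized"]
        .agg(mean="mean", sem=sem, n="count")
        .reset_index()
    )
    return out


@dataclass
class HalfLife:
    """Time (minutes) at which the normalized signal first reaches 0.5.

    ``reached`` is False when the series never drops to 0.5; ``minutes``
    then holds the last sampled time as a sentinel.
    """

    minutes: float
    reached: bool


def time_to_half(
    times, values, method: str = "interpolate", start_tolerance: float = 1e-6
) -> HalfLife:
    """50%-decay time of a mean normalized series.

    ``method="interpolate"`` (default) takes the first downward crossing
    of 0.5 and interpolates log-linearly between the flanking time
    points, assuming nothing about the kinetics. ``method="fit"`` fits a
    single exponential through s(0)=1 by least squares on log signal and
    returns ln 2 / λ.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape or times.size < 2:
        raise ValueError("need matching 1-D times and values with >= 2 points")
    order = np.argsort(times)
    times, values = times[order], values[order]
    if times[0] != 0 or abs(values[0] - 1.0) > start_tolerance:
        raise ValueError("series must start at t=0 with a normalized value of 1")
    if (values <= 0).any():
        raise ValueError("normalized values must be positive for log interpolation")

    if method == "fit":
        # slope through the origin in log space: ln s = -lambda * t
        lam = -np.sum(times * np.log(values)) / np.sum(times**2)
        if lam <= 0:
            return HalfLife(float(times[-1]), reached=False)
        return HalfLife(float(math.log(2) / lam), reached=True)
    if method != "interpolate":
        raise ValueError(f"unknown method {method!r}")

    below = np.nonzero(values <= 0.5)[0]
    if below.size == 0:
        return HalfLife(float(times[-1]), reached=False)
    j = int(below[0])  # first downward crossing
    if values[j] == 0.5:
        return HalfLife(float(times[j]), reached=True)
    i = j - 1
    t1, t2 = times[i], times[j]
    s1, s2 = values[i], values[j]
    frac = (math.log(s1) - math.log(0.5)) / (math.log(s1) - math.log(s2))
    return HalfLife(float(t1 + frac * (t2 - t1)), reached=True)


@dataclass
class FoldChangeResult:
    fold_change: float
    se: float | None
    p_value: float | None
    degenerate: bool = False


def fold_change_test(
    values_condition, values_reference, equal_var: bool = True
) -> FoldChangeResult:
    """Mean fold change with a two-sided Student's t-test.

    Inputs are replicate values already normalized to their loading or
    transfection control. Fold change = mean(condition)/mean(reference);
    the standard error of the ratio comes from per-replicate ratios
    against the reference mean. The t-test is equal-variance by default
    (Welch via ``equal_var=False``). With fewer than two replicates in
    either group the fold change is still returned but the p-value is
    absent; zero variance in both groups with unequal means is flagged
    ``degenerate`` with p → 0.
    """
    cond = np.asarray(values_condition, dtype=float)
    ref = np.asarray(values_reference, dtype=float)
    if cond.size == 0 or ref.size == 0:
        raise ValueError("both groups need at least one value")
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero; fold change undefined")
    fold = float(cond.mean() / ref_mean)
    ratios = cond / ref_mean
    se = float(ratios.std(ddof=1) / math.sqrt(cond.size)) if cond.size > 1 else None

    if cond.size < 2 or ref.size < 2:
        return FoldChangeResult(fold, se, None)
    var_c = cond.var(ddof=1)
    var_r = ref.var(ddof=1)
    if var_c == 0 and var_r == 0:
        # t undefined; identical means are indistinguishable, different means
        # are infinitely separated at zero variance
        if np.isclose(cond.mean(), ref.mean()):
            return FoldChangeResult(fold, se, 1.0)
        return FoldChangeResult(fold, se, 0.0, degenerate=True)
    t = stats.ttest_ind(cond, ref, equal_var=equal_var)
    return FoldChangeResult(fold, se, float(t.pvalue))


def quantify_table(
    table: pd.DataFrame, control_species: str = "Actin", method: str = "interpolate"
) -> pd.DataFrame:
    """Full time-course readout: per-species normalized means and the
    50%-decay time; returns a tidy summary frame."""
    norm = normalize_timecourse(table, control_species)
    summary = summarize_timecourse(norm)
    rows = []
    for sp, grp in summary.groupby("species", sort=True):
        hl = time_to_half(grp["time"].to_numpy(), grp["mean"].to_numpy(), method=method)
        rows.append((sp, hl.minutes, hl.reached))
    return pd.DataFrame(rows, columns=["species", "half_time_min", "reached_half"])
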