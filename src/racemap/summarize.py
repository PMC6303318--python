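"""Per-sample 3′-end distributions and between-sample comparison.

Tallies assigned end coordinates over the analysis window — every
assigned read counts once, irrespective of whether it carried a
non-templated tail — computes isoform-class fractions over assigned
reads, and forms signed fraction differences between a treatment and a
control sample (the knockdown-versus-control readout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .refmodel import ReferenceModel
from .endmap import ASSIGNED, STATUSES, EndCall, tail_composition


@dataclass
class EndDistribution:
    """Tally of one sample's assigned 3′ ends.

    ``counts`` covers every coordinate of the window; ``failures`` counts
    reads per non-assigned status; class and sub-bin fractions are over
    assigned reads only.
    """

    sample: str
    window: tuple[int, int]
    counts: dict[int, int]
    failures: dict[str, int]
    total_assigned: int
    class_fractions: dict[str, float]
    sub_bin_fractions: dict[str, float]
    ntna_fraction: float
    pure_a_fraction: float

    @property
    def coordinate_fractions(self) -> dict[int, float]:
        if self.total_assigned == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / self.total_assigned for c, n in self.counts.items()}

    @property
    def total_input(self) -> int:
        return self.total_assigned + sum(self.failures.values())


def tally(calls, model: ReferenceModel, sample: str = "sample") -> EndDistribution:
    """Build an :class:`EndDistribution` from end calls.

    Empty input yields a zero-total distribution, not an error.
    """
    ws, we = model.window
    counts = {c: 0 for c in range(ws, we + 1)}
    failures = {s: 0 for s in STATUSES if s != ASSIGNED}
    n_ntna = 0
    n_pure_a = 0
    total = 0
    for call in calls:
        if call.status != ASSIGNED:
            failures[call.status] += 1
            continue
        counts[call.end_coord] += 1
        total += 1
        if call.ntna:
            n_ntna += 1
            _, pure_a = tail_composition(call)
            if pure_a:
                n_pure_a += 1
    class_fr = {}
    for label, (lo, hi) in model.class_bounds.items():
        c = sum(counts[x] for x in range(lo, hi + 1))
        class_fr[label] = c / total if total else 0.0
    sub_fr = {}
    for lo, hi in model.sub_bins:
        c = sum(counts[x] for x in range(lo, hi + 1) if ws <= x <= we)
        sub_fr[f"{lo}-{hi}"] = c / total if total else 0.0
    return EndDistribution(
        sample=sample,
        window=model.window,
        counts=counts,
        failures=failures,
        total_assigned=total,
        class_fractions=class_fr,
        sub_bin_fractions=sub_fr,
        ntna_fraction=n_ntna / total if total else 0.0,
        pure_a_fraction=n_pure_a / total if total else 0.0,
    )


@dataclass
class Comparison:
    """Signed fraction differences, treatment − control."""

    treatment: str
    control: str
    coordinate_delta: dict[int, float]
    class_delta: dict[str, float]
    chi2_p: float | None = None


def compare(
    treatment: EndDistribution, control: EndDistribution, chi_square: bool = False
) -> Comparison:
    """Δfraction per coordinate and per class (treatment − control).

    Deltas are over assigned-read fractions, so they sum to ~0 across
    bins. An optional chi-square test on the coordinate counts is
    available but off by default — no between-distribution test is part
    of the standard readout.
    """
    if treatment.window != control.window:
        raise ValueError(
            f"window mismatch: {treatment.window} vs {control.window}"
        )
    tf = treatment.coordinate_fractions
    cf = control.coordinate_fractions
    coord_delta = {c: tf[c] - cf[c] for c in tf}
    class_delta = {
        k: treatment.class_fractions[k] - control.class_fractions[k]
        for k in treatment.class_fractions
    }
    chi2_p = None
    if chi_square:
        from scipy.stats import chi2_contingency

        rows = [
            [treatment.counts[c] for c in tf],
            [control.counts[c] for c in tf],
        ]
        keep = [i for i in range(len(tf)) if rows[0][i] + rows[1][i] > 0]
        table = [[rows[0][i] for i in keep], [rows[1][i] for i in keep]]
        chi2_p = float(chi2_contingency(table).pvalue)
    return Comparison(treatment.sample, control.sample, coord_delta, class_delta, chi2_p)


# -- reporting ---------------------------------------------------------------


def distribution_frame(dist: EndDistribution) -> pd.DataFrame:
    fr = dist.coordinate_fractions
    return pd.DataFrame(
        {
            "coord": list(dist.counts),
            "count": list(dist.counts.values()),
            "fraction": [fr[c] for c in dist.counts],
        }
    )


def write_report(
    distributions,
    comparisons=(),
    outdir=".",
    plot: bool = False,
) -> list[Path]:
    """Write per-sample TSVs, a JSON class summary, comparison TSVs and
    optional paired bar charts; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary = {}
    for dist in distributions:
        p = outdir / f"{dist.sample}.ends.tsv"
        distribution_frame(dist).to_csv(p, sep="\t", index=False)
        written.append(p)
        summary[dist.sample] = {
            "window": list(dist.window),
            "total_assigned": dist.total_assigned,
            "failures": dist.failures,
            "class_fractions": dist.class_fractions,
            "sub_bin_fractions": dist.sub_bin_fractions,
            "ntna_fraction": dist.ntna_fraction,
            "pure_a_fraction": dist.pure_a_fraction,
        }
    p = outdir / "class_summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=1)
    written.append(p)
    for comp in comparisons:
        name = f"{comp.treatment}_vs_{comp.control}"
        df = pd.DataFrame(
            {
                "coord": list(comp.coordinate_delta),
                "delta_fraction": list(comp.coordinate_delta.values()),
            }
        )
        p = outdir / f"{name}.delta.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
        if plot:
            written.append(_plot_comparison(comp, outdir / f"{name}.png"))
    return written


def read_distribution_tsv(path, sample: str | None = None) -> tuple[dict[int, int], int]:
    """Re-read a per-sample ends TSV; returns (counts, total_assigned)."""
    df = pd.read_csv(path, sep="\t")
    counts = {int(c): int(n) for c, n in zip(df["coord"], df["count"])}
    return counts, int(df["count"].sum())


def _plot_comparison(comp: Comparison, path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = list(comp.coordinate_delta)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.bar(coords, list(comp.coordinate_delta.values()), width=1.0)
    ax.set_xlabel("3' end coordinate (nt)")
    ax.set_ylabel("Δ fraction (treatment − control)")
    ax.set_title(f"{comp.treatment} vs {comp.control}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
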