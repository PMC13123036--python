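"""Per-generation reporting: gain scaling, conversion efficiencies, ancestry.

Genetic levels are expressed in genetic standard deviations (gSD), the
square root of the genic variance in the first post-burn-in generation of
the same replicate, with that generation's mean centred to zero.  Conversion
efficiencies relate the cumulative gain over the reported horizon to the
diversity lost over the same span, mirroring the usual Delta-G per
Delta-diversity bookkeeping of long-term selection studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_sim import HaplotypePanel, TraitArchitecture

__all__ = [
    "MetricsReport",
    "scale_metrics",
    "conversion_efficiencies",
    "trace_donor_ancestry",
    "potential_ancestors",
    "lost_beneficial_alleles",
    "compare_scenarios",
    "summarize_replicates",
]


@dataclass
class MetricsReport:
    """A per-generation metrics table for one replicate of one scenario.

    Wraps the raw frame produced by the scheme and adds the gSD-scaled
    view (generation 0 = first post-burn-in generation).
    """

    raw: pd.DataFrame

    def __post_init__(self) -> None:
        if "generation" not in self.raw.columns:
            raise ValueError("metrics frame lacks a generation column")

    @property
    def scaled(self) -> pd.DataFrame:
        return scale_metrics(self.raw)


def scale_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Post-burn-in metrics with TBV means re-expressed in gSD units.

    Generation 0 is the first generation after burn-in; its genic variance
    defines the gSD unit and its elite mean TBV the zero point.  The
    selection limit is centred the same way so gain and limit share a scale.
    """
    out = df[df["generation"] >= 0].reset_index(drop=True).copy()
    base = out[out["generation"] == 0]
    if base.empty:
        raise ValueError("no generation-0 row; run the scheme past burn-in")
    gsd = float(np.sqrt(base["genic_variance"].iloc[0]))
    origin = float(base["mean_tbv_elite"].iloc[0])
    out["gain_gsd"] = (out["mean_tbv_elite"] - origin) / gsd
    out["gsd"] = np.sqrt(out["genic_variance"]) / gsd
    out["selection_limit_gsd"] = (out["selection_limit"] - origin) / gsd
    return out


def conversion_efficiencies(report: MetricsReport | pd.DataFrame) -> dict[str, float]:
    """Gain per unit diversity lost between the first and last generation.

    Returns Delta-G per Delta-gSD, per percentage-point kinship increase,
    per gSD of selection limit lost, and per 1000 unique haplotypes lost.
    Ratios with a zero-loss denominator are reported as NaN; everything is
    computed from unrounded accumulators.
    """
    df = report.scaled if isinstance(report, MetricsReport) else scale_metrics(report)
    if len(df) < 2:
        raise ValueError("need at least two generations")
    first, last = df.iloc[0], df.iloc[-1]
    gain = last["gain_gsd"] - first["gain_gsd"]

    def ratio(loss: float) -> float:
        return float(gain / loss) if abs(loss) > 1e-12 else float("nan")

    return {
        "gain_gsd": float(gain),
        "per_gsd": ratio(first["gsd"] - last["gsd"]),
        "per_pct_kinship": ratio(100.0 * (last["mean_kinship_ibd"] - first["mean_kinship_ibd"])),
        "per_selection_limit_gsd": ratio(first["selection_limit_gsd"] - last["selection_limit_gsd"]),
        "per_1k_haplotypes": ratio((first["unique_haplotypes_all"] - last["unique_haplotypes_all"]) / 1000.0),
    }


def potential_ancestors(depth: int) -> int:
    """Maximum number of distinct ancestor slots ``depth`` generations back."""
    return 2 ** depth


def trace_donor_ancestry(
    pedigree: pd.DataFrame,
    animals: np.ndarray | list,
    donor_ids: set[int] | list,
    depth: int = 10,
) -> pd.DataFrame:
    """Flag donor descendants and their expected donor pedigree contribution.

    For each animal, paths up the pedigree are followed for at most
    ``depth`` generations; a path terminates at the first donor it meets and
    contributes 2^-(path length).  A donor used as sire therefore
    contributes 0.5 and one donor ancestor ten generations back 1/1024.
    """
    donor_ids = set(int(d) for d in donor_ids)
    sire = dict(zip(pedigree["id"].astype(int), pedigree["sire"].astype(int)))
    dam = dict(zip(pedigree["id"].astype(int), pedigree["dam"].astype(int)))
    cache: dict[tuple[int, int], float] = {}
    visiting: set[int] = set()

    def contrib(a: int, d: int) -> float:
        if d == 0 or a < 0:
            return 0.0
        key = (a, d)
        if key in cache:
            return cache[key]
        if a in visiting:
            raise ValueError(f"pedigree cycle at animal {a}")
        visiting.add(a)
        total = 0.0
        for parent in (sire.get(a, -1), dam.get(a, -1)):
            if parent < 0:
                continue
            total += 0.5 * (1.0 if parent in donor_ids else contrib(parent, d - 1))
        visiting.discard(a)
        cache[key] = total
        return total

    rows = []
    for a in animals:
        c = contrib(int(a), depth)
        rows.append({"id": int(a), "has_donor_ancestor": c > 0.0, "donor_contribution": c})
    return pd.DataFrame(rows)


def lost_beneficial_alleles(panel: HaplotypePanel, trait: TraitArchitecture, rows=None) -> float:
    """Percentage of QTL fixed for the unfavourable allele in the subset."""
    p = trait.beneficial_freq(panel, rows=rows)
    return 100.0 * float(np.mean(p == 0.0))


def compare_scenarios(
    tables_a: list[pd.DataFrame],
    tables_b: list[pd.DataFrame],
    metric: str,
    generation: int | None = None,
) -> dict:
    """Paired t-test of a metric between two scenarios, paired by replicate.

    Replicates must match in number and seed order.  With identical values
    the statistic is 0 and p = 1; a constant non-zero difference (zero
    variance) is flagged as degenerate.
    """
    if len(tables_a) != len(tables_b):
        raise ValueError("replicate counts differ")
    if len(tables_a) < 3:
        raise ValueError("need at least 3 paired replicates")

    def value(df: pd.DataFrame) -> float:
        gen = df["generation"].max() if generation is None else generation
        return float(df.loc[df["generation"] == gen, metric].iloc[0])

    a = np.array([value(t) for t in tables_a])
    b = np.array([value(t) for t in tables_b])
    diff = a - b
    if np.allclose(diff, 0.0):
        return {"t": 0.0, "p": 1.0, "mean_diff": 0.0, "degenerate": False}
    if np.isclose(np.std(diff, ddof=1), 0.0):
        return {"t": np.inf, "p": 0.0, "mean_diff": float(diff.mean()), "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "mean_diff": float(diff.mean()), "degenerate": False}


def plot_trajectories(
    tables_by_scenario: dict,
    metrics: tuple[str, ...] = ("gain_gsd", "genic_variance", "mean_kinship_ibd", "unique_haplotypes_all"),
    out: str | None = None,
):
    """Replicate-mean trajectories per scenario (gain and diversity panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2))
    axes = np.atleast_1d(axes)
    for label, tables in tables_by_scenario.items():
        summary = summarize_replicates(tables, columns=list(metrics))
        for ax, m in zip(axes, metrics):
            ax.plot(summary["generation"], summary[f"{m}_mean"], label=str(label))
            ax.set_xlabel("generation")
            ax.set_ylabel(m)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig


def summarize_replicates(tables: list[pd.DataFrame], columns: list[str] | None = None) -> pd.DataFrame:
    """Replicate mean (and SD) of the scaled metrics per generation."""
    scaled = [scale_metrics(t) for t in tables]
    cols = columns or [
        "gain_gsd",
        "genic_variance",
        "mean_kinship_ibd",
        "selection_limit_gsd",
        "unique_haplotypes_all",
        "pct_beneficial_lost",
    ]
    stacked = pd.concat(scaled, keys=range(len(scaled)), names=["replicate"])
    g = stacked.groupby("generation")[cols]
    mean = g.mean().add_suffix("_mean")
    sd = g.std().add_suffix("_sd")
    return mean.join(sd).reset_index()
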