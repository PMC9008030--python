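"""EM morphometry summaries: densities, class fractions, sizes, connectivity.

Operates on three tables (spines, synapses, dendrites) describing
EM-reconstructed dendritic segments. Printed percentages use round-half-up
to integer percent, matching how such tables are conventionally formatted.

A compound (redundant) connection is an axon forming at least two synapses
with the same dendritic segment; contacts of one axon on different
dendrites do not count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "MorphometryTable",
    "densities_and_fractions",
    "size_metrics",
    "compound_connections",
    "ttest_unpaired",
    "round_half_up_pct",
]


def round_half_up_pct(numerator: float, denominator: float) -> int:
    """Percentage rounded half-up to an integer (table formatting rule)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class MorphometryTable:
    """spines / synapses / dendrites record tables (see module docstring)."""

    spines: pd.DataFrame  # id, dendrite_id, group, volume_um3, surface_um2, has_er, new_spine
    synapses: pd.DataFrame  # id, dendrite_id, class, surface_um2, location, spine_id, axon_id, msb
    dendrites: pd.DataFrame  # id, group, length_um

    def __post_init__(self):
        if (self.dendrites["length_um"] <= 0).any():
            raise ValueError("dendrite lengths must be positive")
        bad = ~self.synapses["class"].isin(["exc", "inh", "unclassified"])
        if bad.any():
            raise ValueError("synapse class labels must be exc/inh/unclassified")
        on_spine = self.synapses["location"] == "spine"
        known = self.synapses.loc[on_spine, "spine_id"].isin(self.spines["id"])
        if not known.all():
            raise ValueError("spine-located synapse references unknown spine")

    def group_of_dendrite(self) -> pd.Series:
        return self.dendrites.set_index("id")["group"]


def densities_and_fractions(table: MorphometryTable) -> pd.DataFrame:
    """Per-group synapse densities and composition fractions.

    Columns include the synapse linear density (um^-1), per-class counts,
    densities and integer percentages, percent of synapses located on
    spines, percent of spines with >= 1 / >= 2 synapses and >= 2 excitatory
    synapses, percent of spines with ER, and percent of excitatory spine
    synapses with multisynaptic boutons.
    """
    gmap = table.group_of_dendrite()
    syn = table.synapses.assign(group=lambda d: d["dendrite_id"].map(gmap))
    spines = table.spines
    rows = []
    for group, dsub in table.dendrites.groupby("group"):
        length = float(dsub["length_um"].sum())
        s = syn[syn["group"] == group]
        sp = spines[spines["group"] == group]
        n_syn = len(s)
        row = {
            "group": group,
            "dendrite_length_um": length,
            "n_synapses": n_syn,
            "synapse_density_per_um": n_syn / length,
        }
        for cls in ("exc", "inh", "unclassified"):
            n_cls = int((s["class"] == cls).sum())
            row[f"n_{cls}"] = n_cls
            row[f"density_{cls}_per_um"] = n_cls / length
            row[f"pct_{cls}"] = round_half_up_pct(n_cls, n_syn) if n_syn else 0
        row["pct_synapses_on_spines"] = (
            round_half_up_pct(int((s["location"] == "spine").sum()), n_syn) if n_syn else 0
        )
        for cls in ("exc", "inh"):
            n_cls = int((s["class"] == cls).sum())
            n_on_spine = int(((s["class"] == cls) & (s["location"] == "spine")).sum())
            row[f"n_{cls}_on_spines"] = n_on_spine
            row[f"pct_{cls}_on_spines"] = round_half_up_pct(n_on_spine, n_cls) if n_cls else 0
        if len(sp):
            syn_per_spine = (
                s[s["location"] == "spine"].groupby("spine_id").size().reindex(sp["id"]).fillna(0)
            )
            exc_per_spine = (
                s[(s["location"] == "spine") & (s["class"] == "exc")]
                .groupby("spine_id")
                .size()
                .reindex(sp["id"])
                .fillna(0)
            )
            row["n_spines"] = len(sp)
            row["spine_density_per_um"] = len(sp) / length
            row["pct_spines_with_syn"] = round_half_up_pct(int((syn_per_spine >= 1).sum()), len(sp))
            row["pct_spines_multi_syn"] = round_half_up_pct(int((syn_per_spine >= 2).sum()), len(sp))
            row["pct_spines_multi_exc"] = round_half_up_pct(int((exc_per_spine >= 2).sum()), len(sp))
            if "has_er" in sp:
                row["pct_spines_with_er"] = round_half_up_pct(int(sp["has_er"].sum()), len(sp))
            exc_spine_syn = s[(s["class"] == "exc") & (s["location"] == "spine")]
            if "msb" in exc_spine_syn and len(exc_spine_syn):
                row["pct_exc_spine_syn_msb"] = round_half_up_pct(
                    int(exc_spine_syn["msb"].sum()), len(exc_spine_syn)
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def size_metrics(table: MorphometryTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-spine size ratios and per-group summaries.

    Returns ``(per_spine, summary)``. Per spine: surface-to-volume ratio
    (um^-1) and summed excitatory synapse surface divided by spine volume.
    Records with non-positive volume are rejected with a diagnostic warning.
    """
    sp = table.spines.copy()
    bad = sp["volume_um3"] <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} spine record(s) with non-positive volume rejected")
        sp = sp[~bad]
    syn = table.synapses
    exc_sa = (
        syn[(syn["class"] == "exc") & (syn["location"] == "spine")]
        .groupby("spine_id")["surface_um2"]
        .sum()
    )
    per = sp[["id", "dendrite_id", "group", "volume_um3", "surface_um2"]].copy()
    per["sa_to_vol"] = per["surface_um2"] / per["volume_um3"]
    per["exc_syn_sa"] = per["id"].map(exc_sa)
    per["syn_sa_to_spine_vol"] = per["exc_syn_sa"] / per["volume_um3"]
    summary = (
        per.groupby("group")[["volume_um3", "surface_um2", "sa_to_vol", "syn_sa_to_spine_vol"]]
        .agg(["mean", "std", "count"])
    )
    return per, summary


def compound_connections(table: MorphometryTable) -> pd.DataFrame:
    """Per-group compound-connection statistics.

    A synapse is compound iff its axon makes >= 2 synapses on the same
    dendrite. Reports counts and integer percentages of compound synapses,
    plus the number and linear density of compound axons. Synapses with a
    missing axon id are excluded (with a warning carrying the count).
    """
    gmap = table.group_of_dendrite()
    syn = table.synapses.assign(group=lambda d: d["dendrite_id"].map(gmap))
    missing = syn["axon_id"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} synapse(s) without axon id excluded")
        syn = syn[~missing]
    rows = []
    for group, dsub in table.dendrites.groupby("group"):
        s = syn[syn["group"] == group]
        length = float(dsub["length_um"].sum())
        sizes = s.groupby(["axon_id", "dendrite_id"]).size()
        compound_pairs = sizes[sizes >= 2]
        n_comp_syn = int(compound_pairs.sum())
        n_comp_axons = int(compound_pairs.index.get_level_values("axon_id").nunique())
        rows.append(
            {
                "group": group,
                "n_synapses": len(s),
                "n_compound_synapses": n_comp_syn,
                "pct_compound_synapses": (
                    round_half_up_pct(n_comp_syn, len(s)) if len(s) else 0
                ),
                "n_compound_axons": n_comp_axons,
                "compound_axon_density_per_um": n_comp_axons / length,
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def ttest_unpaired(
    a=None,
    b=None,
    *,
    stats: tuple[tuple[float, float, int], tuple[float, float, int]] | None = None,
    welch: bool = True,
) -> TTestResult:
    """Two-tailed unpaired t-test from raw samples or (mean, sd, n) summaries.

    Welch (unequal variances) by default; ``welch=False`` gives the
    pooled-variance Student variant. Two zero-variance groups with equal
    means return p = 1 by convention.
    """
    from scipy import stats as sps

    if stats is not None:
        (m1, s1, n1), (m2, s2, n2) = stats
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs n >= 2")
        if s1 == 0 and s2 == 0:
            if m1 == m2:
                return TTestResult(t=0.0, df=n1 + n2 - 2, p=1.0, variant="degenerate")
            return TTestResult(t=np.inf, df=n1 + n2 - 2, p=0.0, variant="degenerate")
        res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
        if welch:
            v1, v2 = s1**2 / n1, s2**2 / n2
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
        return TTestResult(
            t=float(res.statistic), df=float(df), p=float(res.pvalue),
            variant="welch" if welch else "student",
        )
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return TTestResult(t=0.0, df=a.size + b.size - 2, p=1.0, variant="degenerate")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    return TTestResult(
        t=float(res.statistic), df=df, p=float(res.pvalue),
        variant="welch" if welch else "student",
    )
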