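"""Synthetic EM morphometry tables.

Emulates the record structure of EM-reconstructed dendritic segments: two
groups of spines with truncated-normal volumes/surfaces, synapses with a
configurable excitatory/inhibitory/unclassified mix and spine/shaft
location, and axon identifiers drawn so that a chosen fraction of synapses
belongs to compound connections (axons contacting the same dendrite at
least twice). Default size distributions follow the published group
summaries (spine volume 0.07 +/- 0.05 um^3 for the VIP group vs
0.16 +/- 0.16 um^3 for the control dendrite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .._rng import substream
from ..morphometry import MorphometryTable

__all__ = ["MorphometrySimParams", "simulate_morphometry_table"]


@dataclass
class GroupParams:
    n_spines: int = 77
    dendrite_length_um: float = 161.0
    volume_mean: float = 0.07
    volume_sd: float = 0.05
    surface_mean: float = 1.04
    surface_sd: float = 0.49
    syn_per_um: float = 1.92
    class_mix: tuple[float, float, float] = (0.80, 0.10, 0.10)  # exc, inh, uncl
    syn_surface_mean: float = 0.13
    syn_surface_sd: float = 0.08
    frac_syn_on_spines: float = 0.3
    er_fraction: float = 0.79
    msb_fraction: float = 0.10
    compound_rate: float = 0.19  # target fraction of synapses in compound connections


@dataclass
class MorphometrySimParams:
    groups: Mapping[str, GroupParams] = field(
        default_factory=lambda: {
            "VIP": GroupParams(),
            "CTR": GroupParams(
                n_spines=80,
                dendrite_length_um=67.0,
                volume_mean=0.16,
                volume_sd=0.16,
                surface_mean=1.88,
                surface_sd=1.16,
                syn_per_um=1.84,
                class_mix=(0.79, 0.19, 0.02),
                syn_surface_mean=0.19,
                syn_surface_sd=0.15,
                frac_syn_on_spines=0.7,
                er_fraction=0.76,
                msb_fraction=0.08,
                compound_rate=0.05,
            ),
        }
    )
    seed: int = 0


def _trunc_normal(rng, mean, sd, n, floor=1e-3):
    """Normal draws truncated at a small positive floor by redrawing."""
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out <= floor
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, floor, None)


def simulate_morphometry_table(params: MorphometrySimParams) -> MorphometryTable:
    params_items = list(params.groups.items())
    spine_rows, syn_rows, dend_rows = [], [], []
    sid = syn_id = axon_id = 0
    for group, gp in params_items:
        rng = substream(params.seed, "morphometry", group)
        if not np.isclose(sum(gp.class_mix), 1.0):
            raise ValueError("class mix must sum to 1")
        dendrite = f"{group.lower()}_d0"
        dend_rows.append({"id": dendrite, "group": group, "length_um": gp.dendrite_length_um})

        vols = _trunc_normal(rng, gp.volume_mean, gp.volume_sd, gp.n_spines)
        surfs = _trunc_normal(rng, gp.surface_mean, gp.surface_sd, gp.n_spines)
        spine_ids = []
        for v, s in zip(vols, surfs):
            spine_ids.append(f"sp{sid:05d}")
            spine_rows.append(
                {
                    "id": spine_ids[-1],
                    "dendrite_id": dendrite,
                    "group": group,
                    "volume_um3": v,
                    "surface_um2": s,
                    "has_er": bool(rng.random() < gp.er_fraction),
                    "new_spine": False,
                }
            )
            sid += 1

        n_syn = int(round(gp.syn_per_um * gp.dendrite_length_um))
        classes = rng.choice(["exc", "inh", "unclassified"], size=n_syn, p=gp.class_mix)
        on_spine = rng.random(n_syn) < gp.frac_syn_on_spines
        surfaces = _trunc_normal(rng, gp.syn_surface_mean, gp.syn_surface_sd, n_syn)

        # assign axons: pair up ~compound_rate of synapses on shared axons
        n_compound_syn = int(round(gp.compound_rate * n_syn))
        axons = []
        k = 0
        while k < n_compound_syn - 1:
            ax = f"ax{axon_id:05d}"
            axon_id += 1
            axons += [ax, ax]  # a compound axon with two contacts
            k += 2
        while len(axons) < n_syn:
            axons.append(f"ax{axon_id:05d}")
            axon_id += 1
        rng.shuffle(axons)

        for j in range(n_syn):
            syn_rows.append(
                {
                    "id": f"syn{syn_id:05d}",
                    "dendrite_id": dendrite,
                    "class": classes[j],
                    "surface_um2": surfaces[j],
                    "location": "spine" if on_spine[j] else "shaft",
                    "spine_id": (
                        spine_ids[int(rng.integers(len(spine_ids)))] if on_spine[j] else None
                    ),
                    "axon_id": axons[j],
                    "msb": bool(rng.random() < gp.msb_fraction),
                }
            )
            syn_id += 1

    return MorphometryTable(
        spines=pd.DataFrame(spine_rows),
        synapses=pd.DataFrame(syn_rows),
        dendrites=pd.DataFrame(dend_rows),
    )
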