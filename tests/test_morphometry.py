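"""EM morphometry arithmetic (densities, fractions, sizes, compound
connections, t-tests) checked against hand counts and closed forms."""

import numpy as np
import pandas as pd
import pytest

from spinefate.morphometry import (
    MorphometryTable,
    compound_connections,
    densities_and_fractions,
    round_half_up_pct,
    size_metrics,
    ttest_unpaired,
)
from spinefate.simulate import MorphometrySimParams, simulate_morphometry_table
from spinefate.simulate.morphometry import GroupParams


def minimal_table(spines=None, synapses=None, dendrites=None):
    spines = spines if spines is not None else pd.DataFrame(
        columns=["id", "dendrite_id", "group", "volume_um3", "surface_um2", "has_er", "new_spine"]
    )
    synapses = synapses if synapses is not None else pd.DataFrame(
        columns=["id", "dendrite_id", "class", "surface_um2", "location", "spine_id", "axon_id", "msb"]
    )
    dendrites = dendrites if dendrites is not None else pd.DataFrame(
        {"id": ["d0"], "group": ["VIP"], "length_um": [10.0]}
    )
    return MorphometryTable(spines=spines, synapses=synapses, dendrites=dendrites)


def synapse_rows(n, dendrite="d0", cls="exc", location="shaft", start=0, **kw):
    return [
        {
            "id": f"syn{start + i}",
            "dendrite_id": dendrite,
            "class": cls,
            "surface_um2": kw.get("surface", 0.1),
            "location": location,
            "spine_id": kw.get("spine_id"),
            "axon_id": kw.get("axon_id", f"ax{start + i}"),
            "msb": False,
        }
        for i in range(n)
    ]


class TestDensities:
    def test_published_table_arithmetic(self):
        syn = pd.DataFrame(
            synapse_rows(309, "d_vip") + synapse_rows(123, "d_ctr", start=1000)
        )
        dend = pd.DataFrame(
            {"id": ["d_vip", "d_ctr"], "group": ["VIP", "CTR"], "length_um": [161.0, 67.0]}
        )
        out = densities_and_fractions(minimal_table(synapses=syn, dendrites=dend))
        assert out.loc["VIP", "synapse_density_per_um"] == pytest.approx(1.92, abs=0.005)
        assert out.loc["CTR", "synapse_density_per_um"] == pytest.approx(1.84, abs=0.005)

    def test_empty_synapse_table(self):
        out = densities_and_fractions(minimal_table())
        assert out.loc["VIP", "synapse_density_per_um"] == 0.0

    def test_class_percentages_sum_to_100(self):
        table = simulate_morphometry_table(MorphometrySimParams(seed=3))
        out = densities_and_fractions(table)
        sums = out[["pct_exc", "pct_inh", "pct_unclassified"]].sum(axis=1)
        assert ((sums - 100).abs() <= 1).all()

    def test_density_times_length_is_integer(self):
        table = simulate_morphometry_table(MorphometrySimParams(seed=0))
        out = densities_and_fractions(table)
        counts = out["synapse_density_per_um"] * out["dendrite_length_um"]
        assert np.allclose(counts, np.round(counts))

    def test_multi_synapse_spine_fraction(self):
        # 19 of 77 spines with >= 2 synapses -> 25%
        spines = pd.DataFrame(
            {
                "id": [f"sp{i}" for i in range(77)],
                "dendrite_id": "d0",
                "group": "VIP",
                "volume_um3": 0.1,
                "surface_um2": 1.0,
                "has_er": False,
                "new_spine": False,
            }
        )
        rows = []
        k = 0
        for i in range(19):  # two synapses each
            for _ in range(2):
                rows += synapse_rows(1, cls="exc", location="spine", spine_id=f"sp{i}", start=k)
                k += 1
        out = densities_and_fractions(
            minimal_table(spines=spines, synapses=pd.DataFrame(rows))
        )
        assert out.loc["VIP", "pct_spines_multi_syn"] == 25

    def test_round_half_up(self):
        assert round_half_up_pct(7, 80) == 9  # 8.75 rounds up
        assert round_half_up_pct(19, 77) == 25
        assert round_half_up_pct(248, 309) == 80
        assert round_half_up_pct(68, 248) == 27


class TestSizeMetrics:
    def test_sa_to_vol_ratio(self):
        spines = pd.DataFrame(
            [
                {
                    "id": "sp0",
                    "dendrite_id": "d0",
                    "group": "VIP",
                    "volume_um3": 0.10,
                    "surface_um2": 1.50,
                    "has_er": True,
                    "new_spine": False,
                }
            ]
        )
        per, _ = size_metrics(minimal_table(spines=spines))
        assert per["sa_to_vol"].iloc[0] == pytest.approx(15.0)

    def test_summed_synapse_surface_over_volume(self):
        spines = pd.DataFrame(
            [
                {
                    "id": "sp0",
                    "dendrite_id": "d0",
                    "group": "VIP",
                    "volume_um3": 0.07,
                    "surface_um2": 1.0,
                    "has_er": True,
                    "new_spine": False,
                }
            ]
        )
        syn = pd.DataFrame(
            synapse_rows(1, cls="exc", location="spine", spine_id="sp0", surface=0.05)
            + synapse_rows(1, cls="exc", location="spine", spine_id="sp0", surface=0.08, start=1)
        )
        per, _ = size_metrics(minimal_table(spines=spines, synapses=syn))
        assert per["syn_sa_to_spine_vol"].iloc[0] == pytest.approx(0.13 / 0.07, abs=1e-9)

    def test_group_mean_matches_generator(self):
        rng = np.random.default_rng(8)
        ratios = rng.normal(18.4, 6.9, 77)
        vols = np.full(77, 0.1)
        spines = pd.DataFrame(
            {
                "id": [f"sp{i}" for i in range(77)],
                "dendrite_id": "d0",
                "group": "VIP",
                "volume_um3": vols,
                "surface_um2": ratios * vols,
                "has_er": False,
                "new_spine": False,
            }
        )
        _, summary = size_metrics(minimal_table(spines=spines))
        mean = summary.loc["VIP", ("sa_to_vol", "mean")]
        assert abs(mean - 18.4) < 2.58 * 6.9 / np.sqrt(77)

    def test_nonpositive_volume_rejected_with_warning(self):
        spines = pd.DataFrame(
            {
                "id": ["a", "b"],
                "dendrite_id": "d0",
                "group": "VIP",
                "volume_um3": [0.1, 0.0],
                "surface_um2": [1.0, 1.0],
                "has_er": False,
                "new_spine": False,
            }
        )
        with pytest.warns(UserWarning, match="non-positive"):
            per, _ = size_metrics(minimal_table(spines=spines))
        assert len(per) == 1


class TestCompound:
    def test_hand_count(self):
        rows = synapse_rows(3, axon_id="shared") + synapse_rows(7, start=10)
        for i in range(3):
            rows[i]["id"] = f"c{i}"
        out = compound_connections(minimal_table(synapses=pd.DataFrame(rows)))
        assert out.loc["VIP", "pct_compound_synapses"] == 30
        assert out.loc["VIP", "n_compound_axons"] == 1

    def test_unique_axons_give_zero(self):
        out = compound_connections(minimal_table(synapses=pd.DataFrame(synapse_rows(10))))
        assert out.loc["VIP", "n_compound_synapses"] == 0

    def test_contacts_on_different_dendrites_not_compound(self):
        dend = pd.DataFrame(
            {"id": ["d0", "d1"], "group": ["VIP", "VIP"], "length_um": [10.0, 10.0]}
        )
        rows = synapse_rows(1, dendrite="d0", axon_id="ax_shared") + synapse_rows(
            1, dendrite="d1", axon_id="ax_shared", start=1
        )
        out = compound_connections(minimal_table(synapses=pd.DataFrame(rows), dendrites=dend))
        assert out.loc["VIP", "n_compound_synapses"] == 0

    def test_invariant_to_row_order_and_relabeling(self):
        rows = synapse_rows(2, axon_id="A") + synapse_rows(5, start=5)
        df = pd.DataFrame(rows)
        base = compound_connections(minimal_table(synapses=df))
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["axon_id"] = shuffled["axon_id"].map(lambda a: f"relabel_{a}")
        again = compound_connections(minimal_table(synapses=shuffled))
        pd.testing.assert_frame_equal(base, again)

    def test_missing_axon_ids_excluded_with_warning(self):
        rows = synapse_rows(4)
        rows[0]["axon_id"] = None
        with pytest.warns(UserWarning, match="without axon id"):
            out = compound_connections(minimal_table(synapses=pd.DataFrame(rows)))
        assert out.loc["VIP", "n_synapses"] == 3


class TestTTest:
    def test_welch_from_published_summaries(self):
        res = ttest_unpaired(stats=((0.07, 0.05, 77), (0.16, 0.16, 80)))
        assert abs(res.t) == pytest.approx(4.8, abs=0.1)
        assert res.p < 0.001

    def test_identical_groups(self):
        res = ttest_unpaired([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_summary_equals_moment_matched_raw_samples(self):
        rng = np.random.default_rng(2)

        def matched(mean, sd, n):
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        a = matched(0.07, 0.05, 77)
        b = matched(0.16, 0.16, 80)
        from_raw = ttest_unpaired(a, b)
        from_stats = ttest_unpaired(stats=((0.07, 0.05, 77), (0.16, 0.16, 80)))
        assert from_raw.t == pytest.approx(from_stats.t, abs=1e-9)
        assert from_raw.df == pytest.approx(from_stats.df, abs=1e-6)

    def test_student_variant_available(self):
        res = ttest_unpaired([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], welch=False)
        assert res.variant == "student" and res.df == 4


class TestSimulator:
    def test_zero_compound_rate(self):
        gp = {"VIP": GroupParams(compound_rate=0.0)}
        table = simulate_morphometry_table(MorphometrySimParams(groups=gp, seed=0))
        out = compound_connections(table)
        assert out.loc["VIP", "n_compound_synapses"] == 0

    def test_all_asymmetric_gives_pure_excitatory(self):
        gp = {"VIP": GroupParams(class_mix=(1.0, 0.0, 0.0))}
        table = simulate_morphometry_table(MorphometrySimParams(groups=gp, seed=1))
        out = densities_and_fractions(table)
        assert out.loc["VIP", "pct_exc"] == 100

    def test_volume_difference_power_at_published_effect_size(self):
        """77 vs 80 spines at the published volume summaries: Welch detects
        the difference at p < 0.001 in nearly every replicate."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            table = simulate_morphometry_table(MorphometrySimParams(seed=seed))
            vip = table.spines.loc[table.spines["group"] == "VIP", "volume_um3"]
            ctr = table.spines.loc[table.spines["group"] == "CTR", "volume_um3"]
            res = ttest_unpaired(vip, ctr)
            hits += res.p < 0.001
        assert hits >= int(0.95 * n_seeds)

    def test_determinism(self):
        a = simulate_morphometry_table(MorphometrySimParams(seed=5))
        b = simulate_morphometry_table(MorphometrySimParams(seed=5))
        pd.testing.assert_frame_equal(a.spines, b.spines)
        pd.testing.assert_frame_equal(a.synapses, b.synapses)
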