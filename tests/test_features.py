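import numpy as np
import pandas as pd
import pytest

from epspec import features, pipeline
from epspec.dataio import ContactMap, ElementTable
from .conftest import tiny_sim_config
from .oracles import naive_feature_table


def _elements(rows):
    return ElementTable(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "element_id", "kind"])
    )


class TestCandidates:
    def test_half_window_rule(self):
        """Pairing uses half the window span, center to center."""
        tab = _elements(
            [
                ("chr1", 10_000_000, 10_000_001, "p1", "tss"),
                ("chr1", 8_999_750, 9_000_250, "e1", "enhancer"),  # 1 Mb away
                ("chr1", 13_999_750, 14_000_250, "e2", "enhancer"),  # 4 Mb away
            ]
        )
        ep = features.ep_candidates(tab, window_bp=5_000_000)
        assert list(ep["enhancer_id"]) == ["e1"]
        assert ep["distance"].iloc[0] == 1_000_000

    def test_other_chromosome_excluded(self):
        tab = _elements(
            [
                ("chr1", 100, 101, "p1", "tss"),
                ("chr2", 200, 300, "e1", "enhancer"),
            ]
        )
        assert len(features.ep_candidates(tab)) == 0

    def test_exact_half_window_boundary_included(self):
        tab = _elements(
            [
                ("chr1", 10_000_000, 10_000_001, "p1", "tss"),
                ("chr1", 12_499_900, 12_500_100, "e1", "enhancer"),  # mid exactly +2.5 Mb
            ]
        )
        ep = features.ep_candidates(tab, window_bp=5_000_000)
        assert len(ep) == 1
        assert ep["distance"].iloc[0] == 2_500_000

    def test_no_enhancers_gives_empty_table(self):
        tab = _elements([("chr1", 100, 101, "p1", "tss")])
        assert len(features.ep_candidates(tab)) == 0


def _one_tss_setup(contacts_by_enh, activities):
    """One TSS at 1 Mb with enhancers at distinct bins and set contacts."""
    rows = [("chr1", 1_000_000, 1_000_001, "p1", "tss")]
    cmap = ContactMap(bin_size=5000)
    tss_bin = 1_000_000 // 5000
    sig = {"element_id": [], "H3K27ac": []}
    for i, (c, a) in enumerate(zip(contacts_by_enh, activities)):
        start = 1_010_000 + i * 10_000
        rows.append(("chr1", start, start + 1000, f"e{i}", "enhancer"))
        cmap.add("chr1", tss_bin, (start + 500) // 5000, c)
        sig["element_id"].append(f"e{i}")
        sig["H3K27ac"].append(a)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "element_id", "kind"])
    df["H3K27ac"] = df["element_id"].map(
        dict(zip(sig["element_id"], sig["H3K27ac"]))
    ).fillna(1.0)
    tab = ElementTable(df)
    ep = features.ep_candidates(tab, window_bp=5_000_000)
    ep = features.attach_contact(ep, cmap)
    return tab, cmap, ep


class TestABC:
    def test_hand_normalized_product(self):
        tab, cmap, ep = _one_tss_setup([0.3, 0.1], [2.0, 1.0])
        score = features.abc_score(ep, tab)
        by_enh = dict(zip(ep["enhancer_id"], score))
        assert by_enh["e0"] == pytest.approx(0.6 / 0.7)
        assert by_enh["e1"] == pytest.approx(0.1 / 0.7)
        assert score.sum() == pytest.approx(1.0)

    def test_single_candidate_scores_one(self):
        tab, cmap, ep = _one_tss_setup([0.5], [3.0])
        assert features.abc_score(ep, tab).iloc[0] == pytest.approx(1.0)

    def test_all_zero_contacts_give_zero_scores(self):
        tab, cmap, ep = _one_tss_setup([0.0, 0.0], [2.0, 1.0])
        assert (features.abc_score(ep, tab) == 0).all()

    def test_per_tss_normalization_on_simulated_data(self, tiny_sim):
        ep = tiny_sim.ep
        score = features.abc_score(ep, tiny_sim.elements)
        sums = score.groupby(ep["tss_id"].to_numpy()).sum()
        nonzero = sums[sums > 0]
        assert np.allclose(nonzero, 1.0)

    def test_negative_activity_rejected(self):
        tab, cmap, ep = _one_tss_setup([0.3], [2.0])
        tab.df.loc[tab.df["kind"] == "enhancer", "H3K27ac"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            features.abc_score(ep, tab)


class TestRelativeContact:
    def test_hand_ranking_three_enhancers(self):
        tab, cmap, ep = _one_tss_setup([0.5, 0.3, 0.1], [1, 1, 1])
        rel = features.contact_relative_features(ep)
        focal = rel.loc[ep["enhancer_id"] == "e1"].iloc[0]
        assert focal["diff.from.max.contact.to.TSS"] == pytest.approx(0.2)
        assert focal["contact.rank.to.TSS"] == 2

    def test_focal_maximum_has_zero_diff(self):
        tab, cmap, ep = _one_tss_setup([0.5, 0.3], [1, 1])
        rel = features.contact_relative_features(ep)
        best = rel.loc[ep["enhancer_id"] == "e0"].iloc[0]
        assert best["diff.from.max.contact.to.TSS"] == 0.0
        assert best["contact.rank.to.TSS"] == 1

    def test_singleton_neighborhood(self):
        tab, cmap, ep = _one_tss_setup([0.4], [1])
        rel = features.contact_relative_features(ep)
        assert rel["diff.from.max.contact.to.TSS"].iloc[0] == 0.0
        assert rel["contact.rank.to.TSS"].iloc[0] == 1

    def test_diffs_nonnegative_and_ranks_positive(self, tiny_sim):
        rel = features.contact_relative_features(tiny_sim.ep)
        for col in rel.columns:
            if col.startswith("diff."):
                assert (rel[col] >= 0).all()
            if col.startswith("contact.rank"):
                assert (rel[col] >= 1).all()


class TestRemainingSums:
    def test_hand_sum_excluding_focal(self):
        """Enhancer contacting three TSSs: remaining sum drops the focal."""
        rows = [("chr1", 1_000_000, 1_001_000, "e0", "enhancer")]
        for i, pos in enumerate([1_100_000, 1_200_000, 1_300_000]):
            rows.append(("chr1", pos, pos + 1, f"p{i + 1}", "tss"))
        tab = _elements(rows)
        cmap = ContactMap(bin_size=5000)
        e_bin = 1_000_500 // 5000
        for pos, c in zip([1_100_000, 1_200_000, 1_300_000], [0.3, 0.2, 0.05]):
            cmap.add("chr1", e_bin, pos // 5000, c)
        ep = features.attach_contact(features.ep_candidates(tab), cmap)
        rem = features.remaining_contact_sums(ep)
        focal = rem.loc[ep["tss_id"] == "p1"].iloc[0]
        assert focal["remaining.TSS.contact.from.enhancer"] == pytest.approx(0.25)

    def test_no_other_tss_gives_zero(self):
        tab, cmap, ep = _one_tss_setup([0.4], [1])
        rem = features.remaining_contact_sums(ep)
        assert rem["remaining.TSS.contact.from.enhancer"].iloc[0] == 0.0

    def test_row_order_invariance(self, tiny_sim):
        ep = tiny_sim.ep
        shuffled = ep.sample(frac=1, random_state=0)
        r1 = features.remaining_contact_sums(ep)
        r2 = features.remaining_contact_sums(shuffled).loc[r1.index]
        pd.testing.assert_frame_equal(r1, r2)


class TestDensity:
    def test_hand_count_within_half_window(self):
        rows = [("chr1", 10_000_000, 10_000_001, "p1", "tss")]
        for i, pos in enumerate([8_000_000, 12_000_000, 16_000_000]):
            rows.append(("chr1", pos, pos + 500, f"e{i}", "enhancer"))
        tab = _elements(rows)
        ep = features.ep_candidates(tab, window_bp=5_000_000)
        dens = features.density_counts(ep, tab, window_bp=5_000_000)
        assert (dens["Enhancer.count.near.TSS"] == 2).all()

    def test_focal_side_minimum_is_one(self, tiny_sim):
        dens = features.density_counts(tiny_sim.ep, tiny_sim.elements)
        assert dens["Enhancer.count.near.TSS"].min() >= 1
        assert dens["TSS.count.near.enhancer"].min() >= 1

    def test_counts_monotone_in_window(self, tiny_sim):
        small = features.density_counts(tiny_sim.ep, tiny_sim.elements, 2_000_000)
        large = features.density_counts(tiny_sim.ep, tiny_sim.elements, 5_000_000)
        assert (large["Enhancer.count.near.TSS"] >= small["Enhancer.count.near.TSS"]).all()


class TestTFPresence:
    def _setup(self):
        tab = _elements(
            [
                ("chr1", 150, 250, "e1", "enhancer"),
                ("chr1", 5_000, 5_001, "p1", "tss"),
            ]
        )
        ep = features.ep_candidates(tab, window_bp=1_000_000)
        return tab, ep

    def test_overlap_and_halfopen_abutment(self):
        tab, ep = self._setup()
        overlapping = {"TFA": pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})}
        abutting = {"TFA": pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [150]})}
        assert features.tf_presence(ep, overlapping, tab)["TFA_e"].iloc[0] == 1
        assert features.tf_presence(ep, abutting, tab)["TFA_e"].iloc[0] == 0

    def test_tss_flank_arithmetic(self):
        tab, ep = self._setup()
        near = {"TFA": pd.DataFrame({"chrom": ["chr1"], "start": [5_400], "end": [5_401]})}
        out = features.tf_presence(ep, near, tab, tss_flank_bp=500)
        assert out["TFA_TSS"].iloc[0] == 1
        out0 = features.tf_presence(ep, near, tab, tss_flank_bp=100)
        assert out0["TFA_TSS"].iloc[0] == 0

    def test_duplicate_tf_names_rejected(self, tiny_sim):
        presence = tiny_sim.tf_presence.copy()
        presence.columns = ["TFX"] * len(presence.columns)
        with pytest.raises(ValueError, match="duplicate"):
            features.tf_presence_from_matrix(tiny_sim.ep, presence)


class TestLabeling:
    @pytest.mark.parametrize(
        "adj_p,direction,expected",
        [(0.05, "down", 1), (0.05, "up", 0), (0.5, "down", 0), (0.099, "down", 1)],
    )
    def test_label_rule(self, adj_p, direction, expected):
        ep = pd.DataFrame(
            {
                "enhancer_id": ["e1"],
                "tss_id": ["p1"],
                "adj_p": [adj_p],
                "effect_direction": [direction],
            }
        )
        assert features.label_positives(ep)["label"].iloc[0] == expected

    def test_missing_adj_p_row_dropped(self):
        ep = pd.DataFrame(
            {
                "enhancer_id": ["e1", "e2"],
                "tss_id": ["p1", "p1"],
                "adj_p": [np.nan, 0.05],
                "effect_direction": ["down", "down"],
            }
        )
        out = features.label_positives(ep)
        assert list(out["enhancer_id"]) == ["e2"]

    def test_invalid_alpha_rejected(self):
        ep = pd.DataFrame(
            {"enhancer_id": [], "tss_id": [], "adj_p": [], "effect_direction": []}
        )
        with pytest.raises(ValueError):
            features.label_positives(ep, alpha_label=1.5)


class TestAssembly:
    def test_expected_families_present(self, tiny_features, tiny_config):
        fams = tiny_features.families()
        assert len(fams["histone"]) == 6
        assert fams["expression"] == ["TargetGeneExpression"]
        assert fams["distance"] == ["distance"]
        assert fams["contact"] == ["hic_contact"]
        assert len(fams["relative"]) >= 4
        assert len(fams["density"]) == 2
        assert len(fams["tf"]) == 2 * tiny_config.n_tf
        assert len(fams["nmf"]) == 24  # k = 12 per side

    def test_conflicting_column_names_rejected(self, tiny_sim):
        ep = tiny_sim.ep
        f = pd.DataFrame({"x": np.zeros(len(ep))}, index=ep.index)
        with pytest.raises(ValueError, match="conflicting"):
            features.assemble_features(ep, {"distance": f, "contact": f.copy()})

    def test_missing_values_rejected(self, tiny_sim):
        ep = tiny_sim.ep
        f = pd.DataFrame({"x": np.full(len(ep), np.nan)}, index=ep.index)
        with pytest.raises(ValueError, match="missing"):
            features.assemble_features(ep, {"distance": f})


class TestOracleEquivalence:
    def test_all_features_match_naive_loops(self):
        """Production (vectorized) features equal the brute-force oracle
        on small instances."""
        for seed in (0, 1):
            cfg = tiny_sim_config(
                n_chrom=1,
                chrom_length_bp=6_000_000,
                n_enhancers=30,
                n_tss=10,
                seed=40 + seed,
            )
            sd = pipeline.simulate_dataset(cfg)
            oracle = naive_feature_table(sd.elements, sd.contacts, cfg.window_bp)
            ep = sd.ep
            prod = pd.concat(
                [
                    ep[["enhancer_id", "tss_id", "distance", "hic_contact"]].reset_index(
                        drop=True
                    ),
                    features.abc_score(ep, sd.elements).reset_index(drop=True),
                    features.contact_relative_features(ep).reset_index(drop=True),
                    features.remaining_contact_sums(ep).reset_index(drop=True),
                    features.density_counts(ep, sd.elements, cfg.window_bp).reset_index(
                        drop=True
                    ),
                ],
                axis=1,
            )
            assert len(prod) == len(oracle)
            merged = prod.merge(
                oracle, on=["enhancer_id", "tss_id"], suffixes=("", "_oracle")
            )
            assert len(merged) == len(prod)
            for col in [
                "distance",
                "hic_contact",
                "abc_score",
                "max.contact.to.TSS",
                "diff.from.max.contact.to.TSS",
                "contact.rank.to.TSS",
                "max.contact.from.enhancer",
                "diff.from.max.contact.from.enhancer",
                "contact.rank.from.enhancer",
                "remaining.enhancers.contact.to.TSS",
                "remaining.TSS.contact.from.enhancer",
                "Enhancer.count.near.TSS",
                "TSS.count.near.enhancer",
            ]:
                assert np.allclose(
                    merged[col], merged[f"{col}_oracle"], rtol=1e-9, atol=1e-12
                ), col
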