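"""LD collapsing, cis/trans labelling, level combination and SR/MR merging."""

import numpy as np
import pandas as pd
import pytest

from mreqtl.postprocess import (
    ClassifierConfig,
    GenotypePanel,
    bin_frequencies,
    classify_cis_trans,
    collapse_redundant,
    combine_levels,
    identify_sr_mr,
)

CUTOFF = int(10**6.5)  # 3,162,277 (floor)


def make_panel(columns: dict) -> GenotypePanel:
    return GenotypePanel(pd.DataFrame(columns, dtype=float))


def correlated_column(rng, base, r_target):
    """Construct a dosage-like column with roughly the target correlation."""
    noise = rng.normal(0, 1, len(base))
    mix = r_target * (base - base.mean()) / base.std() + np.sqrt(1 - r_target**2) * noise
    return np.round(np.clip(mix + 1, 0, 2))


class TestCollapse:
    snp_map = pd.DataFrame(
        {
            "id": ["s1", "s2", "s3"],
            "chromosome": ["1", "1", "1"],
            "position": [100, 200, 300],
        }
    )

    def test_single_record_is_its_own_block(self, rng):
        panel = make_panel({"s1": rng.binomial(2, 0.5, 50)})
        rec = pd.DataFrame({"snp_id": ["s1"], "feature_id": ["f"], "p": [1e-8]})
        out, blocks = collapse_redundant(rec, panel, self.snp_map)
        assert len(out) == 1 and len(blocks) == 1
        assert blocks.iloc[0]["members"] == ("s1",)

    def test_perfect_ld_keeps_smaller_p(self, rng):
        g = rng.binomial(2, 0.5, 60).astype(float)
        panel = make_panel({"s1": g, "s2": g})  # R^2 = 1
        rec = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "feature_id": ["f", "f"], "p": [1e-6, 1e-9]}
        )
        out, _ = collapse_redundant(rec, panel, self.snp_map)
        assert len(out) == 1
        assert out.iloc[0]["snp_id"] == "s2"  # the more significant one

    def test_chain_break_at_low_r2(self):
        # constructed dosage columns: r2(s1, s2) high, r2(s2, s3) low;
        # verified against a brute-force correlation oracle
        rng = np.random.default_rng(99)
        s1 = np.asarray(rng.binomial(2, 0.5, 4000), dtype=float)
        s2 = s1.copy()
        flip = rng.random(4000) < 0.05
        s2[flip] = rng.binomial(2, 0.5, int(flip.sum()))
        s3 = correlated_column(rng, s1, 0.55)
        panel = make_panel({"s1": s1, "s2": s2, "s3": s3})
        r2_12 = np.corrcoef(s1, s2)[0, 1] ** 2
        r2_23 = np.corrcoef(s2, s3)[0, 1] ** 2
        assert r2_12 > 0.5 and r2_23 < 0.5  # oracle check of the construction
        rec = pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3"],
                "feature_id": ["f"] * 3,
                "p": [1e-9, 1e-7, 1e-8],
            }
        )
        out, blocks = collapse_redundant(rec, panel, self.snp_map)
        assert len(out) == 2
        assert tuple(blocks["members"]) == (("s1", "s2"), ("s3",))
        assert set(out["snp_id"]) == {"s1", "s3"}  # best p of each block

    def test_collapse_never_increases_and_keeps_min_p(self, rng):
        g = rng.binomial(2, 0.5, (80, 3)).astype(float)
        panel = make_panel({f"s{i+1}": g[:, i] for i in range(3)})
        rec = pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3"],
                "feature_id": ["f"] * 3,
                "p": [0.5e-8, 1e-8, 2e-8],
            }
        )
        out, blocks = collapse_redundant(rec, panel, self.snp_map)
        assert len(out) <= len(rec)
        for _, block in blocks.iterrows():
            members = block["members"]
            best = rec[rec.snp_id.isin(members)].p.min()
            rep_p = out[out.snp_id == block["representative"]].p.iloc[0]
            assert rep_p == best

    def test_unknown_snp_is_error(self, rng):
        panel = make_panel({"s1": rng.binomial(2, 0.5, 10)})
        rec = pd.DataFrame({"snp_id": ["sX"], "feature_id": ["f"], "p": [0.1]})
        with pytest.raises(KeyError):
            collapse_redundant(rec, panel, self.snp_map)


class TestCisTrans:
    def test_zero_distance_is_cis(self):
        assert classify_cis_trans(["1"], [500], ["1"], [500])[0] == "cis"

    def test_other_chromosome_is_trans(self):
        assert classify_cis_trans(["1"], [500], ["2"], [500])[0] == "trans"

    def test_exact_cutoff_boundary(self):
        # 10^6.5 = 3,162,277.66: distance 3,162,277 is inside, 3,162,278 out
        lab = classify_cis_trans(
            ["1", "1"], [1, 1], ["1", "1"], [1 + 3_162_277, 1 + 3_162_278]
        )
        assert list(lab) == ["cis", "trans"]

    def test_partition_total_and_exclusive(self, rng):
        n = 200
        chroms = rng.choice(["1", "2"], n)
        lab = classify_cis_trans(
            chroms, rng.integers(1, 10**7, n), rng.choice(["1", "2"], n),
            rng.integers(1, 10**7, n),
        )
        assert set(lab) <= {"cis", "trans"}


class TestCombineLevels:
    annotation = pd.DataFrame(
        {
            "feature_id": ["T1", "T2", "e1", "e3"],
            "level": ["transcript", "transcript", "exon", "exon"],
            "transcript_cluster_id": ["T1", "T2", "T1", "T2"],
            "chromosome": ["1"] * 4,
            "start": [100, 5000, 100, 5000],
            "end": [200, 6000, 150, 5100],
        }
    )

    def base(self, rng):
        g1 = rng.binomial(2, 0.5, 100).astype(float)
        g2 = rng.binomial(2, 0.5, 100).astype(float)
        return make_panel({"h1": g1, "h2": g2, "h3": rng.binomial(2, 0.5, 100)})

    def test_both_label_when_exon_shares_haplotype(self, rng):
        panel = self.base(rng)
        tr = pd.DataFrame({"snp_id": ["h1"], "feature_id": ["T1"], "p": [1e-9]})
        ex = pd.DataFrame({"snp_id": ["h1"], "feature_id": ["e1"], "p": [1e-8]})
        out = combine_levels(tr, ex, self.annotation, panel)
        assert set(out.level_class) == {"both"}

    def test_transcript_only_without_exon_support(self, rng):
        panel = self.base(rng)
        tr = pd.DataFrame({"snp_id": ["h2"], "feature_id": ["T2"], "p": [1e-9]})
        ex = pd.DataFrame(columns=["snp_id", "feature_id", "p"])
        out = combine_levels(tr, ex, self.annotation, panel)
        assert list(out.level_class) == ["transcript_only"]

    def test_exon_only_without_transcript_eqtl(self, rng):
        panel = self.base(rng)
        tr = pd.DataFrame(columns=["snp_id", "feature_id", "p"])
        ex = pd.DataFrame({"snp_id": ["h3"], "feature_id": ["e3"], "p": [1e-7]})
        out = combine_levels(tr, ex, self.annotation, panel)
        assert list(out.level_class) == ["exon_only"]

    def test_different_haplotype_not_both(self, rng):
        panel = self.base(rng)  # h1 and h2 independent
        tr = pd.DataFrame({"snp_id": ["h1"], "feature_id": ["T1"], "p": [1e-9]})
        ex = pd.DataFrame({"snp_id": ["h2"], "feature_id": ["e1"], "p": [1e-8]})
        out = combine_levels(tr, ex, self.annotation, panel)
        got = dict(zip(out.feature_id, out.level_class))
        assert got == {"T1": "transcript_only", "e1": "exon_only"}

    def test_unmapped_exon_is_error(self, rng):
        panel = self.base(rng)
        tr = pd.DataFrame({"snp_id": ["h1"], "feature_id": ["T1"], "p": [1e-9]})
        ex = pd.DataFrame({"snp_id": ["h1"], "feature_id": ["eX"], "p": [1e-8]})
        with pytest.raises(KeyError):
            combine_levels(tr, ex, self.annotation, panel)


def records_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["region", "level", "feature_id", "snp_id", "beta", "p", "cis_trans"],
    )


class TestSrMr:
    def test_single_region_all_sr(self, rng):
        panel = make_panel({"s1": rng.binomial(2, 0.5, 40)})
        rec = records_frame([("CRBL", "transcript", "T1", "s1", 1.0, 1e-9, "cis")])
        res = identify_sr_mr(rec, panel)
        assert list(res.entities.sr_mr) == ["SR"]

    def test_linked_records_merge_across_regions(self, rng):
        g = rng.binomial(2, 0.5, 40).astype(float)
        panel = make_panel({"s1": g, "s2": g})  # R^2 = 1
        rec = records_frame(
            [
                ("A", "transcript", "T1", "s1", 1.0, 1e-9, "cis"),
                ("B", "transcript", "T1", "s2", 1.1, 1e-8, "cis"),
            ]
        )
        res = identify_sr_mr(rec, panel)
        e = res.entities.iloc[0]
        assert len(res.entities) == 1
        assert e.sr_mr == "MR" and e.n_regions == 2
        freq = res.frequency_table("transcript")
        assert freq.cumulative_eqtls.sum() == 2  # one MR-eQTL, two eQTLs

    def test_unlinked_records_stay_separate(self, rng):
        panel = make_panel(
            {"s1": rng.binomial(2, 0.5, 60), "s2": rng.binomial(2, 0.5, 60)}
        )
        rec = records_frame(
            [
                ("A", "transcript", "T1", "s1", 1.0, 1e-9, "cis"),
                ("B", "transcript", "T1", "s2", 1.1, 1e-8, "cis"),
            ]
        )
        res = identify_sr_mr(rec, panel)
        assert len(res.entities) == 2
        assert set(res.entities.sr_mr) == {"SR"}

    def test_frequency_identity_and_sharing_bounds(self, default_outcome):
        ent = default_outcome.srmr.entities
        rec = default_outcome.catalogue
        for level in ("transcript", "exon"):
            freq = default_outcome.frequency_tables[level]
            total_records = (rec.level == level).sum()
            assert freq.cumulative_eqtls.sum() == total_records
            mat = default_outcome.sharing_matrices[level]
            assert (mat.values == mat.values.T).all()
            totals = rec[rec.level == level].groupby("region").size()
            for a in mat.index:
                for b in mat.columns:
                    if a != b and a in totals.index and b in totals.index:
                        assert mat.loc[a, b] <= min(totals[a], totals[b])

    def test_sr_mr_partition(self, default_outcome):
        ent = default_outcome.srmr.entities
        assert ((ent.sr_mr == "SR") == (ent.n_regions == 1)).all()
        assert len(ent) == (ent.sr_mr == "SR").sum() + (ent.sr_mr == "MR").sum()


class TestBins:
    def test_hand_counted_multiplicities(self):
        rows = []
        # haplotype multiplicities {1, 1, 3, 11} for one region/level
        for h, k in (("h1", 1), ("h2", 1), ("h3", 3), ("h4", 11)):
            for j in range(k):
                rows.append(("A", "transcript", f"f{h}_{j}", h, 1.0, 1e-9, "cis"))
        out = bin_frequencies(records_frame(rows), "features_per_haplotype")
        row = out.iloc[0]
        assert (row["bin_1"], row["bin_2-5"], row["bin_6-10"], row["bin_>10"]) == (2, 1, 0, 1)
        assert row["max"] == 11

    def test_seven_features_in_6_10_bin(self):
        rows = [("A", "exon", f"f{j}", "h1", 1.0, 1e-9, "cis") for j in range(7)]
        out = bin_frequencies(records_frame(rows), "features_per_haplotype")
        assert out.iloc[0]["bin_6-10"] == 1 and out.iloc[0]["max"] == 7

    def test_haplotypes_per_feature_axis(self):
        rows = [("A", "exon", "f1", f"h{j}", 1.0, 1e-9, "cis") for j in range(3)]
        out = bin_frequencies(records_frame(rows), "haplotypes_per_feature")
        assert out.iloc[0]["bin_2-5"] == 1

    def test_empty_input(self):
        out = bin_frequencies(records_frame([]), "features_per_haplotype")
        assert out.empty

    def test_bad_axis(self):
        with pytest.raises(ValueError):
            bin_frequencies(records_frame([]), "sideways")
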