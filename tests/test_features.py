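from collections import Counter

import numpy as np
import pytest

from clonoscope import (EmbedParams, FeatureMatrix, FeatureSpec,
                        build_feature_matrix, embed, one_hot_vdj,
                        pair_chains, plot_feature)

from test_clonotype import _airr, _row


class TestOneHotVdj:
    def test_allele_stripped_and_other_loci_zero(self):
        rows = [_row("c1", "TRA", v="TRAV3*01", j="TRAJ2*01"),
                _row("c1", "TRB", v="TRBV19*01", d="TRBD1*01", j="TRBJ5*01"),
                _row("c2", "TRG", v="TRGV2*01", j="TRGJ1*01"),
                _row("c2", "TRD", v="TRDV1*01", d="TRDD3*01", j="TRDJ2*01")]
        paired, _ = pair_chains(_airr(rows))
        block, names = one_hot_vdj(paired)
        assert "TRBV:TRBV19" in names
        assert not any("*" in n for n in names)
        ab_row = block[[pc.tcr_type == "AB" for pc in paired].index(True)]
        for j, name in enumerate(names):
            if name.startswith(("TRG", "TRD")):
                assert ab_row[j] == 0.0
        assert ab_row[names.index("TRBV:TRBV19")] == 1.0

    def test_gd_only_dataset_has_no_ab_columns(self):
        rows = [_row("c1", "TRG", v="TRGV2*01", j="TRGJ1*01"),
                _row("c1", "TRD", v="TRDV1*01", j="TRDJ2*01")]
        paired, _ = pair_chains(_airr(rows))
        _, names = one_hot_vdj(paired)
        assert names and not any(n.startswith(("TRA", "TRB")) for n in names)

    def test_column_sums_equal_gene_usage_tally(self, paired_default):
        paired, _ = paired_default
        block, names = one_hot_vdj(paired)
        tally = Counter()
        for pc in paired:
            for chain in (pc.chain_1, pc.chain_2):
                for slot, call in (("V", chain.v_call), ("D", chain.d_call),
                                   ("J", chain.j_call)):
                    gene = call.split(",")[0].split("*")[0].strip()
                    if gene:
                        tally[f"{chain.locus}{slot}:{gene}"] += 1
        sums = dict(zip(names, block.sum(axis=0)))
        assert sums == {k: float(v) for k, v in tally.items()}


class TestBuildFeatureMatrix:
    def test_block_contracts(self, pipeline_state, sim_default):
        norm, paired, counts = pipeline_state
        spec = FeatureSpec(markers=("CD4", "CD8A", "NKG7", "FOXP3"))
        fm = build_feature_matrix(norm, paired, counts, spec)

        # block arithmetic: markers + count + tags + clonotypes + type + vdj
        n_tags = len({t for t in norm.sample_tags})
        prov = Counter(fm.provenance)
        assert prov["marker"] == 4
        assert prov["count"] == 1
        assert prov["sample_tag"] == n_tags
        assert prov["tcr_type"] == 1
        assert len(fm.feature_names) == sum(prov.values())

        # one-hot row sums
        values = fm.values
        for tag_block in ("sample_tag", "clonotype"):
            cols = [j for j, p in enumerate(fm.provenance) if p == tag_block]
            np.testing.assert_array_equal(values[:, cols].sum(axis=1),
                                          np.ones(len(fm.cell_ids)))

        # tcr_type is the αβ indicator
        type_of = {pc.cell_id: pc.tcr_type for pc in paired}
        col = fm.column("tcr-type")
        expected = np.array([1.0 if type_of[c] == "AB" else 0.0
                             for c in fm.cell_ids])
        np.testing.assert_array_equal(col, expected)

    def test_dominant_clone_count_feature(self, pipeline_state, sim_default):
        norm, paired, counts = pipeline_state
        fm = build_feature_matrix(norm, paired, counts, FeatureSpec())
        truth = sim_default.truth
        dom_cells = set(
            truth.cells.loc[(truth.cells["clonotype_contig"]
                             == truth.dominant_contig)
                            & ~truth.cells["is_unpaired"], "cell_id"])
        col = fm.column("clonotype-count")
        got = {c: v for c, v in zip(fm.cell_ids, col) if c in dom_cells}
        assert set(got.values()) == {float(truth.dominant_n_cells)}

    def test_unresolvable_marker_named(self, pipeline_state):
        norm, paired, counts = pipeline_state
        with pytest.raises(KeyError, match="NOPE"):
            build_feature_matrix(norm, paired, counts,
                                 FeatureSpec(markers=("NOPE",)))

    def test_small_clonotypes_share_singleton_column(self, pipeline_state):
        norm, paired, counts = pipeline_state
        fm = build_feature_matrix(norm, paired, counts,
                                  FeatureSpec(clonotype_min_cells=2))
        singleton = fm.column("clonotype:singleton")
        size_of = dict(zip(counts["contig"], counts["n_cells"]))
        expected = np.array([
            1.0 if size_of[pc.clonotype_contig] < 2 else 0.0
            for pc in paired if pc.cell_id in set(fm.cell_ids)])
        np.testing.assert_array_equal(singleton, expected)


@pytest.fixture(scope="module")
def small_features(pipeline_state):
    norm, paired, counts = pipeline_state
    return build_feature_matrix(norm, paired, counts,
                                FeatureSpec(markers=("CD8A",)))


class TestEmbed:
    def test_too_few_cells_rejected(self, small_features):
        tiny = FeatureMatrix(cell_ids=small_features.cell_ids[:5],
                             feature_names=small_features.feature_names,
                             values=small_features.values[:5],
                             provenance=small_features.provenance)
        with pytest.raises(ValueError, match="at least"):
            embed(tiny, EmbedParams())

    def test_seeded_rerun_identical(self, small_features):
        p = EmbedParams(umap_neighbors=10, hdbscan_min_cluster_size=5)
        a = embed(small_features, p)
        b = embed(small_features, p)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.cluster_labels, b.cluster_labels)

    def test_constant_feature_has_no_effect(self, small_features):
        """Standardization zeroes a zero-variance column, so adding one
        leaves the embedding unchanged."""
        p = EmbedParams(umap_neighbors=10, hdbscan_min_cluster_size=5)
        base = embed(small_features, p)
        padded = FeatureMatrix(
            cell_ids=small_features.cell_ids,
            feature_names=small_features.feature_names + ["const"],
            values=np.hstack([small_features.values,
                              np.full((len(small_features.cell_ids), 1), 7.0)]),
            provenance=small_features.provenance + ["marker"],
        )
        again = embed(padded, p)
        np.testing.assert_allclose(base.coords, again.coords)

    def test_plot_feature_binary_and_continuous(self, small_features, tmp_path):
        p = EmbedParams(umap_neighbors=10, hdbscan_min_cluster_size=5)
        emb = embed(small_features, p)
        out1 = plot_feature(emb, small_features.column("tcr-type"),
                            tmp_path / "type.png", title="TCR type")
        out2 = plot_feature(emb, small_features.column("clonotype-count"),
                            tmp_path / "count.png")
        assert out1.stat().st_size > 0 and out2.stat().st_size > 0

    def test_length_mismatch_rejected(self, small_features, tmp_path):
        p = EmbedParams(umap_neighbors=10, hdbscan_min_cluster_size=5)
        emb = embed(small_features, p)
        with pytest.raises(ValueError):
            plot_feature(emb, np.zeros(3), tmp_path / "x.png")
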