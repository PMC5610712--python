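"""Core concatenation, gap stripping, SNP distances, NJ and bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

import strainpan as sp
from strainpan.phylogeny import (
    CoreAlignment,
    bipartitions,
    mafft_align,
    passthrough_align,
)


def _family_set(members_by_family, gene_strain):
    fams = sp.OrthologFamilySet(gene_strain=gene_strain)
    for fid, members in members_by_family.items():
        fams.families[fid] = set(members)
    return fams


class TestConcatenateCore:
    def test_blocks_in_identical_sorted_order(self):
        gene_strain = {f"{s}_{f}": s for s in ("a", "b") for f in ("f1", "f2", "f3")}
        fams = _family_set(
            {f: [f"a_{f}", f"b_{f}"] for f in ("f1", "f2", "f3")}, gene_strain
        )
        seqs = {g: "M" * (10 + i) for i, g in enumerate(sorted(gene_strain))}
        aln = sp.concatenate_core(fams, ["a", "b"], seqs)
        assert [b[0] for b in aln.blocks] == ["f1", "f2", "f3"]
        assert set(aln.sequences) == {"a", "b"}

    def test_multicopy_family_excluded(self):
        gene_strain = {"a_f1": "a", "b_f1": "b", "a_f2": "a", "a_f2x": "a", "b_f2": "b"}
        fams = _family_set(
            {"f1": ["a_f1", "b_f1"], "f2": ["a_f2", "a_f2x", "b_f2"]}, gene_strain
        )
        seqs = {g: "MKV" for g in gene_strain}
        aln = sp.concatenate_core(fams, ["a", "b"], seqs)
        assert [b[0] for b in aln.blocks] == ["f1"]

    def test_family_missing_from_one_strain_excluded(self):
        gene_strain = {"a_f1": "a", "b_f1": "b", "a_f2": "a"}
        fams = _family_set({"f1": ["a_f1", "b_f1"], "f2": ["a_f2"]}, gene_strain)
        aln = sp.concatenate_core(fams, ["a", "b"], {g: "MKV" for g in gene_strain})
        assert [b[0] for b in aln.blocks] == ["f1"]

    def test_simulated_panel_concatenation_length(self, small_panel, small_panel_families):
        config, panel, truth = small_panel
        families, _matrix = small_panel_families
        proteins = {g.gene_id: g.protein for s in panel for g in s.genes.values()}
        aln = sp.concatenate_core(families, panel.strain_ids, proteins)
        assert len(aln.blocks) == config.n_core
        # star-wise simulation keeps family copies equal length: valid alignment
        assert aln.gap_free
        lengths = {len(s) for s in aln.sequences.values()}
        assert lengths == {sum(b[2] - b[1] for b in aln.blocks)}


class TestStripGapColumns:
    def test_gapless_alignment_unchanged(self):
        aln = CoreAlignment({"a": "ACGT", "b": "ACGA"})
        out = sp.strip_gap_columns(aln)
        assert out.sequences == aln.sequences and out.gap_free

    def test_forced_example(self):
        aln = CoreAlignment({"x": "AC-GT", "y": "ACCGT", "z": "AC-GT"})
        out = sp.strip_gap_columns(aln)
        assert out.sequences == {"x": "ACGT", "y": "ACGT", "z": "ACGT"}

    def test_matches_brute_force_column_filter(self, rng):
        chars = np.asarray(list("ACGT-"))
        rows = ["".join(chars[rng.integers(0, 5, 40)]) for _ in range(4)]
        aln = CoreAlignment(dict(zip("abcd", rows)))
        out = sp.strip_gap_columns(aln)
        keep = [
            i for i in range(40) if all(r[i] != "-" for r in rows)
        ]
        for name, row in zip("abcd", rows):
            assert out.sequences[name] == "".join(row[i] for i in keep)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            sp.strip_gap_columns(CoreAlignment({"a": "ACGT", "b": "ACG"}))


class TestSnpDistance:
    def test_identical_and_single_difference(self):
        aln = CoreAlignment({"a": "AAAA", "b": "AAAT", "c": "aaaa"}, gap_free=True)
        mat = sp.snp_distance(aln).df
        assert mat.loc["a", "c"] == 0      # case-insensitive
        assert mat.loc["a", "b"] == 1

    def test_matches_brute_force_double_loop(self, rng):
        chars = np.asarray(list("ACGT"))
        names = list("abcd")
        rows = {n: "".join(chars[rng.integers(0, 4, 60)]) for n in names}
        mat = sp.snp_distance(CoreAlignment(rows, gap_free=True)).df
        for i, j in itertools.combinations(names, 2):
            brute = sum(x != y for x, y in zip(rows[i], rows[j]))
            assert mat.loc[i, j] == brute == mat.loc[j, i]

    def test_metric_properties(self, rng):
        chars = np.asarray(list("ACGT"))
        rows = {f"s{i}": "".join(chars[rng.integers(0, 4, 50)]) for i in range(5)}
        mat = sp.snp_distance(CoreAlignment(rows, gap_free=True)).df.to_numpy()
        assert (mat == mat.T).all() and (np.diag(mat) == 0).all()
        n = mat.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert mat[i, j] <= mat[i, k] + mat[k, j]

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError):
            sp.snp_distance(CoreAlignment({"a": "A-G", "b": "AAG"}))


class TestDistanceTree:
    def test_two_taxa_split_distance_evenly(self):
        df = pd.DataFrame([[0.0, 6.0], [6.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree = sp.distance_tree(df)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 3.0, "b": 3.0}

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # generating tree: ((A:2,B:3):1,(C:4,D:5))
        labels = list("ABCD")
        d = pd.DataFrame(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = sp.distance_tree(d)
        parts = bipartitions(tree)
        assert parts == {
            frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        }
        # leaf-to-leaf path lengths reproduce the additive matrix
        for i, j in itertools.combinations(labels, 2):
            ti, tj = tree.find(i), tree.find(j)
            assert ti.distance(tj) == pytest.approx(d.loc[i, j])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)

    def test_ultrametric_three_taxa_siblings(self):
        labels = list("abc")
        d = pd.DataFrame(
            [[0, 2, 8], [2, 0, 8], [8, 8, 0]], index=labels, columns=labels, dtype=float
        )
        tree = sp.distance_tree(d)
        pair = {t.name for t in tree.find("a").parent.tips()}
        assert pair == {"a", "b"} or len(pair) == 3  # star only if collapsed

    def test_nan_rejected(self):
        df = pd.DataFrame(
            [[0.0, np.nan], [np.nan, 0.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError):
            sp.distance_tree(df)


class TestBootstrap:
    def test_identical_sequences_give_star_with_no_supports(self):
        aln = CoreAlignment({f"s{i}": "ACGT" * 20 for i in range(5)}, gap_free=True)
        result = sp.bootstrap_tree(aln, n_replicates=10, seed=0)
        assert result.supports == {}
        assert bipartitions(result.tree) == set()

    def test_planted_bipartition_fully_supported(self, rng):
        chars = np.asarray(list("ACGT"))
        clade1, clade2 = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        diag = {s: "A" * 100 for s in clade1} | {s: "C" * 100 for s in clade2}
        noise = {
            s: "".join(chars[rng.integers(0, 4, 20)]) for s in clade1 + clade2
        }
        aln = CoreAlignment(
            {s: diag[s] + noise[s] for s in clade1 + clade2}, gap_free=True
        )
        result = sp.bootstrap_tree(aln, n_replicates=50, seed=3)
        key = frozenset({frozenset(clade1), frozenset(clade2)})
        assert result.supports[key] == 100.0

    def test_same_seed_reproduces_supports(self, rng):
        chars = np.asarray(list("ACGT"))
        aln = CoreAlignment(
            {f"s{i}": "".join(chars[rng.integers(0, 4, 120)]) for i in range(5)},
            gap_free=True,
        )
        r1 = sp.bootstrap_tree(aln, n_replicates=30, seed=7)
        r2 = sp.bootstrap_tree(aln, n_replicates=30, seed=7)
        assert r1.supports == r2.supports

    def test_invalid_replicate_count_rejected(self):
        aln = CoreAlignment({f"s{i}": "ACGT" for i in range(4)}, gap_free=True)
        with pytest.raises(ValueError):
            sp.bootstrap_tree(aln, n_replicates=0, seed=0)


class TestRootTree:
    def _support_tree(self, rng, names):
        chars = np.asarray(list("ACGT"))
        aln = CoreAlignment(
            {n: "".join(chars[rng.integers(0, 4, 150)]) for n in names}, gap_free=True
        )
        return sp.bootstrap_tree(aln, n_replicates=10, seed=1)

    def test_outgroup_becomes_sister_to_rest(self, rng):
        st = self._support_tree(rng, [f"s{i}" for i in range(5)])
        rooted = sp.root_tree(st, "s3")
        children = rooted.tree.children
        sides = [{t.name for t in c.tips()} or {c.name} for c in children]
        assert {"s3"} in sides

    def test_bipartitions_invariant_under_rooting(self, rng):
        st = self._support_tree(rng, [f"s{i}" for i in range(6)])
        rooted = sp.root_tree(st, "s0")
        assert bipartitions(rooted.tree) == bipartitions(st.tree)

    def test_root_distances_match_unrooted_path_sums(self, rng):
        st = self._support_tree(rng, [f"s{i}" for i in range(5)])
        rooted = sp.root_tree(st, "s1")
        for a, b in itertools.combinations([f"s{i}" for i in range(5)], 2):
            d_unrooted = st.tree.find(a).distance(st.tree.find(b))
            d_rooted = rooted.tree.find(a).distance(rooted.tree.find(b))
            assert d_rooted == pytest.approx(d_unrooted)

    def test_unknown_outgroup_rejected(self, rng):
        st = self._support_tree(rng, [f"s{i}" for i in range(4)])
        with pytest.raises(ValueError):
            sp.root_tree(st, "nope")


class TestAlignEngines:
    def test_passthrough_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            passthrough_align({"a": "MKV", "b": "MKVL"})

    def test_mafft_engine_aligns_indel(self):
        seqs = {
            "a": "MKVLITGAGSGIGLAAAKRF",
            "b": "MKVLITGAGSGIGLAKRF",      # 2-residue deletion
            "c": "MKVLITGAGSGIGLAAAKRF",
        }
        aligned = mafft_align(seqs)
        lengths = {len(s) for s in aligned.values()}
        assert len(lengths) == 1
        assert aligned["b"].count("-") == 2
        assert aligned["a"].replace("-", "") == seqs["a"]
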