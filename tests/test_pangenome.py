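"""Rarefaction curves, Heaps-law fits and per-replicon gene summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

import strainpan as sp


def _frame(rows, strains=None, cols=None):
    arr = np.asarray(rows)
    strains = strains or [f"s{i}" for i in range(arr.shape[0])]
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=strains, columns=cols)


class TestCoreGenome:
    def test_all_ones_matrix_keeps_every_family(self):
        df = _frame(np.ones((3, 5), dtype=int))
        assert sp.core_genome(df) == list(df.columns)

    def test_family_missing_from_member_strain_excluded(self):
        df = _frame([[1, 1], [1, 0], [1, 1]])
        assert sp.core_genome(df, ["s0", "s1"]) == ["f0"]
        assert sp.core_genome(df, ["s0", "s2"]) == ["f0", "f1"]

    def test_matches_brute_force_column_scan(self, rng):
        df = _frame(rng.integers(0, 2, size=(5, 20)))
        subset = ["s0", "s2", "s3"]
        oracle = [
            c for c in df.columns if all(df.loc[s, c] == 1 for s in subset)
        ]
        assert sp.core_genome(df, subset) == oracle

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValueError):
            sp.core_genome(_frame([[1], [1]]), ["s0", "nope"])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            sp.core_genome(_frame([[1], [1]]), [])


def _enumeration_oracle(df):
    """Exhaustive rarefaction over all strain orders using raw set algebra."""
    fam_sets = {
        s: {c for c in df.columns if df.loc[s, c]} for s in df.index
    }
    n = len(df.index)
    records = {k: {"core": [], "pan": [], "new": []} for k in range(1, n + 1)}
    for order in itertools.permutations(df.index):
        seen = set()
        core = None
        for k, s in enumerate(order, start=1):
            prev = len(seen)
            seen |= fam_sets[s]
            core = fam_sets[s] if core is None else core & fam_sets[s]
            records[k]["core"].append(len(core))
            records[k]["pan"].append(len(seen))
            records[k]["new"].append(len(seen) - prev)
    return {
        k: {q: float(np.median(v)) for q, v in rec.items()}
        for k, rec in records.items()
    }


class TestRarefaction:
    def test_all_core_matrix_is_flat(self):
        df = _frame(np.ones((4, 7), dtype=int))
        res = sp.rarefaction(df, n_permutations=20, seed=0)
        assert (res.core == 7).all() and (res.pan == 7).all()
        assert (res.new[:, 1:] == 0).all()
        assert (res.new[:, 0] == 7).all()

    def test_disjoint_strains(self):
        g = 6
        df = _frame(np.kron(np.eye(3, dtype=int), np.ones((1, g), dtype=int)))
        res = sp.rarefaction(df, n_permutations=10, seed=1)
        assert (res.core[:, 1:] == 0).all()
        assert (res.pan == g * np.arange(1, 4)).all()
        assert (res.new == g).all()

    def test_forced_full_enumeration_matches_set_algebra_oracle(self, rng):
        df = _frame(rng.integers(0, 2, size=(3, 12)))
        orders = list(itertools.permutations(range(3)))
        res = sp.rarefaction(df, orders=orders)
        med = res.medians().set_index("k")
        oracle = _enumeration_oracle(df)
        for k in (1, 2, 3):
            for q in ("core", "pan", "new"):
                assert med.loc[k, q] == oracle[k][q]

    def test_monotonicity_invariants_hold_per_permutation(self, rng):
        df = _frame(rng.integers(0, 2, size=(8, 30)))
        res = sp.rarefaction(df, n_permutations=200, seed=5)
        assert (np.diff(res.core, axis=1) <= 0).all()
        assert (np.diff(res.pan, axis=1) >= 0).all()
        assert (res.new.cumsum(axis=1) == res.pan).all()
        assert (res.pan[:, -1] == res.pan[0, -1]).all()
        assert (res.core[:, -1] == len(sp.core_genome(df))).all()

    def test_seeded_runs_are_bit_reproducible(self, rng):
        df = _frame(rng.integers(0, 2, size=(6, 25)))
        a = sp.rarefaction(df, n_permutations=50, seed=11)
        b = sp.rarefaction(df, n_permutations=50, seed=11)
        assert (a.core == b.core).all() and (a.new == b.new).all()

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            sp.rarefaction(_frame([[1, 0]]), n_permutations=5, seed=0)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            sp.rarefaction(_frame([[1], [1]]), n_permutations=0, seed=0)


class TestHeapsFit:
    def test_exact_inverse_power_law_gives_alpha_one(self):
        medians = {k: 100.0 * k**-1.0 for k in range(2, 30)}
        fit = sp.fit_heaps(medians)
        assert fit.alpha == pytest.approx(1.0)
        assert not fit.open

    def test_constant_new_curve_gives_alpha_zero(self):
        fit = sp.fit_heaps({k: 50.0 for k in range(2, 20)})
        assert fit.alpha == pytest.approx(0.0)
        assert fit.open

    def test_recovers_generating_exponent_under_noise(self):
        misses = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            k = np.arange(2, 41)
            new = 200.0 * k**-0.5 * rng.lognormal(0.0, 0.05, size=k.size)
            fit = sp.fit_heaps(dict(zip(k.tolist(), new)))
            misses.append(abs(fit.alpha - 0.5))
        assert max(misses) < 0.05

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        medians = {k: 150.0 * k**-0.7 * rng.lognormal(0, 0.03) for k in range(2, 25)}
        fit1 = sp.fit_heaps(medians)
        fit10 = sp.fit_heaps({k: 10.0 * v for k, v in medians.items()})
        assert fit10.alpha == pytest.approx(fit1.alpha)
        assert fit10.kappa == pytest.approx(10.0 * fit1.kappa)

    def test_zero_median_in_range_instructs_range_adjustment(self):
        medians = {2: 40.0, 3: 20.0, 4: 0.0, 5: 10.0}
        with pytest.raises(ValueError, match="fit_range"):
            sp.fit_heaps(medians)


class TestLeaveOneOut:
    def test_all_core_gives_constant_counts(self):
        df = _frame(np.ones((4, 9), dtype=int))
        assert sp.leave_one_out_core(df) == {f"s{i}": 9 for i in range(4)}

    def test_excluding_deficient_strain_raises_core_by_its_gap(self):
        arr = np.ones((5, 30), dtype=int)
        arr[2, :10] = 0   # strain s2 lacks 10 otherwise-universal families
        out = sp.leave_one_out_core(_frame(arr))
        assert out["s2"] == 30
        assert all(out[f"s{i}"] == 20 for i in (0, 1, 3, 4))

    def test_duplicate_strains_are_symmetric(self, rng):
        row = rng.integers(0, 2, size=(1, 15))
        arr = np.vstack([row, row, rng.integers(0, 2, size=(2, 15))])
        out = sp.leave_one_out_core(_frame(arr))
        assert out["s0"] == out["s1"]


class TestRepliconGeneSummary:
    def _genes(self, spec):
        genes = []
        for strain, cls, count in spec:
            for i in range(count):
                genes.append(
                    sp.GeneModel(
                        gene_id=f"{strain}_{cls}_{i}", strain_id=strain,
                        replicon_id=f"{strain}_{cls}", start=1 + 10 * i, end=9 + 10 * i,
                        strand="+", protein="M", replicon_class=cls,
                    )
                )
        return genes

    def test_linear_interpolation_quartiles(self):
        genes = self._genes(
            [("a", "chromosome", 10), ("b", "chromosome", 20), ("c", "chromosome", 30)]
        )
        summary = sp.replicon_gene_summary(genes)
        assert summary.as_tuple("chromosome") == (20.0, 15.0, 25.0)

    def test_class_in_single_strain_collapses_quartiles(self):
        genes = self._genes([("a", "chromosome", 5), ("a", "small_plasmid", 7)])
        assert sp.replicon_gene_summary(genes).as_tuple("small_plasmid") == (7.0, 7.0, 7.0)

    def test_matches_truth_table_recount(self, small_panel):
        _config, panel, truth = small_panel
        summary = sp.replicon_gene_summary(panel.all_genes())
        # independent recount from the truth labels via pandas
        rows = [
            (truth.replicon_class[g.replicon_id], g.strain_id)
            for s in panel for g in s.genes.values()
        ]
        df = pd.DataFrame(rows, columns=["cls", "strain"])
        counts = df.groupby(["cls", "strain"]).size()
        for cls, grp in counts.groupby(level="cls"):
            med, q1, q3 = summary.as_tuple(cls)
            assert med == np.percentile(grp.to_numpy(), 50)
            assert (q1, q3) == (
                np.percentile(grp.to_numpy(), 25), np.percentile(grp.to_numpy(), 75)
            )
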