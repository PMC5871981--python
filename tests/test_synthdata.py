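"""Synthetic benchmark generator: determinism, structure, signal sanity."""

import numpy as np
import pandas as pd
import pytest

from sfbench.descriptors import rf_v3_descriptors
from sfbench.evaluate import pearson_rp
from sfbench.partition import CutoffSchedule, build_nested_sets
from sfbench.regress import ModelSpec, fit_mlr, fit_rf
from sfbench.pipeline import compute_descriptor_tables
from sfbench.synthdata import (
    SyntheticConfig,
    make_benchmark,
    make_similarity_matrix,
    sample_complex_geometry,
)


def _hash_benchmark(bench):
    import hashlib

    h = hashlib.sha256()
    for cid in bench.train_ids + bench.test_ids:
        rec = bench.complexes[cid]
        h.update(cid.encode())
        h.update(repr(rec.affinity).encode())
        h.update(repr([a.coords for a in rec.ligand.atoms]).encode())
        h.update(repr(rec.protein.elements).encode())
    h.update(bench.similarity.frame.to_csv().encode())
    return h.hexdigest()


class TestBenchmarkLayout:
    def test_split_counts_and_disjointness(self, small_benchmark, small_config):
        assert len(small_benchmark.test_ids) == small_config.n_test
        assert len(small_benchmark.train_ids) == small_config.n_train
        assert not set(small_benchmark.train_ids) & set(small_benchmark.test_ids)

    def test_default_config_emulates_benchmark_scale(self):
        cfg = SyntheticConfig()
        assert cfg.n_test == 195
        assert cfg.n_train == 1105

    def test_every_family_has_exact_test_representatives(self, small_benchmark, small_config):
        fams = small_benchmark.family_series(small_benchmark.test_ids)
        assert (fams.value_counts() == small_config.test_per_family).all()
        assert fams.nunique() == small_config.n_families

    def test_determinism_same_seed_same_benchmark(self, small_config):
        a = make_benchmark(small_config, master_seed=123)
        b = make_benchmark(small_config, master_seed=123)
        assert _hash_benchmark(a) == _hash_benchmark(b)
        c = make_benchmark(small_config, master_seed=124)
        assert _hash_benchmark(a) != _hash_benchmark(c)


class TestGeometry:
    def test_single_atom_ligand(self, small_benchmark, rng):
        fam = small_benchmark.family_model.families[0]
        protein, ligand = sample_complex_geometry(fam, 10, 1, rng)
        assert len(ligand) == 1 and ligand.bonds == []

    def test_contacts_guaranteed(self, small_benchmark):
        for cid in list(small_benchmark.complexes)[:10]:
            rec = small_benchmark.complexes[cid]
            vec = rf_v3_descriptors(rec.protein, rec.ligand)
            assert vec.values[:36].sum() > 0

    def test_geometry_reproducible_for_same_stream(self, small_benchmark):
        fam = small_benchmark.family_model.families[0]
        a = sample_complex_geometry(fam, 12, 6, np.random.default_rng(5))
        b = sample_complex_geometry(fam, 12, 6, np.random.default_rng(5))
        assert [at.coords for at in a[0].atoms] == [at.coords for at in b[0].atoms]
        assert [at.coords for at in a[1].atoms] == [at.coords for at in b[1].atoms]

    def test_self_avoidance(self, small_benchmark):
        for cid in list(small_benchmark.complexes)[:5]:
            lig = small_benchmark.complexes[cid].ligand
            coords = lig.coords_array()
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 1.2 - 1e-3  # quantisation slack


class TestSimilarityStructure:
    def test_family_bounds(self, small_benchmark):
        sim = small_benchmark.similarity
        fams = small_benchmark.family_series()
        cfg = small_benchmark.config
        train_f = fams.loc[small_benchmark.train_ids].to_numpy()
        test_f = fams.loc[small_benchmark.test_ids].to_numpy()
        same = train_f[:, None] == test_f[None, :]
        vals = sim.frame.to_numpy()
        w_lo, w_hi = cfg.within_range
        b_lo, b_hi = cfg.between_range
        assert vals[same].min() >= w_lo and vals[same].max() <= w_hi
        assert vals[~same].min() >= b_lo and vals[~same].max() <= b_hi

    def test_midpoint_cutoff_retains_exactly_no_overlap_families(self, small_benchmark):
        """At a cutoff between the two ranges, retention = family bookkeeping."""
        part = build_nested_sets(small_benchmark.similarity, CutoffSchedule((0.5,)))
        fams = small_benchmark.family_series()
        test_families = set(fams.loc[small_benchmark.test_ids])
        expected = frozenset(
            i for i in small_benchmark.train_ids if fams.loc[i] not in test_families
        )
        assert part.retained[0.5] == expected

    def test_similarity_drawn_from_family_labels(self, rng, small_benchmark):
        fm = small_benchmark.family_model
        train = pd.Series({"a": "fam000", "b": "xfam000"})
        test = pd.Series({"t1": "fam000", "t2": "fam001"})
        sim = make_similarity_matrix(train, test, fm, rng)
        assert sim.frame.loc["a", "t1"] >= fm.within_range[0]
        assert sim.frame.loc["b"].max() <= fm.between_range[1]


class TestAffinitySignal:
    def test_noise_free_linear_generator_is_recovered_by_mlr(self):
        cfg = SyntheticConfig(
            n_families=10, test_per_family=3, n_extra_families=4, n_train=140,
            ligand_size_range=(6, 16), protein_size_range=(20, 40),
            mode="linear", noise_sd=0.0, family_offset_sd=0.0, family_tilt_sd=0.0,
        )
        bench = make_benchmark(cfg, master_seed=11)
        y = bench.affinity_series()
        tables = compute_descriptor_tables(
            bench.complexes, bench.train_ids + bench.test_ids, {"rf_v3"}, y)
        table = tables["rf_v3"]
        X_train = table.subset(bench.train_ids)
        X_test = table.subset(bench.test_ids)
        model = fit_mlr(X_train.features().to_numpy(),
                        y.loc[bench.train_ids].to_numpy())
        pred = model.predict(X_test.features().to_numpy())
        assert pearson_rp(y.loc[bench.test_ids].to_numpy(), pred) > 0.99

    def test_nonlinear_generator_favors_forest_over_line(self):
        cfg = SyntheticConfig(
            n_families=12, test_per_family=3, n_extra_families=4, n_train=300,
            ligand_size_range=(6, 16), protein_size_range=(20, 40),
            mode="nonlinear", noise_sd=0.3, family_offset_sd=0.0, family_tilt_sd=0.0,
        )
        bench = make_benchmark(cfg, master_seed=2)
        y = bench.affinity_series()
        tables = compute_descriptor_tables(
            bench.complexes, bench.train_ids + bench.test_ids, {"rf_v3"}, y)
        X_train = tables["rf_v3"].subset(bench.train_ids).features().to_numpy()
        X_test = tables["rf_v3"].subset(bench.test_ids).features().to_numpy()
        y_tr = y.loc[bench.train_ids].to_numpy()
        y_te = y.loc[bench.test_ids].to_numpy()
        rf_rp = pearson_rp(y_te, fit_rf(X_train, y_tr, ModelSpec("RF", n_trees=150), 0).predict(X_test))
        mlr_rp = pearson_rp(y_te, fit_mlr(X_train, y_tr).predict(X_test))
        assert rf_rp > mlr_rp + 0.05

    def test_same_family_training_beats_random_training(self):
        """Restricting training to the test set's own families yields higher
        forest accuracy than an equal-sized sample of other families --
        the mechanism behind the similarity-cutoff analysis."""
        wins = 0
        for seed in range(5):
            # keep the default's ~4:1 ratio of test families to train-only
            # families: the dissimilar pool spans few protein families, as
            # in the full-scale benchmark
            cfg = SyntheticConfig(
                n_families=16, test_per_family=3, n_extra_families=4, n_train=240,
                extra_family_fraction=0.45,
                ligand_size_range=(6, 16), protein_size_range=(20, 40),
            )
            bench = make_benchmark(cfg, master_seed=100 + seed)
            fams = bench.family_series()
            y = bench.affinity_series()
            test_families = set(fams.loc[bench.test_ids])
            same = [i for i in bench.train_ids if fams.loc[i] in test_families]
            other = [i for i in bench.train_ids if fams.loc[i] not in test_families]
            n = min(len(same), len(other))
            rng = np.random.default_rng(seed)
            same = list(rng.choice(same, size=n, replace=False))
            other = list(rng.choice(other, size=n, replace=False))
            tables = compute_descriptor_tables(
                bench.complexes, bench.train_ids + bench.test_ids, {"rf_v3"}, y)
            X = tables["rf_v3"]
            Xt = X.subset(bench.test_ids).features().to_numpy()
            y_te = y.loc[bench.test_ids].to_numpy()
            spec = ModelSpec("RF", n_trees=100)
            rp_same = pearson_rp(y_te, fit_rf(
                X.subset(same).features().to_numpy(), y.loc[same].to_numpy(),
                spec, 1).predict(Xt))
            rp_other = pearson_rp(y_te, fit_rf(
                X.subset(other).features().to_numpy(), y.loc[other].to_numpy(),
                spec, 1).predict(Xt))
            wins += rp_same > rp_other
        assert wins >= 4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(mode="quadratic")
        with pytest.raises(ValueError):
            SyntheticConfig(within_range=(0.3, 0.9), between_range=(0.2, 0.5))
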