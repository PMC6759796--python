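"""Generator determinism, planted structure, and the PK curve model."""

import math

import numpy as np
import pandas as pd
import pytest

from netpharm import network, synthetic
from netpharm.symbols import TargetSet
from netpharm.synthetic import PKTruth, SyntheticSpec


def small_spec(**kw):
    base = dict(n_compounds=5, n_targets_universe=200, targets_per_compound=10.0,
                n_disease_targets=50, planted_overlap=12, rng_seed=3)
    base.update(kw)
    return SyntheticSpec(**base)


class TestCompoundTargetMap:
    def test_every_compound_has_a_target(self):
        spec = SyntheticSpec(n_compounds=2, n_targets_universe=50,
                             targets_per_compound=1.0, n_disease_targets=10,
                             planted_overlap=0, dense_block_compounds=0,
                             dense_block_targets=0, rng_seed=7)
        df = synthetic.gen_compound_target_map(spec)
        assert set(df["compound_id"]) == {"C01", "C02"}
        assert (df.groupby("compound_id").size() >= 1).all()

    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = small_spec()
        a = synthetic.gen_compound_target_map(spec)
        b = synthetic.gen_compound_target_map(spec)
        pd.testing.assert_frame_equal(a, b)
        assert synthetic.gen_disease_targets(spec) == synthetic.gen_disease_targets(spec)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_csv(p1, sep="\t", index=False)
        b.to_csv(p2, sep="\t", index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_changes_output(self):
        a = synthetic.gen_compound_target_map(small_spec(rng_seed=1))
        b = synthetic.gen_compound_target_map(small_spec(rng_seed=2))
        assert not a.equals(b)

    def test_duplicate_assertions_exist_across_sources(self):
        df = synthetic.gen_compound_target_map(SyntheticSpec(rng_seed=0))
        dups = df.duplicated(subset=["compound_id", "target_symbol"])
        assert dups.any()
        # but never the same (compound, target, source) twice
        assert not df.duplicated().any()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            small_spec(planted_overlap=51)  # > n_disease_targets
        with pytest.raises(ValueError):
            small_spec(targets_per_compound=0.0)
        with pytest.raises(ValueError):
            small_spec(ppi_density=1.5)


class TestPlantedOverlap:
    @pytest.mark.parametrize("overlap", [0, 12, 30])
    def test_consensus_equals_planted_exactly(self, overlap):
        spec = small_spec(planted_overlap=overlap)
        ct = synthetic.gen_compound_target_map(spec)
        disease = synthetic.gen_disease_targets(spec)
        union = network.union_compound_targets(ct)
        consensus = network.intersect_targets(union, TargetSet("d", disease))
        assert consensus.symbols == synthetic.planted_symbols(spec)
        assert len(consensus) == overlap

    def test_disease_list_size_and_content(self):
        spec = small_spec()
        disease = synthetic.gen_disease_targets(spec)
        assert len(disease) == spec.n_disease_targets
        assert synthetic.planted_symbols(spec) <= disease

    def test_paper_scale_defaults(self):
        spec = SyntheticSpec(rng_seed=0)
        assert (spec.n_compounds, spec.n_disease_targets, spec.planted_overlap) == (29, 812, 120)
        union = network.union_compound_targets(synthetic.gen_compound_target_map(spec))
        assert 1000 <= len(union) <= 1600  # ~1,300-target scale

    def test_dense_block_inside_planted_pool(self):
        spec = small_spec(dense_block_compounds=3, dense_block_targets=4)
        comps, targets = synthetic.dense_block(spec)
        assert len(comps) == 3 and len(targets) == 4
        assert targets <= synthetic.planted_symbols(spec)
        ct = synthetic.gen_compound_target_map(spec)
        pairs = set(zip(ct["compound_id"], ct["target_symbol"]))
        assert all((c, t) in pairs for c in comps for t in targets)


class TestPPIEdges:
    def test_density_extremes(self):
        genes = [f"G{i}" for i in range(5)]
        assert synthetic.gen_ppi_edges(genes, 0.0).empty
        full = synthetic.gen_ppi_edges(genes, 1.0)
        assert len(full) == 10  # complete graph on 5 nodes
        pairs = {frozenset(p) for p in zip(full["node1"], full["node2"])}
        assert len(pairs) == 10  # no duplicates, no self-loops

    def test_scores_within_range(self):
        df = synthetic.gen_ppi_edges([f"G{i}" for i in range(20)], 0.5,
                                     score_range=(0.7, 0.95), seed=4)
        assert df["score"].between(0.7, 0.95).all()

    def test_threshold_straddle_count_matches_construction(self):
        low = synthetic.gen_ppi_edges([f"L{i}" for i in range(6)], 1.0, (0.5, 0.85), seed=1)
        high = synthetic.gen_ppi_edges([f"H{i}" for i in range(5)], 1.0, (0.92, 0.99), seed=2)
        combined = pd.concat([low, high], ignore_index=True)
        kept = combined[combined["score"] >= 0.9]
        assert len(kept) == len(high)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_ppi_edges(["G1"], 0.5)


class TestConcentrationModel:
    def test_noiseless_matches_closed_form(self):
        truth = PKTruth(noise_cv=0.0)
        df = synthetic.gen_concentration_profiles(truth, n_subjects=2, seed=0)
        times = np.array(truth.sample_times, dtype=float)
        expected = truth.concentration(times)
        for _, grp in df.groupby("subject"):
            np.testing.assert_allclose(grp["conc"].to_numpy(), expected, rtol=1e-10)

    def test_closed_form_tmax(self):
        truth = PKTruth(ka=0.05, ke=0.005, noise_cv=0.0)
        tmax = math.log(truth.ka / truth.ke) / (truth.ka - truth.ke)
        assert tmax == pytest.approx(math.log(10) / 0.045)
        t = np.linspace(0.1, 2000, 200001)
        c = truth.concentration(t)
        assert t[np.argmax(c)] == pytest.approx(tmax, abs=0.02)

    def test_default_sampling_schedule(self):
        assert PKTruth().sample_times == (5, 10, 20, 40, 60, 90, 120, 180,
                                          240, 360, 480, 720, 1440)

    def test_noise_is_positive_and_cv_scaled(self):
        truth = PKTruth(noise_cv=0.3)
        df = synthetic.gen_concentration_profiles(truth, n_subjects=400, seed=5)
        assert (df["conc"] > 0).all()
        at_peak = df[df["time_min"] == 60]["conc"]
        cv = at_peak.std(ddof=1) / at_peak.mean()
        assert cv == pytest.approx(0.3, rel=0.15)

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            PKTruth(ka=0.01, ke=0.01)
        with pytest.raises(ValueError):
            PKTruth(sample_times=(5, 5, 10))
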