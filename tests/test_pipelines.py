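"""End-to-end schemes: SL chaining, CL reconstruction, I intersection, workflow."""

import warnings

import numpy as np
import pandas as pd
import pytest

from chescatools import (
    ChescaConfig,
    GeneratorConfig,
    build_matrix,
    chesca_cl,
    chesca_i,
    chesca_sl,
    correlation_matrix,
    generate,
    make_chaining_fixture,
    make_compression_fixture,
    run_toolset,
)
from chescatools.exceptions import DegenerateInputError
from chescatools.shift_io import ShiftDataset

from conftest import FIVE_STATES


@pytest.fixture(scope="module")
def chaining():
    return make_chaining_fixture(seed=0)


@pytest.fixture(scope="module")
def compression():
    return make_compression_fixture(seed=0)


class TestChescaSL:
    def test_chaining_joins_weakly_correlated_endpoints(self, chaining):
        dataset, info = chaining
        r = correlation_matrix(build_matrix(dataset))
        a, b = info.endpoints
        assert abs(r.values.at[a, b]) < 0.90
        run = chesca_sl(dataset, min_size=2)
        member = run.clusters.membership()
        assert member[a] == member[b]

    def test_noiseless_allosteric_data_forms_one_allosteric_cluster(
        self, noiseless_allosteric
    ):
        dataset, truth = noiseless_allosteric
        with pytest.warns(UserWarning, match="zero-variance"):
            run = chesca_sl(dataset)
        assert len(run.clusters) == 1
        assert run.cluster_functions == ("allosteric",)
        assert run.allosteric_set == truth.allosteric_residues

    def test_identical_states_give_no_clusters(self):
        rows = [
            {"residue_id": rid, "state": s.state, "delta_H": 8.0 + rid * 0.1,
             "delta_N": 118.0 + rid}
            for rid in range(1, 6)
            for s in FIVE_STATES
        ]
        ds = ShiftDataset(pd.DataFrame(rows), FIVE_STATES)
        with pytest.warns(UserWarning):
            run = chesca_sl(ds)
        assert len(run.clusters) == 0
        assert run.allosteric_set == frozenset()


class TestChescaCL:
    def test_chaining_endpoints_separated(self, chaining):
        dataset, info = chaining
        run = chesca_cl(dataset, min_size=2)
        member = run.clusters.membership()
        a, b = info.endpoints
        assert member[a] != member[b]

    def test_noiseless_mixed_dataset_recovered_exactly(self, noiseless_mixed):
        dataset, truth = noiseless_mixed
        with pytest.warns(UserWarning, match="zero-variance"):
            run = chesca_cl(dataset)
        assert run.allosteric_set == truth.allosteric_residues
        assert "binding" in run.cluster_functions

    def test_overstringent_cutoff_empties_the_set(self, noisy_default):
        dataset, _ = noisy_default
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = chesca_cl(dataset, cutoff=1.0)
        assert run.allosteric_set == frozenset()

    def test_parameter_recovery_under_noise(self):
        """Precision/recall against ground truth at the 0.002 ppm noise level."""
        precs, recs = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(10):
                dataset, truth = generate(GeneratorConfig(seed=seed))
                run = chesca_cl(dataset)
                allo, got = truth.allosteric_residues, run.allosteric_set
                tp = len(got & allo)
                precs.append(tp / max(len(got), 1))
                recs.append(tp / len(allo))
        assert np.mean(precs) >= 0.9
        assert np.mean(recs) >= 0.8


class TestChescaI:
    def test_compression_artifact_removed(self, compression):
        dataset, info = compression
        cl = chesca_cl(dataset)
        assert info.compressed_residue in cl.allosteric_set
        i_run = chesca_i(dataset)
        assert info.compressed_residue not in i_run.allosteric_set
        assert i_run.allosteric_set == info.allosteric_residues

    def test_single_nucleus_responder_is_a_deliberate_false_negative(self):
        """A residue shifting only in 1H is dropped by the intersection."""
        cfg = GeneratorConfig(
            n_allosteric=8, n_binding=0, n_unresponsive=0,
            noise_sigma_h=0.0, noise_sigma_n=0.0, seed=4,
        )
        dataset, truth = generate(cfg)
        records = dataset.records.copy()
        # flatten residue 1's nitrogen response: copy its apo deltaN everywhere
        apo_n = records.query("residue_id == 1 and state == 'apo'")["delta_N"].iloc[0]
        records.loc[records["residue_id"] == 1, "delta_N"] = apo_n
        ds = ShiftDataset(records, dataset.states)
        i_run = chesca_i(ds)
        assert 1 not in i_run.allosteric_set
        assert i_run.allosteric_set == truth.allosteric_residues - {1}

    def test_noiseless_residues_responsive_in_both_nuclei_retained(
        self, noiseless_allosteric
    ):
        dataset, truth = noiseless_allosteric
        with pytest.warns(UserWarning, match="zero-variance"):
            i_run = chesca_i(dataset)
        assert i_run.allosteric_set == truth.allosteric_residues


class TestStringencyOrdering:
    def test_i_within_cl_within_sl_on_canonical_fixtures(
        self, noiseless_mixed, compression
    ):
        fixtures = [noiseless_mixed[0], compression[0]]
        for dataset in fixtures:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sl = chesca_sl(dataset)
                cl = chesca_cl(dataset)
                i_run = chesca_i(dataset)
            assert i_run.allosteric_set <= cl.allosteric_set <= sl.allosteric_set


class TestWorkflow:
    def test_compression_escalates_to_intersection(self, compression):
        dataset, info = compression
        report = run_toolset(dataset, ("apo", "Sp", "Rp"))
        assert "CL" in report.runs and "I" in report.runs
        assert info.compressed_residue in report.runs["CL"].allosteric_set
        flagged = (
            report.outlier_flags.flagged if report.outlier_flags else frozenset()
        ) | report.nonlinear
        assert info.compressed_residue in flagged
        assert info.compressed_residue not in report.runs["I"].allosteric_set
        assert info.compressed_residue in report.comparison.index

    def test_clean_data_runs_cl_only(self, noiseless_allosteric):
        dataset, truth = noiseless_allosteric
        with pytest.warns(UserWarning, match="zero-variance"):
            report = run_toolset(dataset, ("apo", "Sp", "Rp"))
        assert set(report.runs) == {"CL"}
        assert report.runs["CL"].allosteric_set == truth.allosteric_residues

    def test_missed_same_sign_residues_trigger_single_linkage(self):
        # under noise CHESCA-CL typically drops a few weak allosteric residues;
        # their in-band fractional activations must pull in the SL safety net
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(10):
                dataset, truth = generate(GeneratorConfig(seed=seed))
                report = run_toolset(dataset, ("apo", "Sp", "Rp"))
                dropped = truth.allosteric_residues - report.runs["CL"].allosteric_set
                if dropped:
                    assert "SL" in report.runs
                    assert dropped & report.missed_same_sign
                    break
            else:
                pytest.fail("no seed produced a dropped allosteric residue")

    def test_degrades_without_chespa_states(self, noiseless_allosteric):
        dataset, _ = noiseless_allosteric
        with pytest.warns(UserWarning):
            report = run_toolset(dataset, None)
        assert set(report.runs) == {"CL"}
        assert report.chespa is None

    def test_too_few_states_rejected(self, small_dataset):
        records = small_dataset.records
        trimmed = records[records["state"].isin(["apo", "Sp", "Rp"])]
        ds = ShiftDataset(trimmed, [s for s in FIVE_STATES if s.state in ("apo", "Sp", "Rp")])
        with pytest.raises(DegenerateInputError):
            chesca_sl(ds)
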