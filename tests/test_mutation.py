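"""Mutation analysis: filtering, load, spectra, signature fitting, clustering."""

import numpy as np
import pandas as pd
import pytest

from conftest import fisher_oracle
from focalcna import mutation as mut
from focalcna.genomics_io import CohortDesign, MutationRecord
from focalcna.mutation import SPECTRUM_CONTEXTS


def _rec(sample, gene, vclass, pos=100, ref="C", alt="T", ctx=None):
    return MutationRecord(sample, gene, "1", pos, ref, alt, vclass, ctx)


class TestImpactFilter:
    def test_silent_removed_nonsense_kept(self):
        records = [_rec("a", "g1", "Silent"), _rec("a", "g2", "Nonsense_Mutation")]
        kept = mut.filter_by_impact(records)
        assert [r.gene_id for r in kept] == ["g2"]

    def test_unknown_class_maps_to_unknown_and_is_dropped(self):
        records = [_rec("a", "g1", "Weird_New_Class")]
        assert mut.impact_of("Weird_New_Class") == "unknown"
        assert mut.filter_by_impact(records) == []

    def test_empty_input(self):
        assert mut.filter_by_impact([]) == []

    def test_mapping_total_over_vocabulary(self):
        from focalcna.genomics_io import MAF_VARIANT_CLASSES
        for vc in MAF_VARIANT_CLASSES:
            assert mut.impact_of(vc) in {"high", "moderate", "low", "modifier"}


class TestMutationalLoad:
    def test_counts_all_mode(self):
        design = CohortDesign({"a": "R", "b": "fS"})
        records = [_rec("a", f"g{i}", "Silent", pos=i + 1) for i in range(7)]
        counts, _ = mut.mutational_load(records, design, mode="all")
        assert counts["a"] == 7 and counts["b"] == 0

    def test_interleaved_loads_give_p1(self):
        design = CohortDesign({"a": "R", "b": "R", "c": "fS", "d": "fS"})
        loads = {"a": 1, "b": 4, "c": 2, "d": 3}
        records = [_rec(s, f"g{i}", "Silent", pos=i + 1)
                   for s, n in loads.items() for i in range(n)]
        _, p = mut.mutational_load(records, design, mode="all")
        assert p == pytest.approx(1.0)

    def test_planted_load_shift_detected(self):
        """3x mean load in one class (n = 8 vs 8): p < 0.05 in >= 90% of
        seeded replicates (Poisson loads, rank-sum test)."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            design = CohortDesign({f"r{i}": "R" for i in range(8)}
                                  | {f"s{i}": "fS" for i in range(8)})
            records = []
            for s in design.samples():
                lam = 60 if design[s] == "R" else 20
                for i in range(rng.poisson(lam)):
                    records.append(_rec(s, f"g{i}", "Silent", pos=i + 1))
            _, p = mut.mutational_load(records, design, mode="all")
            hits += p < 0.05
        assert hits >= 0.9 * n_rep


class TestTopMutatedGenes:
    def test_unique_sample_counts_and_multi_hit(self):
        records = [
            _rec("a", "g1", "Silent", pos=1), _rec("a", "g1", "Silent", pos=2),
            _rec("b", "g1", "Silent", pos=3), _rec("c", "g1", "Silent", pos=4),
            _rec("a", "g2", "Silent", pos=5), _rec("b", "g2", "Silent", pos=6),
        ]
        top = mut.top_mutated_genes(records, min_patients=3)
        assert list(top.index) == ["g1"]
        assert top.loc["g1", "n_samples"] == 3      # distinct samples
        assert top.loc["g1", "n_records"] == 4      # raw records
        assert bool(top.loc["g1", "multi_hit"]) is True

    def test_threshold_excludes(self):
        records = [_rec("a", "g1", "Silent"), _rec("b", "g1", "Silent", pos=2)]
        assert len(mut.top_mutated_genes(records, min_patients=3)) == 0


class TestPathwayStatus:
    def test_single_member_marks_pathway(self):
        records = [_rec("a", "g1", "Missense_Mutation")]
        status = mut.pathway_mutation_status(records, {"P": ["g1", "g9"]}, ["a", "b"])
        assert status.loc["P", "a"] == 1 and status.loc["P", "b"] == 0

    def test_disjoint_pathway_all_zero(self):
        records = [_rec("a", "g1", "Missense_Mutation")]
        status = mut.pathway_mutation_status(records, {"P": ["g7"]}, ["a", "b"])
        assert (status.loc["P"] == 0).all()

    def test_association_matches_oracle(self):
        design = CohortDesign({"a": "R", "b": "R", "c": "fS", "d": "fS"})
        records = [_rec("a", "g1", "Missense_Mutation"),
                   _rec("b", "g2", "Missense_Mutation"),
                   _rec("c", "g9", "Missense_Mutation")]
        status = mut.pathway_mutation_status(
            records, {"P1": ["g1", "g2"], "P2": ["g9"]}, design.samples())
        from focalcna.cna import class_association
        res = class_association(status, design)
        assert res.loc["P1", "p"] == pytest.approx(fisher_oracle(2, 0, 0, 2), abs=1e-12)
        assert res.loc["P2", "p"] == pytest.approx(fisher_oracle(0, 2, 1, 1), abs=1e-12)


class TestSpectrum:
    def test_purine_reference_folded(self):
        assert mut.fold_snv("G", "A", "AGC") == "G[C>T]T"

    def test_pyrimidine_reference_unchanged(self):
        assert mut.fold_snv("C", "T", "ACA") == "A[C>T]A"

    def test_every_snv_maps_to_exactly_one_bin(self):
        bins = set(SPECTRUM_CONTEXTS)
        n = 0
        for ref in "ACGT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for five in "ACGT":
                    for three in "ACGT":
                        label = mut.fold_snv(ref, alt, f"{five}{ref}{three}")
                        assert label in bins
                        n += 1
        assert n == 12 * 16  # all possible SNVs land in the 96-bin partition

    def test_totals_count_snvs_only(self):
        records = [
            _rec("a", "g1", "Silent", ref="C", alt="T", ctx="ACA"),
            _rec("a", "g2", "Silent", ref="G", alt="A", ctx="AGC", pos=2),
            _rec("a", "g3", "Frame_Shift_Del", ref="AT", alt="A", pos=3),  # not an SNV
            _rec("a", "g4", "Silent", ref="C", alt="G", pos=4),            # no context
        ]
        spectra = mut.spectrum_from_records(records)
        assert spectra["a"].sum() == 2

    def test_generator_context_round_trip(self, default_cohort):
        """Counts rebuilt from MAF records match the 96-bin totals exactly."""
        spectra = mut.spectrum_from_records(default_cohort.mutations,
                                            default_cohort.design.samples())
        n_snv = sum(1 for r in default_cohort.mutations
                    if r.is_snv and r.trinucleotide_context)
        assert spectra.to_numpy().sum() == n_snv
        assert (spectra.to_numpy() >= 0).all()


class TestFitSignatures:
    def test_identity_recovery(self, catalog):
        exp = mut.fit_signatures(catalog["Signature_4"].to_numpy() * 1000, catalog)
        assert exp.weights["Signature_4"] == pytest.approx(1.0, abs=1e-6)
        assert exp.weights.drop("Signature_4").abs().sum() < 1e-9
        assert exp.reconstruction_error < 1e-9

    def test_two_signature_mixture(self, catalog):
        mix = 0.6 * catalog["Signature_2"] + 0.4 * catalog["Signature_9"]
        exp = mut.fit_signatures(mix.to_numpy() * 10_000, catalog)
        assert exp.weights["Signature_2"] == pytest.approx(0.6, abs=0.01)
        assert exp.weights["Signature_9"] == pytest.approx(0.4, abs=0.01)

    def test_noiseless_triples_l1_error(self, catalog):
        rng = np.random.default_rng(5)
        names = list(catalog.columns)
        for _ in range(5):
            chosen = rng.choice(len(names), size=3, replace=False)
            w = rng.dirichlet(np.ones(3))
            w = np.clip(w, 0.08, None)
            w = w / w.sum()  # keep every component above the retention cutoff
            mix = catalog.iloc[:, chosen].to_numpy() @ w
            exp = mut.fit_signatures(mix * 50_000, catalog)
            truth = pd.Series(0.0, index=names)
            truth.iloc[chosen] = w
            assert (exp.weights - truth).abs().sum() < 0.02

    def test_retention_cutoff_zeroes_small_weights(self, catalog):
        mix = 0.97 * catalog["Signature_2"] + 0.03 * catalog["Signature_9"]
        exp = mut.fit_signatures(mix.to_numpy() * 10_000, catalog,
                                 retention_cutoff=0.06)
        assert exp.weights["Signature_9"] == 0.0
        small = exp.weights[(exp.weights > 0) & (exp.weights < 0.06)]
        assert small.empty

    def test_residual_decreases_with_tighter_tolerance(self, catalog):
        rng = np.random.default_rng(8)
        w = np.zeros(catalog.shape[1])
        w[[1, 6, 12]] = [0.5, 0.3, 0.2]
        x = rng.multinomial(500, catalog.to_numpy() @ w)
        loose = mut.fit_signatures(x, catalog, improvement_tol=0.1)
        tight = mut.fit_signatures(x, catalog, improvement_tol=1e-6)
        assert tight.reconstruction_error <= loose.reconstruction_error + 1e-12

    def test_weight_sum_bounded(self, catalog):
        rng = np.random.default_rng(9)
        x = rng.multinomial(60, np.full(96, 1 / 96))
        exp = mut.fit_signatures(x, catalog)
        assert exp.weights.sum() <= 1.0 + 1e-12
        assert exp.unexplained == pytest.approx(1.0 - exp.weights.sum())

    def test_empty_catalog_rejected(self, catalog):
        with pytest.raises(ValueError):
            mut.fit_signatures(np.ones(96), catalog.iloc[:, :0])


class TestClustering:
    def test_orthogonal_groups_separate_perfectly(self, catalog):
        exposures = pd.DataFrame(0.0, index=[f"s{i}" for i in range(8)],
                                 columns=catalog.columns)
        exposures.iloc[:4, 0] = 1.0   # group 1: pure Signature_1
        exposures.iloc[4:, 2] = 1.0   # group 2: pure Signature_3
        _, labels, _ = mut.cluster_by_signatures(exposures, top_k=5)
        assert labels.iloc[:4].nunique() == 1
        assert labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_samples_have_zero_linkage_heights(self, catalog):
        exposures = pd.DataFrame(0.25, index=[f"s{i}" for i in range(6)],
                                 columns=catalog.columns[:4])
        z, _, _ = mut.cluster_by_signatures(exposures, top_k=4)
        assert np.allclose(z[:, 2], 0.0)

    def test_class_association_reported(self, catalog):
        design = CohortDesign({f"s{i}": ("R" if i < 4 else "fS") for i in range(8)})
        exposures = pd.DataFrame(0.0, index=design.samples(), columns=catalog.columns)
        exposures.iloc[:4, 0] = 1.0
        exposures.iloc[4:, 2] = 1.0
        _, _, p = mut.cluster_by_signatures(exposures, design, top_k=5)
        assert p == pytest.approx(fisher_oracle(4, 0, 0, 4), abs=1e-12)
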