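import numpy as np
import pytest

from clinalign.embeddings import EmbeddingModel, cosine
from clinalign.errors import ConfigError
from clinalign.harmonize import fit_procrustes
from clinalign.pathways import EventType
from clinalign.synthdata import (
    SyntheticConfig,
    delete_diagnoses,
    generate_cohort,
    generate_events,
    relabel_site_codes,
    simulate_transformed_embedding,
    split_sites,
)


class TestConfigValidation:
    def test_too_many_targets_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(
                n_conditions=60,
                diagnoses_per_condition=2,
                vocab_sizes={"lab": 50, "prescription": 50, "condition": 50,
                             "symptom": 50, "diagnosis": 100},
            )

    def test_bad_ranges_and_noise_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(admissions_per_patient=(3, 2))
        with pytest.raises(ConfigError):
            SyntheticConfig(label_noise=0.6)
        with pytest.raises(ConfigError):
            SyntheticConfig(emission_concentration=0.0)


class TestGenerateCohort:
    def test_reproducible_from_seed(self):
        cfg = SyntheticConfig(n_patients=60, seed=9)
        ev1, gt1 = generate_events(cfg)
        ev2, gt2 = generate_events(cfg)
        assert ev1 == ev2
        assert gt1.patient_conditions == gt2.patient_conditions

    def test_structure_pathways_labels_and_ground_truth(self):
        cfg = SyntheticConfig(n_patients=80, seed=4)
        cohort, gt = generate_cohort(cfg)
        assert len(cohort) == 80
        a_lo, a_hi = cfg.admissions_per_patient
        for pid, pw in cohort.pathways.items():
            assert a_lo <= pw.n_admissions <= a_hi
            assert pw.admission_index == sorted(pw.admission_index)
            assert all(c[:2] in ("l_", "p_", "c_", "s_", "d_") for c in pw.events)
        # labels: every unflipped target of the patient's conditions present
        n_checked = 0
        for pid, conds in gt.patient_conditions.items():
            labels = cohort.label_map.get(pid, set())
            planted = {d for k in conds for d in gt.condition_diagnoses[k]}
            n_checked += len(planted & labels)
        assert n_checked > 0.8 * sum(
            len(c) * cfg.diagnoses_per_condition
            for c in gt.patient_conditions.values()
        )

    def test_degenerate_concentration_collapses_emissions(self):
        cfg = SyntheticConfig(
            n_patients=30, emission_concentration=1e9, n_synonym_groups=0, seed=1
        )
        cohort, gt = generate_cohort(cfg)
        for k, per_type in gt.emissions.items():
            for t, p in per_type.items():
                assert p.max() == pytest.approx(1.0)
        # each condition emits one deterministic code per event type
        single = [
            pid for pid, c in gt.patient_conditions.items() if len(c) == 1
        ]
        for pid in single[:10]:
            (k,) = gt.patient_conditions[pid]
            history = {
                c for c in cohort.pathways[pid].events if not c.startswith("d_")
            }
            assert len(history) <= 4  # at most one lab/rx/condition/symptom code

    def test_label_prevalence_matches_generative_design(self):
        # exact oracle: enumerate condition sets and integrate the label
        # probability (direct label + final-admission emission leakage)
        cfg = SyntheticConfig(n_patients=2000, seed=12)
        cohort, gt = generate_cohort(cfg)
        K, dpc = cfg.n_conditions, cfg.diagnoses_per_condition
        e_lo, e_hi = cfg.events_per_admission
        p_diag_type = 0.15
        n_targets = K * dpc

        singles = [(k,) for k in range(K)]
        pairs = [(a, b) for a in range(K) for b in range(a + 1, K)]
        p_single = 0.5 / len(singles)
        p_pair = 0.5 / len(pairs)

        def p_label(i):  # target index i = k * dpc + j
            k = i // dpc
            total = 0.0
            for sets, pc in ((singles, p_single), (pairs, p_pair)):
                for C in sets:
                    q = p_diag_type * np.mean(
                        [gt.emissions[c]["diagnosis"][i] for c in C]
                    )
                    no_leak = np.mean(
                        [(1 - q) ** n for n in range(e_lo, e_hi + 1)]
                    )
                    direct = (1 - cfg.label_noise) if k in C else 0.0
                    total += pc * (1 - (1 - direct) * no_leak)
            return total

        for i, d in enumerate(
            f"d_{100 + i}" for i in range(n_targets)
        ):
            expected = p_label(i)
            observed = np.mean(
                [int(d in cohort.label_map.get(p, set())) for p in cohort.patient_ids]
            )
            se = np.sqrt(expected * (1 - expected) / len(cohort))
            assert abs(observed - expected) <= 3 * se, (d, observed, expected)

    def test_planted_signal_is_learnable(self, small_cohort, trained_pair):
        # embeddings place same-condition signature codes closer together
        _, gt = small_cohort
        model, _, _ = trained_pair
        prefix = {"lab": "l_", "prescription": "p_", "condition": "c_", "symptom": "s_"}
        fmt = {"lab": "L{:03d}", "prescription": "P{:03d}",
               "condition": "C{:03d}", "symptom": "S{:03d}"}
        signatures = {}
        for k, per_type in gt.emissions.items():
            codes = []
            for t in ("lab", "prescription"):
                for i in np.argsort(per_type[t])[-3:]:
                    code = prefix[t] + fmt[t].format(i)
                    if code in model:
                        codes.append(code)
            signatures[k] = codes
        within, cross = [], []
        ks = sorted(signatures)
        for k in ks:
            sig = signatures[k]
            for i in range(len(sig)):
                for j in range(i + 1, len(sig)):
                    within.append(cosine(model.vector(sig[i]), model.vector(sig[j])))
            other = signatures[(k + 1) % len(ks)]
            for a in sig[:2]:
                for b in other[:2]:
                    cross.append(cosine(model.vector(a), model.vector(b)))
        assert np.mean(within) > np.mean(cross)


class TestSplitSites:
    def test_even_and_imbalanced_sizes(self, small_cohort):
        cohort, _ = small_cohort
        half = split_sites(cohort.subset(cohort.patient_ids[:100]), [0.5, 0.5], 1)
        assert [len(s) for s in half] == [50, 50]
        cfg = SyntheticConfig(n_patients=1000, seed=2)
        big, _ = generate_cohort(cfg)
        sites = split_sites(big, [0.95, 0.05], 3)
        assert [len(s) for s in sites] == [950, 50]

    def test_partition_law(self, small_cohort):
        cohort, _ = small_cohort
        sites = split_sites(cohort, [0.3, 0.3, 0.4], 7)
        ids = [set(s.pathways) for s in sites]
        assert set.union(*ids) == set(cohort.pathways)
        assert sum(len(i) for i in ids) == len(cohort)

    def test_invalid_fractions(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ConfigError):
            split_sites(cohort, [0.5, 0.4], 0)
        with pytest.raises(ConfigError):
            split_sites(cohort, [1.2, -0.2], 0)


class TestRelabel:
    def test_keep_all_is_identity(self, small_cohort):
        cohort, _ = small_cohort
        all_codes = {c for pw in cohort.pathways.values() for c in pw.events}
        all_codes |= {c for s in cohort.label_map.values() for c in s}
        out = relabel_site_codes(cohort, "_m1", all_codes)
        assert {p: pw.events for p, pw in out.pathways.items()} == {
            p: pw.events for p, pw in cohort.pathways.items()
        }

    def test_keep_nothing_suffixes_everything(self, small_cohort):
        cohort, _ = small_cohort
        out = relabel_site_codes(cohort, "_m1", set())
        assert all(
            c.endswith("_m1") for pw in out.pathways.values() for c in pw.events
        )

    def test_seeded_sample_complement_suffixed_and_invertible(self, small_cohort):
        cohort, _ = small_cohort
        vocab = sorted({c for pw in cohort.pathways.values() for c in pw.events})
        rng = np.random.default_rng(5)
        keep = set(rng.choice(vocab, size=int(0.4 * len(vocab)), replace=False))
        out = relabel_site_codes(cohort, "_m2", keep)
        for pid, pw in out.pathways.items():
            orig = cohort.pathways[pid].events
            for c_new, c_old in zip(pw.events, orig):
                if c_old in keep:
                    assert c_new == c_old
                else:
                    assert c_new == c_old + "_m2"
        # invertible given (suffix, keep)
        back = {
            pid: [c[: -len("_m2")] if c.endswith("_m2") else c for c in pw.events]
            for pid, pw in out.pathways.items()
        }
        assert back == {p: pw.events for p, pw in cohort.pathways.items()}


class TestDeleteDiagnoses:
    def test_absent_code_is_identity(self, small_cohort):
        cohort, _ = small_cohort
        out = delete_diagnoses(cohort, {"d_zzz"})
        assert {p: pw.events for p, pw in out.pathways.items()} == {
            p: pw.events for p, pw in cohort.pathways.items()
        }

    def test_delete_all_diagnoses_leaves_no_d_events(self, small_cohort):
        cohort, _ = small_cohort
        d_codes = {
            c for pw in cohort.pathways.values() for c in pw.events if c.startswith("d_")
        }
        out = delete_diagnoses(cohort, d_codes)
        assert not any(
            c.startswith("d_") for pw in out.pathways.values() for c in pw.events
        )
        assert not out.label_map

    def test_delete_half_of_planted_targets(self, small_cohort):
        cohort, gt = small_cohort
        targets = gt.target_diagnoses
        half = set(targets[:20])

        def count(cohort_, codes):
            return sum(
                1
                for pw in cohort_.pathways.values()
                for c in pw.events
                if c in codes
            )

        kept_before = count(cohort, set(targets[20:]))
        out = delete_diagnoses(cohort, half)
        assert count(out, half) == 0
        assert count(out, set(targets[20:])) == kept_before


class TestSimulatedTransform:
    def test_identity_parameters_reproduce_input(self, rng):
        model = EmbeddingModel([f"c{i}" for i in range(20)], rng.standard_normal((20, 6)))
        out, t = simulate_transformed_embedding(
            model, k0=1.0, noise_sd=0.0, rotation=np.eye(6),
            translation=model.matrix.mean(axis=0),
        )
        assert np.allclose(out.matrix, model.matrix, atol=1e-12)

    def test_invalid_scale_rejected(self, rng):
        model = EmbeddingModel(["a", "b"], rng.standard_normal((2, 3)))
        with pytest.raises(ConfigError):
            simulate_transformed_embedding(model, k0=0.0)

    def test_noise_free_recovery(self, rng):
        model = EmbeddingModel(
            [f"c{i}" for i in range(100)], rng.standard_normal((100, 15))
        )
        moved, true_t = simulate_transformed_embedding(
            model, k0=3.0, rotation_seed=11, noise_sd=0.0,
            translation=rng.standard_normal(15),
        )
        t = fit_procrustes(model.matrix, moved.matrix)
        assert t.residual < 1e-8
        assert abs(t.k - true_t.k) < 1e-8
        assert np.linalg.norm(t.Q - true_t.Q) < 1e-8

    def test_noise_band_on_per_anchor_residual(self, rng):
        # per-anchor residual should sit near noise_sd * k0 * sqrt(m)
        model = EmbeddingModel(
            [f"c{i}" for i in range(150)], rng.standard_normal((150, 12))
        )
        noise_sd, k0, m = 0.1, 2.0, 12
        vals = []
        for rep in range(20):
            moved, _ = simulate_transformed_embedding(
                model, k0=k0, rotation_seed=rep, noise_sd=noise_sd
            )
            t = fit_procrustes(model.matrix, moved.matrix)
            per_anchor = t.residual / np.sqrt(len(model))
            vals.append(per_anchor)
        expected = noise_sd * k0 * np.sqrt(m)
        assert 0.5 * expected < np.median(vals) < 1.5 * expected
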