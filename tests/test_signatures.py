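"""Spectra, signature refitting, hypermutation, category comparisons."""

import numpy as np
import pandas as pd
import pytest

from recurrevol import signatures as sig


def frame(rows):
    return pd.DataFrame(rows, columns=["ref", "alt", "context", "variant_class"])


class TestSpectrum:
    def test_purine_strand_complemented(self):
        # G>T with context AGA is the reverse complement of C>A at TCT
        spec = sig.spectrum(frame([("G", "T", "AGA", "SNV")]), with_context=True)
        assert spec.counts6["C>A"] == 1
        idx = sig.CATEGORY_LABELS.index("T[C>A]T")
        assert spec.counts96[idx] == 1

    def test_only_t_to_a(self):
        rows = [("T", "A", "ATC", "SNV")] * 7
        spec = sig.spectrum(frame(rows))
        assert spec.counts6.tolist() == [0, 0, 0, 7, 0, 0]

    def test_indels_excluded(self):
        spec = sig.spectrum(
            pd.DataFrame(
                {
                    "ref": ["A", "AT"],
                    "alt": ["T", "A"],
                    "context": ["CAT", ""],
                    "variant_class": ["SNV", "indel"],
                }
            )
        )
        assert spec.counts6.sum() == 1

    def test_96_marginalizes_to_6(self):
        rng = np.random.default_rng(3)
        cats = rng.integers(0, 96, 500)
        ref, alt, ctx = sig.category_to_alleles(cats)
        spec = sig.spectrum(
            frame(list(zip(ref, alt, ctx, ["SNV"] * 500))), with_context=True
        )
        assert spec.counts96.reshape(6, 16).sum(axis=1).tolist() == spec.counts6.tolist()

    def test_complement_idempotence(self):
        rng = np.random.default_rng(4)
        cats = rng.integers(0, 96, 300)
        ref, alt, ctx = sig.category_to_alleles(cats)
        fwd = sig.spectrum(frame(list(zip(ref, alt, ctx, ["SNV"] * 300))), with_context=True)
        rc = sig.spectrum(
            frame(
                list(
                    zip(
                        sig.complement_alleles(ref),
                        sig.complement_alleles(alt),
                        sig.reverse_complement_contexts(ctx),
                        ["SNV"] * 300,
                    )
                )
            ),
            with_context=True,
        )
        assert np.array_equal(fwd.counts96, rc.counts96)

    def test_missing_context_rejected_in_96_mode(self):
        with pytest.raises(ValueError):
            sig.spectrum(frame([("C", "A", "", "SNV")]), with_context=True)


class TestReferenceMatrix:
    def test_shape_and_normalization(self):
        S = sig.synthetic_reference_signatures()
        assert S.shape == (96, 30)
        assert np.allclose(S.sum(axis=0), 1.0)
        assert (S.to_numpy() >= 0).all()

    def test_deterministic(self):
        assert sig.synthetic_reference_signatures().equals(sig.synthetic_reference_signatures())

    def test_signature_22_is_t_to_a_dominant(self):
        S = sig.synthetic_reference_signatures()
        block = S["Signature.22"].to_numpy().reshape(6, 16).sum(axis=1)
        assert block[3] > 0.7  # T>A class

    def test_round_trip_via_tsv(self, tmp_path):
        p = tmp_path / "sigs.tsv"
        sig.write_reference_signatures(p)
        back = sig.read_signature_matrix(p)
        assert np.allclose(back.to_numpy(), sig.synthetic_reference_signatures().to_numpy())


class TestRefit:
    def test_identity_column(self):
        S = sig.synthetic_reference_signatures()
        x = S["Signature.4"].to_numpy() * 1000
        exp = sig.refit_exposures(x, S)
        assert exp.weights["Signature.4"] == pytest.approx(1.0)
        assert (exp.weights.drop("Signature.4") == 0).all()

    def test_noise_free_combination_recovered(self):
        S = sig.synthetic_reference_signatures()
        w = pd.Series(0.0, index=S.columns)
        w[["Signature.1", "Signature.4", "Signature.16", "Signature.22"]] = [0.3, 0.25, 0.25, 0.2]
        x = S.to_numpy() @ w.to_numpy()
        exp = sig.refit_exposures(x, S)
        assert np.allclose(exp.weights.to_numpy(), w.to_numpy(), atol=1e-6)

    def test_below_cutoff_zeroed(self):
        S = sig.synthetic_reference_signatures()
        w = pd.Series(0.0, index=S.columns)
        w[["Signature.4", "Signature.22"]] = [0.97, 0.03]
        x = S.to_numpy() @ w.to_numpy()
        exp = sig.refit_exposures(x, S, cutoff=0.06)
        assert exp.weights["Signature.22"] == 0.0
        assert exp.weights.sum() == pytest.approx(1.0)

    def test_zero_spectrum_rejected(self):
        S = sig.synthetic_reference_signatures()
        with pytest.raises(ValueError):
            sig.refit_exposures(np.zeros(96), S)

    def test_length_mismatch(self):
        S = sig.synthetic_reference_signatures()
        with pytest.raises(ValueError):
            sig.refit_exposures(np.ones(95), S)

    def test_exposures_sum_to_one_and_respect_cutoff(self):
        S = sig.synthetic_reference_signatures()
        rng = np.random.default_rng(0)
        x = rng.poisson(50, 96).astype(float)
        exp = sig.refit_exposures(x, S, cutoff=0.06)
        w = exp.weights.to_numpy()
        assert w.sum() == pytest.approx(1.0)
        assert ((w == 0) | (w >= 0.06 - 1e-9)).all()


class TestHypermutation:
    @pytest.mark.parametrize(
        "n, expected", [(30_000, True), (2_990, False), (0, False), (25_200, False)]
    )
    def test_flag(self, n, expected):
        assert sig.hypermutation_flag(n) is expected

    def test_invalid_genome_size(self):
        with pytest.raises(ValueError):
            sig.hypermutation_flag(10, genome_mb=0)


class TestCategoryComparisons:
    def exposures(self, weights):
        S = sig.synthetic_reference_signatures()
        return {
            cat: sig.SignatureExposure(weights=pd.Series(w, index=S.columns), rss=0.0)
            for cat, w in weights.items()
        }

    def test_identical_exposures_t_zero(self):
        w = np.zeros(30)
        w[3] = 1.0
        pe = [self.exposures({"a": w, "b": w}) for _ in range(4)]
        out = sig.compare_exposures(pe, [("a", "b")])
        assert (out["t"] == 0).all()

    def test_single_patient_descriptive_only(self):
        w = np.zeros(30)
        w[3] = 1.0
        pe = [self.exposures({"a": w, "b": w})]
        out = sig.compare_exposures(pe, [("a", "b")])
        assert out["t"].isna().all()
        assert (out["n"] == 1).all()

    def test_category_exposures_flags_low_confidence(self):
        S = sig.synthetic_reference_signatures()
        rng = np.random.default_rng(1)
        cats = rng.choice(96, 20, p=(S.to_numpy() @ (np.eye(30)[3])) / 1.0)
        ref, alt, ctx = sig.category_to_alleles(cats)
        muts = pd.DataFrame(
            {"ref": ref, "alt": alt, "context": ctx, "variant_class": "SNV"}
        )
        out = sig.category_exposures({"small": muts}, S)
        assert out["small"].low_confidence
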