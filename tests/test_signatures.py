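"""Catalog construction and signature refitting against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import nnls

from conftest import make_snv
from neoexome.contexts import SBS96_CLASSES, class_components, sbs96_class
from neoexome.signatures import MutationCatalog, build_catalog, fit_signatures


class TestContexts:
    def test_single_snv_increments_one_class(self):
        rec = make_snv(ref="C", alt="T", context="ACA")
        cat = build_catalog([rec])
        assert cat.total == 1
        assert cat.counts[SBS96_CLASSES.index("A[C>T]A")] == 1

    def test_purine_reference_reverse_complemented(self):
        # G>A on the forward strand at TGT is C>T at ACA on the pyrimidine strand
        assert sbs96_class("G", "A", "TGT") == "A[C>T]A"
        rec = make_snv(ref="G", alt="A", context="TGT")
        cat = build_catalog([rec])
        assert cat.counts[SBS96_CLASSES.index("A[C>T]A")] == 1

    def test_class_components_round_trip(self):
        for label in SBS96_CLASSES:
            ref, alt, ctx = class_components(label)
            assert sbs96_class(ref, alt, ctx) == label

    def test_context_must_centre_on_ref(self):
        with pytest.raises(ValueError, match="centre"):
            sbs96_class("C", "T", "AGA")


class TestCatalogInclusion:
    def test_vaf_and_quality_cuts_are_strict(self):
        at_vaf = make_snv(pos=1, tumour_depth=100, tumour_alt_reads=10, vaf=0.10)
        at_qual = make_snv(pos=2, call_quality=20.0)
        above = make_snv(pos=3, call_quality=20.5, tumour_depth=100, tumour_alt_reads=11, vaf=0.11)
        cat = build_catalog([at_vaf, at_qual, above])
        assert cat.total == 1

    def test_all_consequence_classes_included(self):
        recs = [make_snv(pos=i, consequence=c) for i, c in enumerate(
            ["missense", "synonymous", "intronic", "intergenic"])]
        assert build_catalog(recs).total == 4

    def test_missing_context_raises(self):
        rec = make_snv()
        rec.context = ""
        with pytest.raises(ValueError, match="context"):
            build_catalog([rec])


class TestFitting:
    def test_identity_fit(self, matrix):
        cat = MutationCatalog("x", matrix.row("Signature 2") * 1000)
        fit = fit_signatures(cat, matrix)
        assert fit.weights.get("Signature 2", 0) >= 0.99
        assert fit.sse == pytest.approx(0.0, abs=1e-8)
        assert fit.unexplained + sum(fit.weights.values()) == pytest.approx(1.0, abs=1e-6)

    def test_even_mixture_recovered_against_nnls_oracle(self, matrix):
        """Expected (noise-free) 50/50 catalog of two dissimilar signatures."""
        mix = 0.5 * matrix.row("Signature 1") + 0.5 * matrix.row("Signature 17")
        cat = MutationCatalog("x", mix * 10_000)
        fit = fit_signatures(cat, matrix)
        assert fit.weights.get("Signature 1", 0) == pytest.approx(0.5, abs=0.02)
        assert fit.weights.get("Signature 17", 0) == pytest.approx(0.5, abs=0.02)
        w_oracle, _ = nnls(matrix.values.T, cat.proportions())
        by_id = dict(zip(matrix.signature_ids, w_oracle))
        assert fit.weights["Signature 1"] == pytest.approx(by_id["Signature 1"], abs=0.02)

    def test_pruning_floor_and_mass_balance(self, matrix):
        rng = np.random.default_rng(11)
        for _ in range(10):
            counts = rng.multinomial(1500, rng.dirichlet(np.ones(96)))
            fit = fit_signatures(MutationCatalog("r", counts), matrix)
            assert all(w >= 0.06 for w in fit.weights.values())
            assert sum(fit.weights.values()) + fit.unexplained == pytest.approx(1.0, abs=1e-6)

    def test_fit_beats_every_single_signature(self, matrix):
        rng = np.random.default_rng(3)
        mix = 0.6 * matrix.row("Signature 1") + 0.4 * matrix.row("Signature 3")
        counts = rng.multinomial(3000, mix)
        cat = MutationCatalog("x", counts)
        fit = fit_signatures(cat, matrix)
        target = cat.proportions()
        for row in matrix.values:
            w = max(0.0, min(1.0, float(row @ target) / float(row @ row)))
            single_sse = float(((target - w * row) ** 2).sum())
            assert fit.sse <= single_sse + 1e-9

    def test_sse_close_to_full_nnls_oracle(self, matrix):
        """Greedy refit SSE within 5% of full-matrix NNLS on noise-free random
        mixtures whose true weights all sit above the pruning floor. (Below the
        floor the pruned fit must exceed NNLS by construction, and on sampled
        catalogs NNLS is free to fit noise with tiny weights the refit prunes.)
        """
        rng = np.random.default_rng(29)
        for _ in range(50):
            k = int(rng.integers(1, 5))
            idx = rng.choice(30, size=k, replace=False)
            w = rng.dirichlet(np.ones(k)) * (1 - 0.08 * k) + 0.08
            mix = w @ matrix.values[idx]
            cat = MutationCatalog("r", mix * 5000)
            fit = fit_signatures(cat, matrix)
            _, resid = nnls(matrix.values.T, cat.proportions())
            assert fit.sse <= 1.05 * resid**2 + 1e-8

    def test_sampled_catalog_sse_tracks_nnls_within_noise(self, matrix):
        """On multinomial-sampled catalogs the pruned refit stays within the
        sampling-noise floor of the unconstrained NNLS optimum."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            idx = rng.choice(30, size=2, replace=False)
            w = rng.uniform(0.2, 0.8)
            mix = w * matrix.values[idx[0]] + (1 - w) * matrix.values[idx[1]]
            counts = rng.multinomial(2500, mix)
            cat = MutationCatalog("r", counts)
            fit = fit_signatures(cat, matrix)
            _, resid = nnls(matrix.values.T, cat.proportions())
            noise_floor = float((mix * (1 - mix)).sum()) / 2500
            assert fit.sse <= resid**2 + 3 * noise_floor

    def test_empty_catalog_rejected(self, matrix):
        with pytest.raises(ValueError, match="empty"):
            fit_signatures(MutationCatalog("x", np.zeros(96)), matrix)
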