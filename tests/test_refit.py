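"""NNLS refitting, etiology merging and the AA-proportion statistic."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear
from sklearn.base import clone

from aasig.refit import (
    ExposureVector,
    MergeMap,
    SignatureRefitter,
    aa_proportion,
    fit_exposures,
    merge_exposures,
)
from aasig.reference import SignatureMatrix
from aasig.simulate import SimCatalogConfig, simulate_catalog
from aasig.spectrum import MutationCatalog

from conftest import mixture_weights


def _disjoint_support_matrix():
    """Two signatures with disjoint support (first vs last 48 classes)."""
    probs = np.zeros((96, 2))
    probs[:48, 0] = 1 / 48
    probs[48:, 1] = 1 / 48
    return SignatureMatrix(["Signature A", "Signature B"], probs)


class TestFitExposures:
    def test_exact_pure_signature_is_recovered(self, signatures):
        counts = 1000.0 * signatures.column("Signature 22")
        exp = fit_exposures(MutationCatalog("pure22", counts), signatures)
        assert exp["Signature 22"] == pytest.approx(1000.0, rel=1e-6)
        others = exp.total - exp["Signature 22"]
        assert others == pytest.approx(0.0, abs=1e-6 * 1000)
        assert exp.reconstruction_cosine == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_bounded_least_squares(self, signatures):
        """Cross-check the active-set NNLS against scipy's TRF bounded solver."""
        for seed in range(5):
            cat = simulate_catalog(
                SimCatalogConfig(5000, mixture_weights(0.4), seed), signatures
            )
            mine = fit_exposures(cat, signatures).exposures
            oracle = lsq_linear(
                signatures.probs, cat.counts.astype(float),
                bounds=(0, np.inf), tol=1e-12,
            ).x
            # both minimize the same strictly convex-on-support objective
            r_mine = np.linalg.norm(cat.counts - signatures.probs @ mine)
            r_oracle = np.linalg.norm(cat.counts - signatures.probs @ oracle)
            assert r_mine == pytest.approx(r_oracle, rel=1e-6)
            assert np.allclose(mine, oracle, atol=5e-3 * cat.total ** 0.5)

    def test_mixture_weight_recovered(self, signatures, merge_map):
        """60/40 signature 22 / 1 mixture: fitted AA fraction within +-0.03."""
        errors = []
        for seed in range(25):
            cfg = SimCatalogConfig(
                20000, {"Signature 22": 0.6, "Signature 1": 0.4}, seed
            )
            cat = simulate_catalog(cfg, signatures)
            merged = merge_exposures(fit_exposures(cat, signatures), merge_map)
            errors.append(aa_proportion(merged) - 0.6)
        assert np.mean(np.abs(errors)) <= 0.03
        assert abs(np.mean(errors)) <= 0.03

    def test_orthogonal_support_gets_zero_exposure(self):
        sigs = _disjoint_support_matrix()
        counts = np.zeros(96)
        counts[:48] = 10.0
        exp = fit_exposures(MutationCatalog("a_only", counts), sigs)
        assert exp["Signature B"] == 0.0
        assert exp["Signature A"] == pytest.approx(480.0, rel=1e-9)

    def test_scale_equivariance(self, signatures):
        cat = simulate_catalog(
            SimCatalogConfig(3000, mixture_weights(0.5), 11), signatures
        )
        e1 = fit_exposures(cat, signatures).exposures
        scaled = MutationCatalog(cat.sample_id, cat.counts * 7.0)
        e7 = fit_exposures(scaled, signatures).exposures
        assert np.allclose(e7, 7.0 * e1, rtol=1e-6, atol=1e-6)

    def test_noiseless_three_signature_mixture_reconstructs(self, signatures):
        mix = (
            0.5 * signatures.column("Signature 22")
            + 0.3 * signatures.column("Signature 1")
            + 0.2 * signatures.column("Signature 5")
        )
        exp = fit_exposures(MutationCatalog("mix", 10000 * mix), signatures)
        assert exp.reconstruction_cosine >= 0.999

    def test_zero_catalog_errors_by_default(self, signatures):
        with pytest.raises(ValueError, match="zero total"):
            fit_exposures(MutationCatalog("empty", np.zeros(96)), signatures)
        exp = fit_exposures(
            MutationCatalog("empty", np.zeros(96)), signatures, allow_zero=True
        )
        assert exp.total == 0.0


class TestMergeExposures:
    def _exposure(self):
        return ExposureVector(
            "s", ["Signature 22", "Signature 1", "Signature 5"],
            np.array([600.0, 250.0, 150.0]),
        )

    def test_identity_map_preserves_vector(self):
        exp = self._exposure()
        mm = MergeMap({n: n for n in exp.names})
        merged = merge_exposures(exp, mm)
        assert merged.names == exp.names
        assert np.allclose(merged.exposures, exp.exposures)

    def test_all_to_one_group_conserves_total(self):
        exp = self._exposure()
        merged = merge_exposures(exp, MergeMap({n: "all" for n in exp.names}))
        assert merged.exposures.tolist() == [1000.0]

    def test_additivity(self):
        exp = self._exposure()
        mm = MergeMap(
            {"Signature 22": "AA", "Signature 1": "clock", "Signature 5": "clock"}
        )
        merged = merge_exposures(exp, mm)
        assert merged["AA"] == 600.0
        assert merged["clock"] == 400.0
        assert merged.total == exp.total

    def test_unmapped_signature_is_error(self):
        exp = self._exposure()
        with pytest.raises(ValueError, match="Signature 5"):
            merge_exposures(exp, MergeMap({"Signature 22": "AA", "Signature 1": "c"}))

    def test_default_map_has_ten_groups_with_aa_first_anchor(self, signatures):
        mm = MergeMap.default(signatures.names)
        groups = mm.group_names()
        assert len(groups) == 10
        assert mm.mapping["Signature 22"] == "AA"
        aa_members = [s for s, g in mm.mapping.items() if g == "AA"]
        assert aa_members == ["Signature 22"]

    def test_merge_map_file_round_trip(self, signatures, merge_map, tmp_path):
        path = tmp_path / "merge.cfg"
        merge_map.to_file(path)
        assert MergeMap.from_file(path).mapping == merge_map.mapping


class TestAAProportion:
    def test_simple_ratio(self):
        exp = ExposureVector("s", ["AA", "other"], np.array([600.0, 400.0]))
        assert aa_proportion(exp) == pytest.approx(0.6)

    def test_zero_aa_gives_zero(self):
        exp = ExposureVector("s", ["AA", "other"], np.array([0.0, 400.0]))
        assert aa_proportion(exp) == 0.0

    def test_pure_signature_22_catalog_is_unity(self, signatures, merge_map):
        counts = 5000.0 * signatures.column("Signature 22")
        merged = merge_exposures(
            fit_exposures(MutationCatalog("p", counts), signatures), merge_map
        )
        assert aa_proportion(merged) == pytest.approx(1.0, abs=1e-6)

    def test_zero_total_is_error(self):
        exp = ExposureVector("s", ["AA", "other"], np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="zero total"):
            aa_proportion(exp)


class TestSignatureRefitterEstimator:
    def test_sklearn_contract(self, signatures):
        est = SignatureRefitter(signatures=signatures)
        params = est.get_params()
        assert "signatures" in params and "allow_zero" in params
        cloned = clone(est)
        X = np.vstack(
            [
                simulate_catalog(
                    SimCatalogConfig(2000, mixture_weights(w), 5), signatures
                ).counts
                for w in (0.0, 0.7)
            ]
        )
        exposures = cloned.fit(X).transform(X)
        assert exposures.shape == (2, signatures.n_signatures)
        assert np.all(exposures >= 0)

    def test_merged_totals_equal_raw_totals(self, signatures):
        X = np.vstack(
            [
                simulate_catalog(
                    SimCatalogConfig(4000, mixture_weights(w), 9), signatures
                ).counts
                for w in (0.2, 0.8)
            ]
        )
        est = SignatureRefitter(signatures=signatures).fit(X)
        raw, merged = est.transform(X), est.transform_merged(X)
        assert np.allclose(raw.sum(axis=1), merged.sum(axis=1))
        props = est.aa_proportion(X)
        assert props.shape == (2,)
        assert props[1] > props[0]

    def test_wrong_feature_count_rejected(self, signatures):
        est = SignatureRefitter(signatures=signatures)
        with pytest.raises(ValueError):
            est.fit(np.ones((3, 50)))
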