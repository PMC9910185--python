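"""Synthetic panels, simulated surveys, and the bundled survey fixture."""

import numpy as np
import pytest

from eelid.assay import Marker, amplify, digest, scan_sites
from eelid.classify import FinalCall, classify_manifest
from eelid.errors import FixtureError, SimulationError
from eelid.simulate import (
    AssayTruthConfig,
    PlantedMarker,
    SurveyScenario,
    TAXON_ANGUILLA,
    TAXON_INTROGRESSED,
    TAXON_JAPONICA,
    TAXON_ROSTRATA,
    TAXON_SALTWATER,
    make_reference_panel,
    simulate_survey,
    retail_survey_fixture,
)

EXPECTED_FRAGMENTS = {
    (TAXON_ROSTRATA, Marker.CYTB): {280, 70},
    (TAXON_ANGUILLA, Marker.CYTB): {350},
    (TAXON_JAPONICA, Marker.CYTB): {117, 164, 69},
    (TAXON_SALTWATER, Marker.CYTB): {280, 70},
    (TAXON_ROSTRATA, Marker.S18): {167, 245},
    (TAXON_ANGUILLA, Marker.S18): {412},
    (TAXON_JAPONICA, Marker.S18): {412},
    (TAXON_SALTWATER, Marker.S18): {412},
}


class TestReferencePanel:
    def test_amplify_and_digest_reproduce_every_configured_profile(self, panel, cfg):
        """Round trip: the virtual assay on each generated reference yields
        exactly its planted fragment multiset."""
        assert len(panel) == 8
        for ref in panel:
            amp = amplify(ref, cfg.primer_for(ref.marker))
            assert amp.length == len(ref.sequence)  # primers at the ends
            res = digest(
                amp, cfg.enzyme_for(ref.marker),
                visibility_threshold=cfg.visibility_threshold,
            )
            assert set(res.fragments) == EXPECTED_FRAGMENTS[(ref.taxon, ref.marker)]

    def test_anguilla_cytb_has_no_recognition_site(self, panel, cfg):
        ref = next(
            r for r in panel
            if r.taxon == TAXON_ANGUILLA and r.marker is Marker.CYTB
        )
        assert scan_sites(ref.sequence, cfg.enzymes["HinfI"]) == []

    def test_no_cross_enzyme_contamination(self, panel, cfg):
        """No sequence carries an unintended site of the *other* enzyme."""
        for ref in panel:
            other = "PauI" if ref.marker is Marker.CYTB else "HinfI"
            assert scan_sites(ref.sequence, cfg.enzymes[other]) == []

    def test_same_seed_is_byte_identical_and_seeds_differ(self, cfg):
        a = make_reference_panel(AssayTruthConfig.default(seed=5), cfg)
        b = make_reference_panel(AssayTruthConfig.default(seed=5), cfg)
        c = make_reference_panel(AssayTruthConfig.default(seed=6), cfg)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_planted_cut_outside_amplicon_rejected(self):
        with pytest.raises(SimulationError):
            AssayTruthConfig(
                profiles={("x", Marker.CYTB): PlantedMarker(350, (350,))}
            )


class TestSimulateSurvey:
    def test_noiseless_survey_is_classified_perfectly(self, panel, cfg):
        scenario = SurveyScenario(
            strata=[("HI", "sushi_bar", 50, None)],
            mixture={TAXON_ROSTRATA: 1.0},
            band_noise=0.0,
            seed=3,
        )
        records, truth = simulate_survey(scenario, panel, cfg)
        classify_manifest(records)
        assert len(records) == 50
        assert all(
            r.final_call.final is FinalCall.A_ROSTRATA for r in records
        )

    def test_noiseless_mixture_recovers_generator_truth(self, panel, cfg):
        """Confusion matrix vs truth is the identity on a no-noise survey."""
        scenario = SurveyScenario(
            strata=[("HI", "sushi_bar", 120, None)],
            mixture={
                TAXON_ROSTRATA: 0.5,
                TAXON_ANGUILLA: 0.25,
                TAXON_JAPONICA: 0.25,
            },
            band_noise=0.0,
            seed=4,
        )
        records, truth = simulate_survey(scenario, panel, cfg)
        classify_manifest(records)
        expected_final = {
            TAXON_ROSTRATA: FinalCall.A_ROSTRATA,
            TAXON_ANGUILLA: FinalCall.A_ANGUILLA,
            TAXON_JAPONICA: FinalCall.A_JAPONICA,
        }
        for rec in records:
            assert rec.final_call.final is expected_final[truth[rec.sample_id]]

    def test_introgressed_hybrids_are_flagged(self, panel, cfg):
        scenario = SurveyScenario(
            strata=[("HI", "grocery", 20, None)],
            mixture={TAXON_INTROGRESSED: 1.0},
            band_noise=0.0,
            seed=5,
        )
        records, _ = simulate_survey(scenario, panel, cfg)
        classify_manifest(records)
        assert all(
            r.final_call.final is FinalCall.PUTATIVE_INTROGRESSED_HYBRID
            for r in records
        )

    def test_saltwater_draws_look_like_hybrid_candidates(self, panel, cfg):
        scenario = SurveyScenario(
            strata=[("HI", "grocery", 10, None)],
            mixture={TAXON_SALTWATER: 1.0},
            band_noise=0.0,
            seed=6,
        )
        records, _ = simulate_survey(scenario, panel, cfg)
        classify_manifest(records)
        assert all(
            r.final_call.final is FinalCall.SALTWATER_OR_HYBRID for r in records
        )

    def test_study_like_mixture_estimates_near_truth(self, panel, cfg):
        """p-hat over several seeds stays within 3 binomial SEs of 5.2%."""
        from eelid.survey import estimate_frequency

        se = 100 * np.sqrt(0.052 * 0.948 / 134)
        for seed in range(5):
            scenario = SurveyScenario(
                strata=[("HI", "sushi_bar", 134, None)],
                mixture={TAXON_ROSTRATA: 0.948, TAXON_ANGUILLA: 0.052},
                seed=seed,
            )
            records, _ = simulate_survey(scenario, panel, cfg)
            classify_manifest(records)
            est = estimate_frequency(records, B=10, seed=seed)
            assert abs(est.p_hat - 5.2) <= 3 * se

    def test_unknown_taxon_in_mixture_rejected(self, panel, cfg):
        scenario = SurveyScenario(
            strata=[("HI", "grocery", 5, None)],
            mixture={"A. mossambica": 1.0},
            seed=1,
        )
        with pytest.raises(SimulationError, match="mossambica"):
            simulate_survey(scenario, panel, cfg)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            SurveyScenario(
                strata=[("HI", "grocery", 5, None)],
                mixture={TAXON_ROSTRATA: 0.7},
                seed=1,
            )

    def test_band_noise_perturbs_but_stays_matchable(self, panel, cfg):
        scenario = SurveyScenario(
            strata=[("HI", "grocery", 200, None)],
            mixture={TAXON_ROSTRATA: 1.0},
            band_noise=0.01,
            seed=7,
        )
        records, _ = simulate_survey(scenario, panel, cfg)
        classify_manifest(records)
        sizes = {r.cytb_profile.bands[0] for r in records}
        assert len(sizes) > 1  # noise actually applied
        assert all(
            r.final_call.final is FinalCall.A_ROSTRATA for r in records
        )


class TestRetailSurveyFixture:
    def test_row_counts_match_the_published_survey(self):
        records = retail_survey_fixture()
        assert len(records) == 137
        fresh = [r for r in records if r.water_class == "freshwater_labeled"]
        assert len(fresh) == 134
        assert sum(r.retail_type == "sushi_bar" for r in records) == 94

    def test_sample_15_is_the_hawaii_grocery_anguilla(self):
        rec = next(r for r in retail_survey_fixture() if r.sample_id == "15")
        assert rec.state == "HI"
        assert rec.retail_type == "grocery"
        assert rec.cytb_profile.bands == (350,)
        assert rec.s18_profile.bands == (412,)

    def test_checksum_guard_detects_tampering(self, monkeypatch):
        import eelid.simulate as sim

        monkeypatch.setattr(sim, "RETAIL_SURVEY_SHA256", "0" * 64)
        with pytest.raises(FixtureError, match="checksum"):
            sim.retail_survey_fixture()
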