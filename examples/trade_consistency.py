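"""Is the observed European-eel frequency explainable by legal trade?

Over 2019-2021 the US imported 16,795,248 kg of freshwater eel, of which
265,500 kg were European eels with CITES export permits.  If all trade were
lawful, about that mass fraction of retail eel should be European.  The
check: does the legally-permitted fraction fall inside the survey's 95%
confidence interval?
"""

from eelid import (
    classify_manifest,
    consistency_check,
    estimate_frequency,
    legal_fraction,
    study_ledger,
    retail_survey_fixture,
)

records = classify_manifest(retail_survey_fixture())
estimate = estimate_frequency(records, B=1000, seed=1234)
fraction = legal_fraction(study_ledger(), years=(2019, 2021))
report = consistency_check(estimate, fraction)

print(f"legally-permitted European-eel fraction of imports: {fraction}%")
print(
    f"observed retail frequency: {estimate.p_hat}% "
    f"(95% CI {estimate.ci[0]}-{estimate.ci[1]}%)"
)
verdict = "inside" if report.inside_ci else "outside"
print(f"the legal fraction falls {verdict} the survey interval -> "
      f"{'consistent with lawful trade alone' if report.inside_ci else 'excess over lawful trade'}")
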