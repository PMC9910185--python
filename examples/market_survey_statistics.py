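"""Survey statistics: how common are European eels in US retail?

Computes the overall and stratified European-eel frequencies among the 134
freshwater-labelled samples, with a 1000-replicate bootstrap SD and a 95%
Wald interval, then asks (binomial GLM likelihood-ratio tests) whether state
or retail type predicts where European eels turn up.
"""

from eelid import classify_manifest, glm_lrt, stratified_report, retail_survey_fixture

records = classify_manifest(retail_survey_fixture())
report = stratified_report(records, B=1000, seed=1234)

overall = report["overall"]
print(
    f"overall: {overall.k}/{overall.n} = {overall.p_hat}% European eel "
    f"(bootstrap sigma {overall.sigma_boot}%, "
    f"95% CI {overall.ci[0]}-{overall.ci[1]}%)"
)

print("\nby state:")
for key, est in report.items():
    if key.startswith("state:") and est.k > 0:
        print(f"  {key[6:]}: {est.k}/{est.n} = {est.p_hat}% (sigma {est.sigma_boot}%)")

print("\nby retail type:")
for key, est in report.items():
    if key.startswith("retail:"):
        print(f"  {key[7:]}: {est.k}/{est.n} = {est.p_hat}%")

print("\nstratum effects (LRT on binomial GLM, low-n states excluded):")
for predictor in ("state", "retail_type"):
    res = glm_lrt(records, predictor)
    verdict = "significant" if res.p_value < 0.05 else "not significant"
    print(
        f"  {predictor}: X2={res.chi_square:.2f}, df={res.df}, N={res.N}, "
        f"p={res.p_value:.2f} -> {verdict}"
    )
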