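"""Market-survey statistics for a classified sample manifest.

The quantity of interest is the frequency of a target species (by default
the European eel, *A. anguilla*) among samples *sold as* freshwater eel:
saltwater-labelled samples (anago / yakianago / "saltwater eel") are excluded
from every denominator.  Uncertainty is reported three ways, matching common
practice for small survey proportions:

* a bootstrap standard deviation of the resampled proportion (B replicates),
* a normal-approximation (Wald) 95% margin of error and interval,
* a likelihood-ratio test from a binomial GLM for stratum effects.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assay import BandProfile
from .classify import FinalCall, SpeciesCall
from .errors import EmptyStratumError, InputError

RETAIL_TYPES = ("grocery", "restaurant", "sushi_bar")

#: states dropped from the GLM for low sample size (1-3 records each)
DEFAULT_EXCLUDED_STATES = frozenset({"IL", "NV", "NY", "TX"})

_SALTWATER_LABEL_TOKENS = ("anago", "saltwater")


def water_class_from_label(label: str) -> str:
    """'saltwater_labeled' iff the retail label names a saltwater eel
    (anago, yakianago or explicit 'saltwater'), else 'freshwater_labeled'."""
    low = label.lower()
    if any(tok in low for tok in _SALTWATER_LABEL_TOKENS):
        return "saltwater_labeled"
    return "freshwater_labeled"


def normalize_retail_type(raw: str) -> str:
    key = raw.strip().lower().replace(" ", "_")
    if key not in RETAIL_TYPES:
        raise InputError(f"unknown retail type {raw!r}")
    return key


@dataclass
class SampleRecord:
    """One retail sample: provenance, label, and its two band profiles."""

    sample_id: str
    date: _dt.date | None
    retail_type: str
    city: str
    state: str
    label_text: str
    cytb_profile: BandProfile
    s18_profile: BandProfile
    water_class: str = ""
    final_call: SpeciesCall | None = None
    source_brand: str = ""
    recorded_identification: str = ""

    def __post_init__(self) -> None:
        self.retail_type = normalize_retail_type(self.retail_type)
        if not self.water_class:
            self.water_class = water_class_from_label(self.label_text)


@dataclass
class FrequencyEstimate:
    """A stratified proportion with bootstrap and Wald uncertainty.

    All percentages are on the 0-100 scale and rounded to one decimal for
    reporting; ``p_exact`` keeps the unrounded proportion.
    """

    k: int
    n: int
    p_hat: float
    sigma_boot: float
    margin: float
    ci: tuple[float, float]
    B: int
    seed: int
    stratum: str = "overall"

    @property
    def p_exact(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class GlmResult:
    predictor: str
    N: int
    df: int
    chi_square: float
    p_value: float


def bootstrap_sigma(k: int, n: int, B: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard deviation (percent) of a sample proportion.

    Resampling n binary indicators (k successes) with replacement makes each
    replicate success count Binomial(n, k/n); the replicates are drawn
    directly from that distribution.  Returns the sample SD (ddof=1) of the
    B replicate proportions, as a percentage.
    """
    if n <= 0:
        raise InputError("n must be positive")
    if not 0 <= k <= n:
        raise InputError("k must be in [0, n]")
    if B < 1:
        raise InputError("B must be >= 1")
    if k in (0, n):
        return 0.0
    rng = np.random.default_rng(seed)
    props = rng.binomial(n, k / n, size=B) / n
    return float(100.0 * props.std(ddof=1))


def wald_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Normal-approximation margin of error and CI for a binomial proportion.

    Returns ``(p_hat, margin, (low, high))`` in percent, each rounded to one
    decimal; the interval endpoints are formed from the rounded point
    estimate and margin so that printed values are self-consistent.
    """
    if n <= 0:
        raise InputError("n must be positive")
    if not 0 < level < 1:
        raise InputError("confidence level must be in (0, 1)")
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    margin = z * 100.0 * np.sqrt(p * (1.0 - p) / n)
    p_r, m_r = round(100.0 * p, 1), round(float(margin), 1)
    return p_r, m_r, (round(p_r - m_r, 1), round(p_r + m_r, 1))


def eligible_records(records: list[SampleRecord]) -> list[SampleRecord]:
    """Freshwater-labelled records only (the survey denominator)."""
    return [r for r in records if r.water_class == "freshwater_labeled"]


def estimate_frequency(
    records: list[SampleRecord],
    target: FinalCall = FinalCall.A_ANGUILLA,
    *,
    state: str | None = None,
    retail_type: str | None = None,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> FrequencyEstimate:
    """Frequency of ``target`` among eligible records in an optional stratum.

    Records must already carry a final call.  Saltwater-labelled samples are
    never counted in the denominator.
    """
    pool = eligible_records(records)
    parts = []
    if state is not None:
        pool = [r for r in pool if r.state == state]
        parts.append(f"state={state}")
    if retail_type is not None:
        rt = normalize_retail_type(retail_type)
        pool = [r for r in pool if r.retail_type == rt]
        parts.append(f"retail_type={rt}")
    stratum = " & ".join(parts) or "overall"
    if not pool:
        raise EmptyStratumError(f"no eligible records in stratum {stratum!r}")
    missing = [r.sample_id for r in pool if r.final_call is None]
    if missing:
        raise InputError(f"records lack species calls: {missing[:5]}")
    n = len(pool)
    k = sum(r.final_call.final is target for r in pool)
    p_hat, margin, ci = wald_ci(k, n, level)
    sigma = round(bootstrap_sigma(k, n, B=B, seed=seed), 1)
    return FrequencyEstimate(
        k=k, n=n, p_hat=p_hat, sigma_boot=sigma, margin=margin, ci=ci,
        B=B, seed=seed, stratum=stratum,
    )


def glm_lrt(
    records: list[SampleRecord],
    predictor: str,
    *,
    target: FinalCall = FinalCall.A_ANGUILLA,
    excluded_states: frozenset[str] = DEFAULT_EXCLUDED_STATES,
    max_iter: int = 100,
) -> GlmResult:
    """Likelihood-ratio test for a stratum effect on the target frequency.

    Fits intercept-only and single-predictor binomial GLMs (logit link) by
    IRLS and compares deviances; the statistic is chi-square on
    (levels - 1) df.  Low-sample states are excluded for both predictors so
    the two tests run on the same records.
    """
    if predictor not in ("state", "retail_type"):
        raise InputError(f"unknown predictor {predictor!r}")
    pool = [
        r for r in eligible_records(records) if r.state not in excluded_states
    ]
    if any(r.final_call is None for r in pool):
        raise InputError("records lack species calls")
    df = pd.DataFrame(
        {
            "y": [int(r.final_call.final is target) for r in pool],
            "level": [getattr(r, predictor) for r in pool],
        }
    )
    levels = sorted(df["level"].unique())
    if len(levels) < 2:
        raise InputError(
            f"predictor {predictor!r} is constant after filtering"
        )
    import statsmodels.api as sm

    y = df["y"].to_numpy(dtype=float)
    X_full = pd.get_dummies(df["level"], drop_first=True, dtype=float)
    X_full.insert(0, "const", 1.0)
    X_null = np.ones((len(df), 1))
    fam = sm.families.Binomial()
    full = sm.GLM(y, X_full, family=fam).fit(maxiter=max_iter)
    null = sm.GLM(y, X_null, family=fam).fit(maxiter=max_iter)
    if not (full.converged and null.converged):
        raise InputError(f"GLM for {predictor!r} did not converge")
    chi2 = float(null.deviance - full.deviance)
    dof = len(levels) - 1
    p = float(stats.chi2.sf(chi2, dof))
    return GlmResult(
        predictor=predictor, N=len(df), df=dof, chi_square=chi2, p_value=p
    )


def stratified_report(
    records: list[SampleRecord],
    *,
    target: FinalCall = FinalCall.A_ANGUILLA,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, FrequencyEstimate]:
    """Overall plus per-state and per-retail-type frequency estimates.

    Stratum bootstrap seeds are derived deterministically from ``seed`` so
    the whole report is reproducible from one integer.
    """
    out: dict[str, FrequencyEstimate] = {}
    out["overall"] = estimate_frequency(
        records, target, B=B, seed=seed, level=level
    )
    eligible = eligible_records(records)
    for i, st in enumerate(sorted({r.state for r in eligible})):
        out[f"state:{st}"] = estimate_frequency(
            records, target, state=st, B=B, seed=seed + 1 + i, level=level
        )
    for j, rt in enumerate(RETAIL_TYPES):
        try:
            out[f"retail:{rt}"] = estimate_frequency(
                records, target, retail_type=rt, B=B, seed=seed + 101 + j,
                level=level,
            )
        except EmptyStratumError:
            continue
    return out
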