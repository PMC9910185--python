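"""Synthetic reference panels and stratified retail surveys.

Real reference sequences are not bundled; instead the generator emits random
amplicon-length sequences with recognition sites planted at exactly the
positions that reproduce each taxon's diagnostic fragment profile
(rostrata cytb 280+70, japonica cytb 117+164+69, anguilla cytb uncut 350;
rostrata 18S 167+245, all others uncut 412) and every unintended occurrence
of any configured recognition motif scrubbed away.  Digesting a generated
reference therefore yields its configured profile exactly, which is what
makes every downstream stage testable without downloads.

The survey simulator draws species per stratum from a known mixture, builds
each sample's band profiles through the virtual assay, and perturbs band
sizes with multiplicative Gaussian noise to emulate gel sizing error.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .assay import (
    Amplicon,
    BandProfile,
    Marker,
    ReferenceSequence,
    amplify,
    digest,
    reverse_complement,
    scan_sites,
    _window_starts,
)
from .config import RunConfig, default_config
from .errors import FixtureError, SimulationError
from .survey import SampleRecord

TAXON_ROSTRATA = "A. rostrata"
TAXON_ANGUILLA = "A. anguilla"
TAXON_JAPONICA = "A. japonica"
TAXON_SALTWATER = "Conger sp."  # saltwater outgroup, profile per the assay
#: pseudo-taxon: American eel nuclear background with European mtDNA
TAXON_INTROGRESSED = "introgressed_hybrid"

PANEL_TAXA = (TAXON_ROSTRATA, TAXON_ANGUILLA, TAXON_JAPONICA, TAXON_SALTWATER)

#: expected fragment multisets implied by the planted cut positions
_CANONICAL_FRAGMENTS = {
    (TAXON_ROSTRATA, Marker.CYTB): (280, 70),
    (TAXON_ANGUILLA, Marker.CYTB): (350,),
    (TAXON_JAPONICA, Marker.CYTB): (117, 164, 69),
    (TAXON_SALTWATER, Marker.CYTB): (280, 70),
    (TAXON_ROSTRATA, Marker.S18): (167, 245),
    (TAXON_ANGUILLA, Marker.S18): (412,),
    (TAXON_JAPONICA, Marker.S18): (412,),
    (TAXON_SALTWATER, Marker.S18): (412,),
}


@dataclass(frozen=True)
class PlantedMarker:
    """Amplicon length and planted cut positions for one taxon x marker."""

    length: int
    cut_positions: tuple[int, ...]

    def fragments(self) -> tuple[int, ...]:
        bounds = (0,) + tuple(sorted(self.cut_positions)) + (self.length,)
        return tuple(b - a for a, b in zip(bounds, bounds[1:]))


@dataclass
class AssayTruthConfig:
    """Ground truth the reference-panel generator realises as sequence."""

    profiles: dict[tuple[str, Marker], PlantedMarker]
    visibility_threshold: int = 100
    gc_fraction: float = 0.5
    seed: int = 1234

    def __post_init__(self) -> None:
        for (taxon, marker), planted in self.profiles.items():
            if any(not 0 < p < planted.length for p in planted.cut_positions):
                raise SimulationError(
                    f"planted cut outside ({taxon}, {marker.value}) amplicon"
                )

    @classmethod
    def default(cls, seed: int = 1234) -> "AssayTruthConfig":
        profiles = {
            (TAXON_ROSTRATA, Marker.CYTB): PlantedMarker(350, (280,)),
            (TAXON_ANGUILLA, Marker.CYTB): PlantedMarker(350, ()),
            (TAXON_JAPONICA, Marker.CYTB): PlantedMarker(350, (117, 281)),
            (TAXON_SALTWATER, Marker.CYTB): PlantedMarker(350, (280,)),
            (TAXON_ROSTRATA, Marker.S18): PlantedMarker(412, (167,)),
            (TAXON_ANGUILLA, Marker.S18): PlantedMarker(412, ()),
            (TAXON_JAPONICA, Marker.S18): PlantedMarker(412, ()),
            (TAXON_SALTWATER, Marker.S18): PlantedMarker(412, ()),
        }
        cfg = cls(profiles=profiles, seed=seed)
        for key, planted in profiles.items():
            expected = Counter(_CANONICAL_FRAGMENTS[key])
            if Counter(planted.fragments()) != expected:
                raise SimulationError(f"default profile mismatch for {key}")
        return cfg


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _concretize(pattern: str, rng: np.random.Generator) -> str:
    from .assay import IUPAC

    return "".join(
        c if c in "ACGT" else str(rng.choice(sorted(IUPAC[c]))) for c in pattern
    )


def _scrub(
    seq: list[str],
    protected: set[int],
    patterns: dict[str, set[int]],
    rng: np.random.Generator,
    max_passes: int = 100,
) -> None:
    """Resample free columns until no pattern matches outside its allowed
    window starts.  ``patterns`` maps each motif (given in both orientations)
    to the window starts where a match is intentional."""
    for _ in range(max_passes):
        dirty = False
        s = "".join(seq)
        for pattern, allowed in patterns.items():
            for start in _window_starts(s, pattern):
                if start in allowed:
                    continue
                free = [
                    j
                    for j in range(start, start + len(pattern))
                    if j not in protected
                ]
                if not free:
                    raise SimulationError(
                        f"unintended {pattern} site at {start} overlaps only "
                        "protected positions"
                    )
                for j in free:
                    seq[j] = str(rng.choice(list("ACGT")))
                dirty = True
        if not dirty:
            return
    raise SimulationError("site scrubbing did not converge")


def make_reference_panel(
    config: AssayTruthConfig | None = None,
    run_config: RunConfig | None = None,
) -> list[ReferenceSequence]:
    """Generate one reference sequence per taxon x marker.

    Each sequence is a complete amplicon: exact primer sites at both ends,
    recognition sites realised at the planted positions, and all unintended
    occurrences of any configured recognition motif (either strand) removed
    by resampling.  Deterministic given the config seed.
    """
    config = config or AssayTruthConfig.default()
    rc = run_config or default_config()
    panel: list[ReferenceSequence] = []
    for idx, ((taxon, marker), planted) in enumerate(
        sorted(config.profiles.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
    ):
        rng = np.random.default_rng([config.seed, idx])
        L = planted.length
        seq = _random_bases(rng, L, config.gc_fraction)
        primers = rc.primer_for(marker)
        fwd = primers.forward
        rev_site = reverse_complement(primers.reverse)
        seq[: len(fwd)] = list(fwd)
        seq[L - len(rev_site) :] = list(rev_site)
        protected = set(range(len(fwd))) | set(range(L - len(rev_site), L))

        enzyme = rc.enzyme_for(marker)
        allowed_starts: set[int] = set()
        for cut in planted.cut_positions:
            start = cut - enzyme.cut_offset
            if start < 0 or start + len(enzyme.recognition) > L:
                raise SimulationError(
                    f"planted window for cut {cut} leaves the amplicon"
                )
            site = _concretize(enzyme.recognition, rng)
            seq[start : start + len(site)] = list(site)
            protected |= set(range(start, start + len(site)))
            allowed_starts.add(start)

        patterns: dict[str, set[int]] = {}
        for name, enz in rc.enzymes.items():
            allowed = allowed_starts if name == rc.marker_enzymes[marker] else set()
            for pat in {enz.recognition, reverse_complement(enz.recognition)}:
                patterns[pat] = patterns.get(pat, set()) | allowed
        _scrub(seq, protected, patterns, rng)

        sequence = "".join(seq)
        cuts = [
            p
            for p in scan_sites(sequence, enzyme, both_strands=rc.scan_both_strands)
            if 0 < p < L
        ]
        if tuple(cuts) != tuple(sorted(planted.cut_positions)):
            raise SimulationError(
                f"generated ({taxon}, {marker.value}) sequence has cuts "
                f"{cuts}, expected {sorted(planted.cut_positions)}"
            )
        panel.append(
            ReferenceSequence(
                id=f"{taxon.replace(' ', '_').replace('.', '')}_{marker.value}",
                taxon=taxon,
                marker=marker,
                sequence=sequence,
            )
        )
    return panel


@dataclass
class SurveyScenario:
    """A stratified survey design with known species mixture.

    ``mixture`` maps taxon -> proportion (summing to 1), applied to every
    stratum unless overridden per stratum in ``strata`` entries of the form
    ``(state, retail_type, n, mixture-or-None)``.
    """

    strata: list[tuple[str, str, int, dict[str, float] | None]]
    mixture: dict[str, float]
    band_noise: float = 0.02
    band_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.strata = [
            (s[0], s[1], s[2], s[3] if len(s) > 3 else None) for s in self.strata
        ]
        for mix in [self.mixture] + [s[3] for s in self.strata if s[3]]:
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"mixture sums to {total}, not 1")
        if any(s[2] < 0 for s in self.strata):
            raise SimulationError("stratum counts must be >= 0")
        if self.band_noise < 0 or not 0 <= self.band_dropout <= 1:
            raise SimulationError("invalid noise parameters")


def _truncated_factor(rng: np.random.Generator, sd: float) -> float:
    """Multiplicative size-error factor, Gaussian truncated at +/-3 SD."""
    if sd == 0:
        return 1.0
    while True:
        eps = rng.normal(0.0, sd)
        if abs(eps) <= 3 * sd:
            return 1.0 + eps


def simulate_survey(
    scenario: SurveyScenario,
    panel: list[ReferenceSequence],
    run_config: RunConfig | None = None,
) -> tuple[list[SampleRecord], dict[str, str]]:
    """Simulate a retail survey: draw species per stratum, run the virtual
    assay on the true taxon's references, and perturb the band sizes.

    Introgressed hybrids take their cytb bands from *A. anguilla* (maternal
    lineage) and their 18S bands from *A. rostrata* (nuclear background).
    Returns the records and a sample_id -> true-taxon table.
    """
    rc = run_config or default_config()
    by_key = {(ref.taxon, ref.marker): ref for ref in panel}

    def marker_bands(taxon: str, marker: Marker) -> tuple[int, ...]:
        ref = by_key.get((taxon, marker))
        if ref is None:
            raise SimulationError(
                f"mixture taxon {taxon!r} has no {marker.value} reference"
            )
        amp = amplify(ref, rc.primer_for(marker),
                      max_product_length=rc.max_product_length)
        return digest(
            amp, rc.enzyme_for(marker),
            visibility_threshold=rc.visibility_threshold,
            both_strands=rc.scan_both_strands,
        ).visible_bands

    taxa_needed = set(scenario.mixture)
    for s in scenario.strata:
        if s[3]:
            taxa_needed |= set(s[3])
    base_bands: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {}
    for taxon in taxa_needed:
        if taxon == TAXON_INTROGRESSED:
            base_bands[taxon] = (
                marker_bands(TAXON_ANGUILLA, Marker.CYTB),
                marker_bands(TAXON_ROSTRATA, Marker.S18),
            )
        else:
            base_bands[taxon] = (
                marker_bands(taxon, Marker.CYTB),
                marker_bands(taxon, Marker.S18),
            )

    rng = np.random.default_rng(scenario.seed)
    records: list[SampleRecord] = []
    truth: dict[str, str] = {}
    counter = 0

    def perturb(bands: tuple[int, ...]) -> tuple[int, ...]:
        sizes = [
            max(1, round(b * _truncated_factor(rng, scenario.band_noise)))
            for b in bands
        ]
        if scenario.band_dropout > 0 and len(sizes) > 1:
            # near-threshold bands (within 20% above) are sometimes missed
            near = [s for s in sizes if s <= 1.2 * rc.visibility_threshold]
            for s in near:
                if len(sizes) > 1 and rng.random() < scenario.band_dropout:
                    sizes.remove(s)
        return tuple(sizes)

    for state, retail_type, n, override in scenario.strata:
        mix = override or scenario.mixture
        taxa = sorted(mix)
        probs = np.array([mix[t] for t in taxa])
        draws = rng.choice(len(taxa), size=n, p=probs / probs.sum())
        for d in draws:
            counter += 1
            taxon = taxa[int(d)]
            cytb_bands, s18_bands = base_bands[taxon]
            sample_id = f"SIM{counter:04d}"
            records.append(
                SampleRecord(
                    sample_id=sample_id,
                    date=_dt.date(2020, 6, 15),
                    retail_type=retail_type,
                    city="Simulated",
                    state=state,
                    label_text="Unagi",
                    cytb_profile=BandProfile(
                        Marker.CYTB, perturb(cytb_bands), rc.band_tolerance
                    ),
                    s18_profile=BandProfile(
                        Marker.S18, perturb(s18_bands), rc.band_tolerance
                    ),
                )
            )
            truth[sample_id] = taxon
    return records, truth


#: integrity digest of the bundled retail-survey manifest
RETAIL_SURVEY_SHA256 = "428aaeaa88b0fe67825d170f1a000855e8dac1a40e2d08e7cf0019ab54d168ef"


def retail_survey_fixture(tolerance: float = 0.05) -> list[SampleRecord]:
    """The bundled 137-sample US retail survey manifest (2019-2021).

    Columns mirror the published survey table: sample number, purchase date,
    retail type, city, state, label text, observed cytb and 18S band sizes,
    the study's identification, and source/brand where known.  The file's
    SHA-256 digest is checked on every load.
    """
    import csv
    import io as _io

    raw = resources.files("eelid.data").joinpath("retail_survey.csv").read_bytes()
    digest_hex = hashlib.sha256(raw).hexdigest()
    if digest_hex != RETAIL_SURVEY_SHA256:
        raise FixtureError(
            f"survey fixture checksum mismatch: {digest_hex} != {RETAIL_SURVEY_SHA256}"
        )
    records: list[SampleRecord] = []
    for row in csv.DictReader(_io.StringIO(raw.decode())):
        records.append(
            SampleRecord(
                sample_id=row["sample"],
                date=_dt.datetime.strptime(row["date"], "%m/%d/%y").date(),
                retail_type=row["retail_type"],
                city=row["city"],
                state=row["state"],
                label_text=row["labeled_as"],
                cytb_profile=BandProfile(
                    Marker.CYTB,
                    tuple(int(b) for b in row["cytb_bands"].split(",")),
                    tolerance,
                ),
                s18_profile=BandProfile(
                    Marker.S18,
                    tuple(int(b) for b in row["s18_bands"].split(",")),
                    tolerance,
                ),
                source_brand=row["source_brand"],
                recorded_identification=row["identification"],
            )
        )
    return records
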