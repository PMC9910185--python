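"""Dual-marker species calling for freshwater eels.

A single mitochondrial marker cannot separate a true European eel from an
American eel carrying introgressed European mtDNA (the two species hybridise
in the North Atlantic).  The classifier therefore reads the cytb (mtDNA) and
18S rRNA (nuclear) digestion profiles jointly:

========================  ==================  ================================
cytb (HinfI)              18S (PauI)          call
========================  ==================  ================================
uncut 350                 uncut 412           European eel (A. anguilla)*
single 280                cut 167+245         American eel (A. rostrata)
cut 117+164               uncut 412           Japanese eel (A. japonica)*
single 280                uncut 412           saltwater eel or hybrid*
uncut 350                 cut 167+245         putative introgressed hybrid*
any unrecognised profile  --                  unresolved*
========================  ==================  ================================

Calls marked ``*`` carry the SEQUENCING_REQUIRED flag: the band pattern alone
cannot or should not be the final word, so the amplicon is escalated to
sequence comparison against a reference panel (``confirm_identity``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .assay import BandProfile, Marker, ReferenceSequence, bands_match, validate_sequence
from .errors import InputError

# Canonical visible-band profiles, per marker.
CANONICAL_CYTB = {
    "UNCUT_350": (350,),
    "CUT_280": (280,),
    "CUT_117_164": (164, 117),
}
CANONICAL_S18 = {
    "UNCUT_412": (412,),
    "CUT_167_245": (245, 167),
}


class CytbState(str, Enum):
    UNCUT_350 = "UNCUT_350"        # mt lineage: A. anguilla
    CUT_280 = "CUT_280"            # mt lineage: A. rostrata or saltwater eel
    CUT_117_164 = "CUT_117_164"    # mt lineage: A. japonica
    OTHER = "OTHER"


class S18State(str, Enum):
    CUT_167_245 = "CUT_167_245"    # nuclear background: A. rostrata
    UNCUT_412 = "UNCUT_412"        # nuclear background: not A. rostrata
    OTHER = "OTHER"


class FinalCall(str, Enum):
    A_ROSTRATA = "A. rostrata"
    A_ANGUILLA = "A. anguilla"
    A_JAPONICA = "A. japonica"
    SALTWATER_OR_HYBRID = "Saltwater eel or hybrid"
    PUTATIVE_INTROGRESSED_HYBRID = "Putative introgressed hybrid"
    UNRESOLVED = "Unresolved"


SEQUENCING_REQUIRED = "SEQUENCING_REQUIRED"
CONFIRMED_BY_SEQUENCE = "CONFIRMED_BY_SEQUENCE"

#: the three freshwater (Anguilla) taxa the assay discriminates
ANGUILLA_TAXA = frozenset({"A. rostrata", "A. anguilla", "A. japonica"})

# mt lineage / nuclear background implied by each marker state.
_MT_LINEAGE = {
    CytbState.UNCUT_350: ("A. anguilla",),
    CytbState.CUT_280: ("A. rostrata", "saltwater eel"),
    CytbState.CUT_117_164: ("A. japonica",),
    CytbState.OTHER: (),
}
_NUCLEAR = {
    S18State.CUT_167_245: ("A. rostrata",),
    S18State.UNCUT_412: ("A. anguilla", "A. japonica", "saltwater eel"),
    S18State.OTHER: (),
}


@dataclass(frozen=True)
class MarkerCall:
    marker: Marker
    state: CytbState | S18State

    def __post_init__(self) -> None:
        expected = CytbState if self.marker is Marker.CYTB else S18State
        if not isinstance(self.state, expected):
            raise InputError(
                f"state {self.state!r} inconsistent with marker {self.marker.value}"
            )


@dataclass
class SpeciesCall:
    sample_id: str
    mt_lineage: tuple[str, ...]
    nuclear_background: tuple[str, ...]
    final: FinalCall
    flags: frozenset[str] = frozenset()
    confirmed_taxon: str | None = None
    confirmed_identity: float | None = None


@dataclass(frozen=True)
class IdentityHit:
    """Nearest and second-nearest panel references for a query sequence."""

    query_id: str
    best_taxon: str
    percent_identity: float
    runner_up_taxon: str | None
    runner_up_identity: float | None

    def __post_init__(self) -> None:
        if (
            self.runner_up_identity is not None
            and self.percent_identity < self.runner_up_identity
        ):
            raise InputError("best hit must be at least as good as runner-up")


def call_marker(profile: BandProfile) -> MarkerCall:
    """Match an observed band profile to the canonical per-marker patterns.

    Bands are compared within the profile's own relative tolerance; any
    profile matching none of the canonical patterns is reported as OTHER.
    """
    canon = CANONICAL_CYTB if profile.marker is Marker.CYTB else CANONICAL_S18
    states = CytbState if profile.marker is Marker.CYTB else S18State
    for name, expected in canon.items():
        if bands_match(profile.bands, expected, profile.tolerance):
            return MarkerCall(marker=profile.marker, state=states(name))
    return MarkerCall(marker=profile.marker, state=states.OTHER)


def combine_calls(
    cytb: MarkerCall, s18: MarkerCall, sample_id: str = ""
) -> SpeciesCall:
    """Combine the mitochondrial and nuclear marker calls into a species call.

    Concordant profiles give a species; a cut cytb over an uncut 18S is a
    saltwater eel or a hybrid (indistinguishable on the gel); an uncut cytb
    over a cut 18S is a putative American eel with introgressed European
    mtDNA.  Everything not positively identified as A. rostrata carries
    SEQUENCING_REQUIRED.
    """
    if cytb.marker is not Marker.CYTB or s18.marker is not Marker.S18:
        raise InputError("combine_calls needs one cytb call and one 18S call")
    c, s = cytb.state, s18.state
    seq_flag = frozenset({SEQUENCING_REQUIRED})
    if c is CytbState.OTHER or s is S18State.OTHER:
        final, flags = FinalCall.UNRESOLVED, seq_flag
    elif c is CytbState.CUT_280 and s is S18State.CUT_167_245:
        final, flags = FinalCall.A_ROSTRATA, frozenset()
    elif c is CytbState.UNCUT_350 and s is S18State.UNCUT_412:
        final, flags = FinalCall.A_ANGUILLA, seq_flag
    elif c is CytbState.CUT_117_164 and s is S18State.UNCUT_412:
        final, flags = FinalCall.A_JAPONICA, seq_flag
    elif c is CytbState.CUT_280 and s is S18State.UNCUT_412:
        final, flags = FinalCall.SALTWATER_OR_HYBRID, seq_flag
    elif c is CytbState.UNCUT_350 and s is S18State.CUT_167_245:
        final, flags = FinalCall.PUTATIVE_INTROGRESSED_HYBRID, seq_flag
    else:
        # cytb says A. japonica while 18S says A. rostrata: no biological
        # reading of this pattern is offered, so it stays unresolved.
        final, flags = FinalCall.UNRESOLVED, seq_flag
    return SpeciesCall(
        sample_id=sample_id,
        mt_lineage=_MT_LINEAGE[c],
        nuclear_background=_NUCLEAR[s],
        final=final,
        flags=flags,
    )


def percent_identity(a: str, b: str) -> float:
    """Pairwise identity in [0, 1]: matches / aligned length.

    Equal-length sequences are compared position-by-position (ungapped).
    Unequal lengths use an end-gap-free global alignment; internal indel
    columns count as mismatches, dangling ends are ignored.
    """
    a, b = validate_sequence(a), validate_sequence(b)
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b)) / len(a)
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    # end gaps are free (dangling ends are not penalised)
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older biopython
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    start = 0
    while sa[start] == "-" or sb[start] == "-":
        start += 1
    end = len(sa)
    while sa[end - 1] == "-" or sb[end - 1] == "-":
        end -= 1
    matches = sum(x == y and x != "-" for x, y in zip(sa[start:end], sb[start:end]))
    return matches / (end - start)


def confirm_identity(
    query: str,
    panel: list[ReferenceSequence],
    query_id: str = "query",
) -> IdentityHit:
    """Nearest-reference assignment: compare a query amplicon to every panel
    sequence and return the best and runner-up taxa by percent identity.

    Where several references share a taxon, the taxon's score is its best
    reference; the runner-up is the best-scoring *different* taxon.
    """
    if not panel:
        raise InputError("reference panel is empty")
    by_taxon: dict[str, float] = {}
    for ref in panel:
        ident = percent_identity(query, ref.sequence)
        if ident > by_taxon.get(ref.taxon, -1.0):
            by_taxon[ref.taxon] = ident
    ranked = sorted(by_taxon.items(), key=lambda kv: kv[1], reverse=True)
    best_taxon, best = ranked[0]
    runner = ranked[1] if len(ranked) > 1 else (None, None)
    return IdentityHit(
        query_id=query_id,
        best_taxon=best_taxon,
        percent_identity=best,
        runner_up_taxon=runner[0],
        runner_up_identity=runner[1],
    )


def apply_confirmation(
    call: SpeciesCall,
    hit: IdentityHit,
    *,
    threshold: float = 0.98,
) -> SpeciesCall:
    """Fold a sequence-comparison result back into a species call.

    A flagged call whose best panel hit agrees with the RFLP call at or
    above ``threshold`` identity gains CONFIRMED_BY_SEQUENCE.  A
    saltwater-or-hybrid call is resolved to a saltwater eel when the cytb
    query hits a non-*Anguilla* panel taxon; if it hits A. rostrata the
    hybrid flag is kept (never silently relabelled).
    """
    call.confirmed_taxon = hit.best_taxon
    call.confirmed_identity = hit.percent_identity
    if hit.percent_identity < threshold:
        return call
    if call.final is FinalCall.SALTWATER_OR_HYBRID:
        if hit.best_taxon not in ANGUILLA_TAXA:
            call.flags = call.flags | {CONFIRMED_BY_SEQUENCE}
        return call
    if hit.best_taxon == call.final.value:
        call.flags = call.flags | {CONFIRMED_BY_SEQUENCE}
    return call


#: Reporting label for each final call; on a gel alone a saltwater eel and
#: a rostrata-mtDNA hybrid are indistinguishable, and the reporting label
#: follows the label used for sequence-confirmed saltwater eels.
REPORT_LABEL = {
    FinalCall.A_ROSTRATA: "A. rostrata",
    FinalCall.A_ANGUILLA: "A. anguilla",
    FinalCall.A_JAPONICA: "A. japonica",
    FinalCall.SALTWATER_OR_HYBRID: "Saltwater eel",
    FinalCall.PUTATIVE_INTROGRESSED_HYBRID: "Putative introgressed hybrid",
    FinalCall.UNRESOLVED: "Unresolved",
}


def classify_profiles(
    cytb_profile: BandProfile, s18_profile: BandProfile, sample_id: str = ""
) -> SpeciesCall:
    """Convenience: per-marker calls plus concordance in one step."""
    return combine_calls(
        call_marker(cytb_profile), call_marker(s18_profile), sample_id=sample_id
    )


def classify_manifest(records: list) -> list:
    """Assign a SpeciesCall to every manifest record (in place) from its
    two band profiles; returns the same list."""
    for rec in records:
        rec.final_call = classify_profiles(
            rec.cytb_profile, rec.s18_profile, sample_id=rec.sample_id
        )
    return records


def species_split(records: list) -> dict[str, int]:
    """Count of classified records per reporting label."""
    counts: dict[str, int] = {}
    for rec in records:
        if rec.final_call is None:
            raise InputError(f"record {rec.sample_id} is not classified")
        label = REPORT_LABEL[rec.final_call.final]
        counts[label] = counts.get(label, 0) + 1
    return counts
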