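"""Virtual PCR amplification and restriction digestion.

The assay model is deliberately simple: primer sites are located by
(near-)exact string matching under IUPAC compatibility, restriction sites by
degenerate pattern matching on a linear molecule, and the gel is modelled by a
single visibility threshold (fragments shorter than it run off or are too
faint to score) plus a relative size tolerance when comparing against recorded
band sizes.  Thermodynamics, partial digestion and methylation sensitivity are
out of scope.

Coordinates are 0-based and half-open internally; a cut at position ``i``
separates ``[0, i)`` from ``[i, len)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import AlphabetError, AmplificationError, InputError

# IUPAC nucleotide codes -> set of unambiguous bases each represents.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class Marker(str, Enum):
    """The two diagnostic markers: mitochondrial cytb and nuclear 18S rRNA."""

    CYTB = "cytb"
    S18 = "18S"


def validate_sequence(sequence: str) -> str:
    """Upper-case ``sequence`` and check it against the IUPAC alphabet."""
    seq = sequence.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise AlphabetError(f"invalid nucleotide characters: {sorted(bad)!r}")
    if not seq:
        raise AlphabetError("empty sequence")
    return seq


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(sequence.upper()))


def iupac_compatible(a: str, b: str) -> bool:
    """True if the base sets of two IUPAC codes intersect."""
    return bool(IUPAC[a] & IUPAC[b])


@dataclass(frozen=True)
class ReferenceSequence:
    """A taxon-labelled marker sequence (reference panel entry)."""

    id: str
    taxon: str
    marker: Marker
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers.

    ``reverse`` is given 5'->3' on the opposite strand, as primers are
    conventionally written; its binding site on the template top strand is
    its reverse complement.
    """

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            validate_sequence(p)
            if not 15 <= len(p) <= 40:
                raise InputError(f"primer length {len(p)} outside 15-40 nt")
        if self.max_mismatch < 0:
            raise InputError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: degenerate recognition motif plus the
    top-strand cut offset within the motif (0-based)."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        validate_sequence(self.recognition)
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise InputError(
                f"cut_offset {self.cut_offset} outside recognition window"
            )


@dataclass(frozen=True)
class Amplicon:
    marker: Marker
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one amplicon with one enzyme.

    ``fragments`` are in left-to-right amplicon order; ``visible_bands`` are
    the fragments at or above the visibility threshold, largest first, as
    they would be scored on a gel.
    """

    enzyme: str
    cut_positions: tuple[int, ...]
    fragments: tuple[int, ...]
    visible_bands: tuple[int, ...]


@dataclass(frozen=True)
class BandProfile:
    """Observed gel bands for one marker, with a relative size tolerance."""

    marker: Marker
    bands: tuple[int, ...]
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if not self.bands:
            raise InputError("band profile must contain at least one band")
        if any(b <= 0 for b in self.bands):
            raise InputError("band sizes must be positive")
        if not 0 <= self.tolerance < 1:
            raise InputError("tolerance must be in [0, 1)")
        object.__setattr__(
            self, "bands", tuple(sorted(self.bands, reverse=True))
        )


_ACGT = frozenset("ACGT")


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    """Overlap-aware regex for a degenerate pattern over an unambiguous
    (pure A/C/G/T) sequence."""
    parts = []
    for c in pattern:
        bases = "".join(sorted(IUPAC[c]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def _window_starts(seq: str, pattern: str) -> list[int]:
    """All window start indices where ``pattern`` matches ``seq`` under
    IUPAC compatibility (overlaps included)."""
    if set(seq) <= _ACGT:
        return [m.start() for m in _pattern_regex(pattern).finditer(seq)]
    m = len(pattern)
    return [
        i
        for i in range(len(seq) - m + 1)
        if all(iupac_compatible(seq[i + j], pattern[j]) for j in range(m))
    ]


def scan_sites(
    sequence: str,
    enzyme: RestrictionEnzyme,
    *,
    both_strands: bool = True,
) -> list[int]:
    """Locate every cut position of ``enzyme`` in ``sequence``.

    Each recognition-site window contributes exactly one double-strand cut.
    A window matching in forward orientation cuts at ``start + cut_offset``;
    a window matching only in reverse orientation (its reverse complement
    matches the top strand) cuts at ``start + len - cut_offset``.  For the
    palindromic defaults (HinfI GANTC, PauI GCGCGC) the reverse scan adds
    nothing; it matters for asymmetric user-defined enzymes.

    Returns ascending, deduplicated positions (between-base indices).
    """
    seq = validate_sequence(sequence)
    m = len(enzyme.recognition)
    forward = set(_window_starts(seq, enzyme.recognition))
    cuts = {i + enzyme.cut_offset for i in forward}
    if both_strands:
        rc_pattern = reverse_complement(enzyme.recognition)
        for i in _window_starts(seq, rc_pattern):
            if i not in forward:
                cuts.add(i + m - enzyme.cut_offset)
    return sorted(cuts)


def _mismatch_positions(window: str, primer: str, limit: int) -> bool:
    """True if ``window`` matches ``primer`` with at most ``limit``
    incompatible positions."""
    misses = 0
    for a, b in zip(window, primer):
        if not iupac_compatible(a, b):
            misses += 1
            if misses > limit:
                return False
    return True


def _binding_sites(seq: str, primer: str, max_mismatch: int) -> list[int]:
    m = len(primer)
    if max_mismatch == 0:
        return _window_starts(seq, primer)
    return [
        i
        for i in range(len(seq) - m + 1)
        if _mismatch_positions(seq[i : i + m], primer, max_mismatch)
    ]


def amplify(
    template: ReferenceSequence,
    primers: PrimerPair,
    *,
    max_product_length: int = 5000,
) -> Amplicon:
    """Virtually amplify ``template`` with ``primers``.

    The product spans from the first base of the forward-primer site to the
    last base of the reverse-primer site (primers included).  When several
    site pairs exist the shortest product is returned, mimicking the
    dominant PCR product.
    """
    seq = template.sequence
    fwd_sites = _binding_sites(seq, primers.forward, primers.max_mismatch)
    if not fwd_sites:
        raise AmplificationError(
            f"no forward-primer site for {primers.name} on {template.id}"
        )
    rev_site_seq = reverse_complement(primers.reverse)
    rev_sites = _binding_sites(seq, rev_site_seq, primers.max_mismatch)
    if not rev_sites:
        raise AmplificationError(
            f"no reverse-primer site for {primers.name} on {template.id}"
        )
    flen, rlen = len(primers.forward), len(rev_site_seq)
    best: tuple[int, int] | None = None
    for f in fwd_sites:
        for r in rev_sites:
            if r >= f + flen:  # primers must not overlap
                length = r + rlen - f
                if best is None or length < best[1] - best[0]:
                    best = (f, r + rlen)
    if best is None:
        raise AmplificationError(
            f"primer sites of {primers.name} on {template.id} are not in "
            "amplifiable orientation"
        )
    start, end = best
    if end - start > max_product_length:
        raise AmplificationError(
            f"shortest product ({end - start} bp) exceeds the maximum "
            f"product length ({max_product_length} bp)"
        )
    return Amplicon(marker=template.marker, sequence=seq[start:end])


def digest(
    amplicon: Amplicon,
    enzyme: RestrictionEnzyme,
    *,
    visibility_threshold: int = 100,
    both_strands: bool = True,
) -> DigestResult:
    """Digest a linear amplicon and report fragments plus visible gel bands.

    Fragments shorter than ``visibility_threshold`` (default 100 bp, i.e.
    below the smallest ladder rung routinely scored) are dropped from
    ``visible_bands`` but kept in ``fragments``.
    """
    if visibility_threshold < 0:
        raise InputError("visibility_threshold must be >= 0")
    n = amplicon.length
    cuts = tuple(
        p for p in scan_sites(amplicon.sequence, enzyme, both_strands=both_strands)
        if 0 < p < n
    )
    bounds = (0,) + cuts + (n,)
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    visible = tuple(
        sorted((f for f in fragments if f >= visibility_threshold), reverse=True)
    )
    return DigestResult(
        enzyme=enzyme.name,
        cut_positions=cuts,
        fragments=fragments,
        visible_bands=visible,
    )


def profile_match(result: DigestResult, profile: BandProfile) -> bool:
    """True iff the digest's visible bands match the recorded profile:
    same band count and each pair within the profile's relative tolerance,
    compared largest-to-largest."""
    observed = result.visible_bands
    if len(observed) != len(profile.bands):
        return False
    return all(
        abs(obs - exp) <= profile.tolerance * exp
        for obs, exp in zip(observed, profile.bands)
    )


def bands_match(
    observed: tuple[int, ...] | list[int],
    expected: tuple[int, ...] | list[int],
    tolerance: float,
) -> bool:
    """Band-list comparison used both by :func:`profile_match` and by the
    classifier when matching observed profiles to canonical ones."""
    obs = sorted(observed, reverse=True)
    exp = sorted(expected, reverse=True)
    if len(obs) != len(exp):
        return False
    return all(abs(o - e) <= tolerance * e for o, e in zip(obs, exp))
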