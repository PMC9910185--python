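"""Exception hierarchy shared across the package."""


class EelidError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(EelidError, ValueError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


class AmplificationError(EelidError):
    """Virtual PCR could not produce a product (missing primer site,
    or the shortest product exceeds the configured maximum length)."""


class InputError(EelidError, ValueError):
    """Malformed or inconsistent user input (manifest rows, FASTA tags,
    mismatched markers, empty files)."""


class EmptyStratumError(InputError):
    """A survey stratum contains no eligible records after filtering."""


class ConfigError(EelidError, ValueError):
    """Invalid run configuration (out-of-range threshold, bad seed type)."""


class SimulationError(EelidError):
    """Synthetic-data generation failed (site scrubbing did not converge,
    mixture names a taxon absent from the panel)."""


class FixtureError(EelidError):
    """The bundled survey fixture failed its integrity check."""
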