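"""Exception hierarchy shared across the toolkit."""


class CrustError(Exception):
    """Base class for all toolkit errors."""


class InvalidRecordError(CrustError):
    """A record violates its field invariants (e.g. negative mismatch count)."""


class CoordinateError(CrustError):
    """An interval falls outside its contig or references an unknown contig."""


class DegenerateGenomeError(CrustError):
    """A genome with zero total length cannot be averaged over."""


class ConsistencyError(CrustError):
    """Cross-table references do not line up (e.g. island on unknown genome)."""


class AmbiguityError(CrustError):
    """More than one call from the same classifier for one vOTU."""


class NoAssociationError(CrustError):
    """Association typing requested for a vOTU with no linked MAGs."""


class DependencyError(CrustError):
    """A pipeline stage needs output from a stage that did not run."""


class ConfigError(CrustError):
    """A simulation or pipeline configuration is internally inconsistent."""
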