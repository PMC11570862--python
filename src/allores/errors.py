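"""Exception hierarchy shared across the package."""


class ContractError(ValueError):
    """A documented precondition or invariant was violated by the caller."""


class StructureParseError(ContractError):
    """A structure file could not be parsed under the requested standard."""


class ResidueMismatchError(ContractError):
    """Two structures expected to share a residue set do not."""
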