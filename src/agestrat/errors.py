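"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its contract.

    The message always names the offending entity (file, gene, species or
    rung) so that command-line users can locate the problem directly.
    """
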