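"""Exception hierarchy.

``HspClassError`` is the root of all errors this package raises on bad
input, so callers (and the CLI) can distinguish user error from bugs.
"""


class HspClassError(Exception):
    """Base class for all input/usage errors raised by hspclass."""


class RecordRejectedError(HspClassError):
    """A FASTA record failed sanitization; carries the record id."""

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        super().__init__(f"record {record_id!r} rejected: {reason}")


class EligibilityError(HspClassError):
    """One or more records are ineligible for the requested encoding."""

    def __init__(self, record_ids: list[str], reason: str):
        self.record_ids = list(record_ids)
        super().__init__(
            f"{len(self.record_ids)} record(s) ineligible ({reason}): "
            + ", ".join(self.record_ids[:10])
            + ("..." if len(self.record_ids) > 10 else "")
        )


class BundleError(HspClassError):
    """A model bundle is missing, incomplete, or version-incompatible."""
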