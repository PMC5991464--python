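"""Exception types shared across adrminer modules."""


class AdrMinerError(Exception):
    """Base class for all adrminer errors."""


class ParseError(AdrMinerError):
    """Malformed input file (TSV, OBO, or XML)."""


class DuplicateIdError(ParseError):
    """A term id occurs more than once in a dictionary source."""


class CycleError(ParseError):
    """The is-a relation of an ontology contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("is_a cycle: " + " -> ".join(map(str, self.cycle)))


class OffsetError(AdrMinerError):
    """A gold mention's offsets do not address its section text."""


class EmptyInputError(AdrMinerError):
    """An operation that needs at least one element received none."""


class UnknownTermError(AdrMinerError):
    """A referenced term id is absent from the ontology or dictionary."""


class EmptyClassError(AdrMinerError):
    """A drug class has no member drug in the profile table."""


class ConfigError(AdrMinerError):
    """An infeasible or invalid configuration."""
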